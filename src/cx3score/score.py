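"""The CX3CR1 score: percent change from baseline and its landmark maximum.

The score for a patient at a landmark week w is the largest percent change
from the pretreatment baseline over all post-baseline measurements taken at or
before w (the "maximal percent change"). A patient is rule-positive when the
score reaches the cutoff (default: an increase of at least 20%, inclusive).
Patients with no post-baseline measurement by w are unevaluable at that
landmark and excluded from landmark diagnostics rather than imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedScoreError, ValidationError
from .tables import CohortTable

DEFAULT_CUTOFF = 20.0
DEFAULT_LANDMARKS = (3, 6, 9, 12)


def percent_change(baseline_pct: float, followup_pct: float) -> float:
    """Signed percent change from baseline: 100 * (followup - baseline) / baseline."""
    if not np.isfinite(baseline_pct) or baseline_pct <= 0:
        raise UndefinedScoreError(
            f"percent change undefined for baseline {baseline_pct!r}; baseline must be > 0"
        )
    return 100.0 * (followup_pct - baseline_pct) / baseline_pct


def classify(score: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """Rule-positive iff score >= cutoff (the 'at least 20% increase' rule is inclusive)."""
    if not np.isfinite(score):
        raise ValidationError(f"cannot classify non-finite score {score!r}")
    return bool(score >= cutoff)


def max_score_by_week(weeks, changes, landmark_week: int) -> float:
    """Maximal percent change over measurements with 0 < week <= landmark_week.

    Returns NaN when the patient has no eligible post-baseline measurement
    (unevaluable at this landmark).
    """
    weeks = np.asarray(weeks, dtype=float)
    changes = np.asarray(changes, dtype=float)
    eligible = (weeks > 0) & (weeks <= landmark_week)
    if not eligible.any():
        return float("nan")
    return float(np.max(changes[eligible]))


def percent_changes(cohort: CohortTable) -> pd.DataFrame:
    """Per-visit percent change from baseline; week-0 rows are 0 by construction."""
    base = cohort.baseline()
    bad = sorted(base.index[base <= 0].tolist())
    if bad:
        raise UndefinedScoreError(f"zero baseline frequency for patients: {bad}")
    m = cohort.measurements.copy()
    b = base.reindex(m["patient_id"]).to_numpy()
    m["percent_change"] = 100.0 * (m["cx3cr1_pct"].to_numpy() - b) / b
    m.loc[m["week"] == 0, "percent_change"] = 0.0
    return m[["patient_id", "week", "percent_change"]]


def score_table(
    cohort: CohortTable,
    landmarks=DEFAULT_LANDMARKS,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """One row per patient x landmark: score, evaluable flag, rule decision.

    The score column is the maximal percent change by the landmark week; it is
    non-decreasing across landmarks for every patient. Unevaluable rows carry
    NaN scores and a null decision.
    """
    changes = percent_changes(cohort)
    rows = []
    for pid, grp in changes.groupby("patient_id", sort=True):
        weeks = grp["week"].to_numpy()
        vals = grp["percent_change"].to_numpy()
        for lw in landmarks:
            s = max_score_by_week(weeks, vals, lw)
            evaluable = bool(np.isfinite(s))
            rows.append({
                "patient_id": pid,
                "landmark_week": int(lw),
                "score": s,
                "evaluable": evaluable,
                "positive": classify(s, cutoff) if evaluable else pd.NA,
            })
    return pd.DataFrame(rows)
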