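"""End-to-end pipeline: score -> landmark diagnostics -> survival."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics, survival
from .errors import ValidationError
from .score import DEFAULT_CUTOFF, DEFAULT_LANDMARKS, score_table
from .tables import CohortTable


@dataclass
class RunConfig:
    measurements_path: str
    metadata_path: str
    landmarks: tuple = DEFAULT_LANDMARKS
    cutoff: float = DEFAULT_CUTOFF
    level: float = 0.95
    out_dir: str = "results"
    seed: int = 0
    verbose: bool = False

    def validate(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValidationError("confidence level must lie in (0, 1)")
        if len(self.landmarks) == 0 or any(w <= 0 for w in self.landmarks):
            raise ValidationError("landmarks must be positive weeks")


def _report_to_dict(report: diagnostics.DiagnosticReport) -> dict:
    t = report.table
    return {
        "counts": {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "n": t.n},
        "rates_pct": {k: round(100.0 * v, 1) if np.isfinite(v) else None
                      for k, v in report.rates.items()},
        "rate_intervals": {k: [round(lo, 4), round(hi, 4)]
                           for k, (lo, hi) in report.rate_intervals.items()},
        "odds_ratio": round(report.odds_ratio, 4),
        "odds_ratio_interval": [round(v, 4) for v in report.odds_ratio_interval],
        "odds_ratio_corrected": report.odds_ratio_corrected,
        "fisher_p": float(f"{report.fisher_p:.6g}"),
    }


def landmark_diagnostics(cohort: CohortTable, scores: pd.DataFrame,
                         landmark: int, level: float = 0.95):
    """Confusion-based report at one landmark, evaluable patients only."""
    labels = cohort.responder_labels()
    sub = scores[(scores["landmark_week"] == landmark) & scores["evaluable"]]
    if len(sub) == 0:
        raise ValidationError(f"no evaluable patients at landmark {landmark}")
    lab = labels.reindex(sub["patient_id"]).to_numpy(dtype=bool)
    return diagnostics.evaluate_binary(sub["positive"].to_numpy(dtype=bool), lab, level)


def survival_by_decision(cohort: CohortTable, scores: pd.DataFrame,
                         landmark: int, endpoint: str = "pfs", level: float = 0.95):
    """KM curves, log-rank and MH hazard ratio for rule-positive vs negative."""
    if endpoint not in ("pfs", "os"):
        raise ValidationError("endpoint must be 'pfs' or 'os'")
    sub = scores[(scores["landmark_week"] == landmark) & scores["evaluable"]]
    meta = cohort.metadata.set_index("patient_id").loc[sub["patient_id"]]
    pos = sub["positive"].to_numpy(dtype=bool)
    t = meta[f"{endpoint}_months"].to_numpy(dtype=float)
    e = meta[f"{endpoint}_event"].to_numpy(dtype=int)
    if pos.all() or not pos.any():
        raise ValidationError("both decision groups must be non-empty for survival")
    curve_pos = survival.km_curve(t[pos], e[pos])
    curve_neg = survival.km_curve(t[~pos], e[~pos])
    chi2, p = survival.logrank_test(t[pos], e[pos], t[~pos], e[~pos])
    hr, lo, hi = survival.mh_hazard_ratio(t[pos], e[pos], t[~pos], e[~pos], level)
    return {
        "endpoint": endpoint,
        "median_positive": curve_pos.median,
        "median_negative": curve_neg.median,
        "logrank_chi2": chi2,
        "logrank_p": p,
        "hazard_ratio": hr,
        "hazard_ratio_interval": (lo, hi),
        "curves": {"positive": curve_pos, "negative": curve_neg},
    }


def run_pipeline(cohort: CohortTable, config: RunConfig) -> dict:
    """Score the cohort, evaluate every landmark, and analyze survival.

    Writes scores.csv and report.json under config.out_dir; the JSON is
    deterministic (sorted keys, no timestamps) for identical inputs.
    """
    config.validate()
    observed = set(cohort.visit_weeks())
    outside = [w for w in config.landmarks if w not in observed]
    if outside:
        raise ValidationError(f"landmark weeks {outside} not among visit weeks {sorted(observed)}")
    scores = score_table(cohort, config.landmarks, config.cutoff)
    report = {"cutoff": config.cutoff, "landmarks": list(config.landmarks), "per_landmark": {}}
    for lw in config.landmarks:
        report["per_landmark"][str(lw)] = _report_to_dict(
            landmark_diagnostics(cohort, scores, lw, config.level)
        )
    final = max(config.landmarks)
    for endpoint in ("pfs", "os"):
        block = survival_by_decision(cohort, scores, final, endpoint, config.level)
        report[f"survival_{endpoint}"] = {
            "median_positive": None if not np.isfinite(block["median_positive"])
            else round(block["median_positive"], 3),
            "median_negative": None if not np.isfinite(block["median_negative"])
            else round(block["median_negative"], 3),
            "logrank_chi2": round(block["logrank_chi2"], 4),
            "logrank_p": float(f"{block['logrank_p']:.6g}"),
            "hazard_ratio": round(block["hazard_ratio"], 4),
            "hazard_ratio_interval": [round(v, 4) for v in block["hazard_ratio_interval"]],
        }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "scores.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
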