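"""Core longitudinal-cohort containers.

A cohort is two tables: per-visit biomarker measurements (long format, one row
per patient x week, CX3CR1+ percentage of CD8+ T cells) and per-patient
clinical metadata (best iRECIST response class, PD-L1 tumor proportion score,
and PFS/OS times with event flags). Responders are CR/PR, non-responders SD/PD.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

MEASUREMENT_COLUMNS = ["patient_id", "week", "cx3cr1_pct"]
METADATA_COLUMNS = [
    "patient_id", "response", "pdl1_tps",
    "pfs_months", "pfs_event", "os_months", "os_event",
]
RESPONDER_CLASSES = frozenset({"CR", "PR"})
NONRESPONDER_CLASSES = frozenset({"SD", "PD"})


@dataclass
class CohortTable:
    """Longitudinal biomarker measurements plus clinical metadata."""

    measurements: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        m, meta = self.measurements, self.metadata
        missing = [c for c in MEASUREMENT_COLUMNS if c not in m.columns]
        if missing:
            raise ValidationError(f"measurement table missing columns: {missing}")
        missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise ValidationError(f"metadata table missing columns: {missing}")
        dup = m.duplicated(subset=["patient_id", "week"])
        if dup.any():
            rows = m.loc[dup, ["patient_id", "week"]].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (patient, week) measurement rows: {rows}")
        if (m["week"] < 0).any():
            raise ValidationError("negative visit weeks present")
        bad = m[(m["cx3cr1_pct"] < 0) | (m["cx3cr1_pct"] > 100) | m["cx3cr1_pct"].isna()]
        if len(bad):
            raise ValidationError(
                f"cx3cr1_pct outside [0, 100] or missing for patients: "
                f"{sorted(bad['patient_id'].unique().tolist())}"
            )
        baselines = m[m["week"] == 0].groupby("patient_id").size()
        no_baseline = sorted(set(m["patient_id"]) - set(baselines.index))
        if no_baseline:
            raise ValidationError(f"patients missing a week-0 baseline row: {no_baseline}")
        if meta["patient_id"].duplicated().any():
            raise ValidationError("duplicate patient_id rows in metadata")
        unknown = set(meta["response"].dropna()) - (RESPONDER_CLASSES | NONRESPONDER_CLASSES)
        if unknown:
            raise ValidationError(f"unknown response classes: {sorted(unknown)}")
        orphans = sorted(set(m["patient_id"]) - set(meta["patient_id"]))
        if orphans:
            raise ValidationError(f"measurements for patients absent from metadata: {orphans}")

    @property
    def patient_ids(self) -> list:
        return sorted(self.metadata["patient_id"].tolist())

    def responder_labels(self) -> pd.Series:
        """Boolean responder (CR/PR) indicator indexed by patient_id."""
        meta = self.metadata.set_index("patient_id")
        return meta["response"].isin(sorted(RESPONDER_CLASSES))

    def baseline(self) -> pd.Series:
        """Week-0 CX3CR1+ percentage indexed by patient_id."""
        base = self.measurements[self.measurements["week"] == 0]
        return base.set_index("patient_id")["cx3cr1_pct"]

    def visit_weeks(self) -> list:
        return sorted(self.measurements["week"].unique().tolist())
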