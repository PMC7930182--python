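"""Reading and writing the cohort CSVs and ImmunoSEQ-style repertoire TSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .repertoire import CLONOTYPE_COLUMNS, Repertoire
from .tables import MEASUREMENT_COLUMNS, METADATA_COLUMNS, CohortTable

#: package-internal column -> default ImmunoSEQ export header
DEFAULT_REPERTOIRE_COLUMNS = {
    "nucleotide": "nucleotide",
    "amino_acid": "aminoAcid",
    "count": "count (templates/reads)",
    "frequency": "frequencyCount",
    "v_gene": "vGeneName",
    "j_gene": "jGeneName",
    "status": "sequenceStatus",
}
_COUNT_ALIASES = ("count (templates/reads)", "count", "templates", "reads")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValidationError(
            f"{path}: malformed numeric value {df.loc[bad.idxmax(), column]!r} "
            f"in column {column!r} at line {line}"
        )
    return converted


def read_cohort(measurements_path, metadata_path) -> CohortTable:
    """Read and validate a cohort from its measurement and metadata CSVs."""
    mpath, dpath = Path(measurements_path), Path(metadata_path)
    for p in (mpath, dpath):
        if not p.exists():
            raise ValidationError(f"file not found: {p}")
    m = pd.read_csv(mpath, dtype={"patient_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in m.columns]
    if missing:
        raise ValidationError(f"{mpath}: missing columns {missing}")
    m["week"] = _numeric(m, "week", mpath).astype(int)
    m["cx3cr1_pct"] = _numeric(m, "cx3cr1_pct", mpath)
    meta = pd.read_csv(dpath, dtype={"patient_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"{dpath}: missing columns {missing}")
    for col in ("pdl1_tps", "pfs_months", "os_months"):
        meta[col] = _numeric(meta, col, dpath)
    for col in ("pfs_event", "os_event"):
        meta[col] = _numeric(meta, col, dpath).astype(int)
    return CohortTable(measurements=m[MEASUREMENT_COLUMNS], metadata=meta[METADATA_COLUMNS])


def write_cohort(cohort: CohortTable, measurements_path, metadata_path) -> None:
    cohort.measurements.to_csv(measurements_path, index=False)
    cohort.metadata.to_csv(metadata_path, index=False)


def read_repertoire(tsv_path, column_map: dict | None = None) -> Repertoire:
    """Read an ImmunoSEQ-style rearrangement TSV.

    column_map overrides the default header names (keys: internal names as in
    Repertoire). The frequency column is optional; when absent it is
    recomputed as count / total count, and when present it must agree with
    the counts to 1e-6.
    """
    path = Path(tsv_path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    columns = dict(DEFAULT_REPERTOIRE_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if columns["count"] not in df.columns:
        for alias in _COUNT_ALIASES:
            if alias in df.columns:
                columns["count"] = alias
                break
    required = {k: columns[k] for k in ("nucleotide", "count")}
    missing = [v for v in required.values() if v not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    out = pd.DataFrame({"nucleotide": df[columns["nucleotide"]]})
    out["amino_acid"] = df.get(columns["amino_acid"], "")
    out["amino_acid"] = out["amino_acid"].fillna("")
    counts = _numeric(df, columns["count"], path)
    if (counts < 0).any():
        raise ValidationError(f"{path}: negative counts present")
    out["count"] = counts.astype(int)
    out["v_gene"] = df.get(columns["v_gene"], "")
    out["j_gene"] = df.get(columns["j_gene"], "")
    out["status"] = df.get(columns["status"], "In")
    rep = Repertoire.from_counts(out)
    if columns["frequency"] in df.columns:
        stated = _numeric(df, columns["frequency"], path).to_numpy(dtype=float)
        if np.abs(stated - rep.clonotypes["frequency"].to_numpy()).max() > 1e-6:
            raise ValidationError(
                f"{path}: frequency column inconsistent with counts (> 1e-6)"
            )
    return rep


def write_repertoire(rep: Repertoire, tsv_path, column_map: dict | None = None) -> None:
    columns = dict(DEFAULT_REPERTOIRE_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = rep.clonotypes[CLONOTYPE_COLUMNS].rename(
        columns={k: columns[k] for k in CLONOTYPE_COLUMNS}
    )
    df.to_csv(tsv_path, sep="\t", index=False)
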