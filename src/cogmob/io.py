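"""Readers/writers for cohort tables, metadata, covariates and reports.

Cohorts travel as three plain-text files: a subjects x variables CSV (first
column ``subject_id``), a variable-metadata CSV sidecar
(``variable_id, block, domain, direction, transform``) and a covariate CSV
(``subject_id, age, gender``).  The ground-truth record of a synthetic cohort
is JSON.  Reports are TSV with the layout of a published association summary:
cognitive domain, cognitive measure, motor domain, motor measure, rho and the
BH-adjusted p-value.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .generate import TruthSet
from .hierarchy import AssociationReport

__all__ = [
    "read_cohort",
    "write_cohort",
    "write_report",
    "write_truth",
    "read_truth",
]

_BLOCKS = {"cognitive", "motor"}
_DOMAINS = {
    "executive_function",
    "processing_speed",
    "memory",
    "language",
    "variability",
    "transition",
    "turn",
    "asymmetry",
    "rhythm",
    "pace",
}


def read_cohort(
    data_path, meta_path, cov_path, na_values=("", "NA", "NaN")
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the three cohort files.

    Raises :class:`SchemaError` naming the offending column/row on any
    mismatch between data and metadata, duplicate subject ids, unknown
    domains, or non-numeric cells.
    """
    data = pd.read_csv(data_path, index_col="subject_id", na_values=list(na_values))
    meta = pd.read_csv(meta_path, index_col="variable_id", keep_default_na=False)
    cov = pd.read_csv(cov_path, index_col="subject_id", na_values=list(na_values))

    if data.index.duplicated().any():
        dup = data.index[data.index.duplicated()][0]
        raise SchemaError(f"duplicate subject id {dup!r} in {data_path}")
    for col in data.columns:
        if col not in meta.index:
            raise SchemaError(f"data column {col!r} missing from metadata")
        if not pd.api.types.is_numeric_dtype(data[col]):
            bad = data[col][pd.to_numeric(data[col], errors="coerce").isna() & data[col].notna()]
            where = bad.index[0] if len(bad) else "?"
            raise SchemaError(f"non-numeric cell in column {col!r}, subject {where!r}")
    for vid in meta.index:
        if vid not in data.columns:
            raise SchemaError(f"metadata variable {vid!r} missing from data columns")
        block = meta.loc[vid, "block"]
        dom = meta.loc[vid, "domain"]
        if block not in _BLOCKS:
            raise SchemaError(
                f"variable {vid!r}: block {block!r} not in {sorted(_BLOCKS)}"
            )
        if dom not in _DOMAINS:
            raise SchemaError(
                f"variable {vid!r}: domain {dom!r} not in {sorted(_DOMAINS)}"
            )
    missing_cov = set(data.index) - set(cov.index)
    if missing_cov:
        raise SchemaError(f"subjects without covariates: {sorted(missing_cov)[:5]}")
    for col in ("age", "gender"):
        if col not in cov.columns:
            raise SchemaError(f"covariate file lacks column {col!r}")
    cov = cov.loc[data.index]
    return data, meta, cov


def write_cohort(out_dir, table, meta, covariates, truth: TruthSet | None = None):
    """Write a cohort to ``out_dir`` (data.csv, meta.csv, covariates.csv,
    truth.json when ground truth is given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "data.csv")
    meta.to_csv(out / "meta.csv")
    covariates.to_csv(out / "covariates.csv")
    if truth is not None:
        write_truth(truth, out / "truth.json")
    return out


def write_truth(truth: TruthSet, path):
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_truth(path) -> TruthSet:
    return TruthSet.from_dict(json.loads(Path(path).read_text()))


def _fmt_p(p: float, decimals: int = 3, floor: float | None = 0.001) -> str:
    if floor is not None and p < floor:
        return f"<{floor:g}"
    return f"{p:.{decimals}f}"


def write_report(
    report: AssociationReport,
    path,
    p_decimals: int = 3,
    p_floor: float | None = 0.001,
    selection_log_path=None,
):
    """Write the discovery table as TSV (header always present; an empty
    report yields a header-only file).  Adjusted p-values are printed to
    ``p_decimals`` decimals with values below ``p_floor`` shown as
    ``<floor`` (set ``p_floor=None`` to disable)."""
    rows = report.rows.copy()
    if len(rows):
        rows["adjusted_p"] = [
            _fmt_p(p, p_decimals, p_floor) for p in rows["adjusted_p"]
        ]
        rows["rho"] = [f"{r:.3f}" if np.isfinite(r) else "" for r in rows["rho"]]
        rows = rows[
            [
                "cognitive_domain",
                "cognitive_measure",
                "motor_domain",
                "motor_measure",
                "rho",
                "adjusted_p",
            ]
        ]
    else:
        rows = pd.DataFrame(
            columns=[
                "cognitive_domain",
                "cognitive_measure",
                "motor_domain",
                "motor_measure",
                "rho",
                "adjusted_p",
            ]
        )
    rows.to_csv(path, sep="\t", index=False)
    if selection_log_path is not None:
        report.selection_log.to_csv(selection_log_path, sep="\t", index=False)
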