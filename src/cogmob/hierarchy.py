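"""Two-stage hierarchical multiple testing over the correlation matrix.

Hypotheses are grouped into families: one family per (motor variable,
cognitive domain) pair, so the family count equals the number of motor
variables times the number of cognitive domains, and a family's members are
that domain's correlations with the motor variable.

Stage one screens families by the Simes combination of their member p-values
at level alpha (strictly smaller than 0.05 by default).  Stage two applies
the Benjamini-Hochberg step-up within each selected family separately at
level q (0.05 by default), reporting monotone-enforced adjusted p-values so
that "adjusted p <= q" and "rejected" coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .association import build_correlation_matrix
from .errors import EmptyAnalysisError, InputError, MetadataError
from .preprocess import preprocess_table, PreprocessResult

__all__ = [
    "HypothesisFamily",
    "AssociationReport",
    "group_hypotheses",
    "simes_pvalue",
    "screen_families",
    "bh_within_family",
    "run_pipeline",
]

_DOMAIN_VOCABULARY = {
    "cognitive": {"executive_function", "processing_speed", "memory", "language"},
    "motor": {"variability", "transition", "turn", "asymmetry", "rhythm", "pace"},
}


@dataclass
class HypothesisFamily:
    """All correlations between one motor variable and one cognitive domain."""

    motor_id: str
    motor_domain: str
    cognitive_domain: str
    members: list  # PartialCorrelation-like rows (dicts)
    simes_p: float | None = None
    selected: bool = False
    adjusted_p: dict = field(default_factory=dict)  # cognitive_id -> BH-adjusted p
    rejected: set = field(default_factory=set)  # cognitive ids

    @property
    def member_pvalues(self) -> list[float]:
        return [m["p"] for m in self.members]


@dataclass
class AssociationReport:
    """Selected-family BH discoveries plus the full selection log."""

    rows: pd.DataFrame  # cognitive_domain, cognitive_id, motor_domain, motor_id, rho, p, adjusted_p
    families: list  # every HypothesisFamily with simes_p and selection flag
    preprocess: PreprocessResult | None = None
    matrix: pd.DataFrame | None = None

    @property
    def selection_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motor_id": [f.motor_id for f in self.families],
                "motor_domain": [f.motor_domain for f in self.families],
                "cognitive_domain": [f.cognitive_domain for f in self.families],
                "n_members": [len(f.members) for f in self.families],
                "simes_p": [f.simes_p for f in self.families],
                "selected": [f.selected for f in self.families],
            }
        )

    @property
    def member_log(self) -> pd.DataFrame:
        rows = []
        for f in self.families:
            for m in f.members:
                rows.append(
                    {
                        "motor_id": f.motor_id,
                        "cognitive_domain": f.cognitive_domain,
                        "cognitive_id": m["cognitive_id"],
                        "rho": m["rho"],
                        "p": m["p"],
                        "adjusted_p": f.adjusted_p.get(m["cognitive_id"], np.nan),
                        "family_selected": f.selected,
                        "rejected": m["cognitive_id"] in f.rejected,
                    }
                )
        return pd.DataFrame(rows)


def group_hypotheses(matrix: pd.DataFrame, meta: pd.DataFrame) -> list[HypothesisFamily]:
    """Partition the correlation matrix into (motor variable, cognitive domain)
    families.  Every matrix entry lands in exactly one family."""
    for vid in set(matrix["cognitive_id"]) | set(matrix["motor_id"]):
        if vid not in meta.index:
            raise MetadataError(f"variable {vid!r} has no metadata")
        block = meta.loc[vid, "block"]
        dom = meta.loc[vid, "domain"]
        if block not in _DOMAIN_VOCABULARY:
            raise MetadataError(f"variable {vid!r}: unknown block {block!r}")
    cog_domain = {v: meta.loc[v, "domain"] for v in set(matrix["cognitive_id"])}
    motor_domain = {v: meta.loc[v, "domain"] for v in set(matrix["motor_id"])}

    families: dict[tuple[str, str], HypothesisFamily] = {}
    for row in matrix.itertuples(index=False):
        key = (row.motor_id, cog_domain[row.cognitive_id])
        if key not in families:
            families[key] = HypothesisFamily(
                motor_id=row.motor_id,
                motor_domain=motor_domain[row.motor_id],
                cognitive_domain=cog_domain[row.cognitive_id],
                members=[],
            )
        families[key].members.append(
            {
                "cognitive_id": row.cognitive_id,
                "rho": row.rho,
                "p": row.p,
                "n_used": row.n_used,
            }
        )
    return list(families.values())


def simes_pvalue(p: Sequence[float]) -> float:
    """Simes combination: min over i of m * p_(i) / i, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InputError("Simes p-value of an empty list is undefined")
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    m = p.size
    ps = np.sort(p)
    return float(min(1.0, np.min(m * ps / np.arange(1, m + 1))))


def screen_families(
    families: list[HypothesisFamily], alpha: float = 0.05
) -> list[HypothesisFamily]:
    """Stage one: compute each family's Simes p-value; select iff it is
    strictly below ``alpha``.  Flags are recorded on every family."""
    for f in families:
        f.simes_p = simes_pvalue(f.member_pvalues)
        f.selected = f.simes_p < alpha
    return [f for f in families if f.selected]


def bh_within_family(family: HypothesisFamily, q: float = 0.05) -> dict[str, float]:
    """Stage two: BH step-up on the family's member p-values only.

    Stores monotone-enforced adjusted p-values and the rejection set
    (adjusted p <= q) on the family; returns the adjusted p-values keyed by
    cognitive variable id.
    """
    ids = [m["cognitive_id"] for m in family.members]
    ps = np.asarray(family.member_pvalues, dtype=float)
    reject, p_adj, *_ = multipletests(ps, alpha=q, method="fdr_bh")
    family.adjusted_p = dict(zip(ids, p_adj.tolist()))
    family.rejected = {i for i, adj in family.adjusted_p.items() if adj <= q}
    return family.adjusted_p


_DOMAIN_ORDER = ["executive_function", "language", "processing_speed", "memory"]
_MOTOR_ORDER = ["variability", "transition", "turn", "asymmetry", "rhythm", "pace"]


def run_pipeline(
    data: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: pd.DataFrame,
    screening_alpha: float = 0.05,
    bh_q: float = 0.05,
    outlier_cutoff_numerator: float = 4.0,
    range_filter_threshold: float = 0.80,
    selection_adjusted_bh: bool = False,
) -> AssociationReport:
    """Full two-stage analysis: preprocess, correlate, screen, BH within family.

    With ``selection_adjusted_bh`` the within-family level becomes
    q * (#selected / #families) (the hierarchical average-FDR adjustment);
    off by default, matching the plain per-family BH procedure.
    """
    pre = preprocess_table(
        data,
        meta,
        covariates,
        cutoff_numerator=outlier_cutoff_numerator,
        range_threshold=range_filter_threshold,
    )
    kept = pre.data.columns
    cog = [v for v in kept if meta.loc[v, "block"] == "cognitive"]
    mot = [v for v in kept if meta.loc[v, "block"] == "motor"]
    if not cog or not mot:
        raise EmptyAnalysisError(
            "no testable variables remain after exclusion "
            f"({len(cog)} cognitive, {len(mot)} motor)"
        )
    matrix = build_correlation_matrix(pre.data[cog], pre.data[mot], covariates)
    families = group_hypotheses(matrix, meta)
    selected = screen_families(families, alpha=screening_alpha)
    q = bh_q
    if selection_adjusted_bh and families:
        q = bh_q * len(selected) / len(families)
    rows = []
    for f in selected:
        bh_within_family(f, q=q)
        for m in f.members:
            if m["cognitive_id"] in f.rejected:
                rows.append(
                    {
                        "cognitive_domain": f.cognitive_domain,
                        "cognitive_measure": m["cognitive_id"],
                        "motor_domain": f.motor_domain,
                        "motor_measure": f.motor_id,
                        "rho": m["rho"],
                        "p": m["p"],
                        "adjusted_p": f.adjusted_p[m["cognitive_id"]],
                    }
                )
    cols = [
        "cognitive_domain",
        "cognitive_measure",
        "motor_domain",
        "motor_measure",
        "rho",
        "p",
        "adjusted_p",
    ]
    report_rows = pd.DataFrame(rows, columns=cols)
    if len(report_rows):
        report_rows = report_rows.sort_values(
            by=["cognitive_domain", "motor_domain", "cognitive_measure", "motor_measure"],
            key=lambda s: (
                s.map({d: i for i, d in enumerate(_DOMAIN_ORDER)}).fillna(99)
                if s.name == "cognitive_domain"
                else s.map({d: i for i, d in enumerate(_MOTOR_ORDER)}).fillna(99)
                if s.name == "motor_domain"
                else s
            ),
            kind="stable",
        ).reset_index(drop=True)
    return AssociationReport(
        rows=report_rows, families=families, preprocess=pre, matrix=matrix
    )
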