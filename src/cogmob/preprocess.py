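"""Preprocessing: normality transforms, covariate-adjusted outlier removal and
the limited-range variable filter.

The transformation step replaces an interactive, semi-automated chooser with a
deterministic catalog: {identity, log(x+s), sqrt(x+s), 1/(x+s), Box-Cox with a
coarse profile-likelihood grid for lambda, rank-inverse-normal with Blom
offsets}.  The member maximizing the Shapiro-Wilk statistic is selected, ties
broken by catalog order.  Downstream statistics are rank-based, so any
monotone member leaves the analysis invariant; the catalog exists for
reproducibility, not inference.  Order-reversing members (the reciprocal) are
multiplied by -1 after transformation so the original ordering is restored.

Outliers are flagged per variable from a linear regression on age and gender:
externally studentized residuals, two-sided t-tail p-values on n-k-2 degrees
of freedom, Bonferroni multiplied by n, flagged when the Bonferroni p-value is
strictly smaller than 4/n.  Flagged cells are set missing cell-wise (the
subject's other variables are kept).

Variables whose modal value covers at least 80% of non-missing observations
are excluded as having too limited a range to carry rank information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InputError,
    RegressionRankError,
    TransformDomainError,
)

__all__ = [
    "TransformSpec",
    "OutlierResult",
    "OutlierReport",
    "ExclusionReport",
    "TRANSFORM_CATALOG",
    "select_and_apply_transform",
    "apply_transform",
    "detect_outliers",
    "limited_range_filter",
    "preprocess_table",
    "PreprocessResult",
]

TRANSFORM_CATALOG = (
    "identity",
    "log-shift",
    "sqrt-shift",
    "reciprocal",
    "box-cox",
    "rank-inverse-normal",
)

_BOXCOX_GRID = np.linspace(-2.0, 2.0, 17)  # coarse lambda grid


@dataclass(frozen=True)
class TransformSpec:
    """A catalog transformation with its fitted parameters."""

    name: str
    shift: float = 0.0
    lmbda: float | None = None
    order_reversing: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "shift": self.shift,
            "lmbda": self.lmbda,
            "order_reversing": self.order_reversing,
        }


def _auto_shift(x: np.ndarray, strict: bool) -> float:
    """Shift s = 1 - min(x) whenever positivity (strict) or non-negativity fails."""
    mn = np.nanmin(x)
    if (strict and mn > 0) or (not strict and mn >= 0):
        return 0.0
    return 1.0 - mn


def _fit_spec(x: np.ndarray, name: str) -> TransformSpec:
    """Fit shift / lambda parameters for catalog member ``name`` on data ``x``."""
    if name == "identity":
        return TransformSpec("identity")
    if name == "log-shift":
        return TransformSpec("log-shift", shift=_auto_shift(x, strict=True))
    if name == "sqrt-shift":
        return TransformSpec("sqrt-shift", shift=_auto_shift(x, strict=False))
    if name == "reciprocal":
        return TransformSpec(
            "reciprocal", shift=_auto_shift(x, strict=True), order_reversing=True
        )
    if name == "box-cox":
        s = _auto_shift(x, strict=True)
        y = x[~np.isnan(x)] + s
        if np.nanmin(y) <= 0 or np.all(y == y[0]):
            return TransformSpec("box-cox", shift=s, lmbda=1.0)
        llf = [stats.boxcox_llf(lm, y) for lm in _BOXCOX_GRID]
        lm = float(_BOXCOX_GRID[int(np.argmax(llf))])
        return TransformSpec("box-cox", shift=s, lmbda=lm)
    if name == "rank-inverse-normal":
        return TransformSpec("rank-inverse-normal")
    raise TransformDomainError(f"unknown transform {name!r}")


def apply_transform(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply ``spec`` verbatim; missing cells stay missing.

    Raises
    ------
    TransformDomainError
        If the transform is undefined on the (shifted) input domain.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    v = x[ok] + spec.shift
    name = spec.name
    if name == "identity":
        t = x[ok]
    elif name == "log-shift":
        if np.any(v <= 0):
            raise TransformDomainError("log-shift requires strictly positive values")
        t = np.log(v)
    elif name == "sqrt-shift":
        if np.any(v < 0):
            raise TransformDomainError("sqrt-shift requires non-negative values")
        t = np.sqrt(v)
    elif name == "reciprocal":
        if np.any(v == 0):
            raise TransformDomainError("reciprocal is undefined at zero")
        t = 1.0 / v
    elif name == "box-cox":
        if np.any(v <= 0):
            raise TransformDomainError("box-cox requires strictly positive values")
        lm = 1.0 if spec.lmbda is None else spec.lmbda
        t = np.log(v) if lm == 0 else (v**lm - 1.0) / lm
    elif name == "rank-inverse-normal":
        # Blom offsets: Phi^{-1}((r - 3/8) / (n + 1/4)) with average ranks.
        r = stats.rankdata(x[ok], method="average")
        t = stats.norm.ppf((r - 0.375) / (ok.sum() + 0.25))
    else:
        raise TransformDomainError(f"unknown transform {spec.name!r}")
    if spec.order_reversing:
        t = -t
    out[ok] = t
    return out


def select_and_apply_transform(
    values: np.ndarray, override: TransformSpec | None = None
) -> tuple[np.ndarray, TransformSpec]:
    """Pick the catalog transform maximizing the Shapiro-Wilk W and apply it.

    If ``override`` is given it is applied verbatim.  Selection is
    deterministic: ties are broken by catalog order.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 3:
        raise InputError("need at least 3 non-missing values to transform")
    if override is not None:
        return apply_transform(x, override), override
    best_spec, best_w = None, -np.inf
    if np.all(finite == finite[0]):
        # Constant input: normality is undefined, keep the identity.
        spec = TransformSpec("identity")
        return apply_transform(x, spec), spec
    for name in TRANSFORM_CATALOG:
        spec = _fit_spec(x, name)
        try:
            t = apply_transform(x, spec)
        except TransformDomainError:
            continue
        tv = t[~np.isnan(t)]
        if not np.all(np.isfinite(tv)) or np.all(tv == tv[0]):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = stats.shapiro(tv).statistic
        if np.isfinite(w) and w > best_w + 1e-12:
            best_spec, best_w = spec, w
    assert best_spec is not None
    return apply_transform(x, best_spec), best_spec


@dataclass
class OutlierResult:
    """Outlier diagnostics for one variable."""

    flagged: list  # subject labels
    studentized_residual: dict  # subject -> external t
    bonferroni_p: dict  # subject -> Bonferroni p
    cutoff_used: float  # 4/n as a probability
    n_used: int


@dataclass
class OutlierReport:
    """Flagged (subject, variable) cells across a table."""

    flagged: set = field(default_factory=set)  # (subject_id, variable_id)
    per_variable: dict = field(default_factory=dict)  # variable_id -> OutlierResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for vid, res in self.per_variable.items():
            for subj in res.flagged:
                rows.append(
                    {
                        "subject_id": subj,
                        "variable_id": vid,
                        "studentized_residual": res.studentized_residual[subj],
                        "bonferroni_p": res.bonferroni_p[subj],
                        "cutoff_used": res.cutoff_used,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "variable_id",
                "studentized_residual",
                "bonferroni_p",
                "cutoff_used",
            ],
        )


@dataclass
class ExclusionReport:
    """Limited-range exclusions with per-variable modal proportions."""

    excluded_variables: set = field(default_factory=set)
    modal_proportion: dict = field(default_factory=dict)
    threshold: float = 0.80

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable_id": list(self.modal_proportion),
                "modal_proportion": list(self.modal_proportion.values()),
                "excluded": [
                    v in self.excluded_variables for v in self.modal_proportion
                ],
                "threshold": self.threshold,
            }
        )


def external_studentized_residuals(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, int]:
    """Externally (leave-one-out) studentized residuals of an OLS fit.

    Returns the residual vector and the t degrees of freedom ``n - p - 1``
    (``p`` columns in ``X`` including the intercept).  Zero-leverage-complement
    or zero-variance edge cases yield 0 (a forced-zero residual is never an
    outlier); a point whose removal zeroes the residual variance yields +/-inf.
    """
    n, p = X.shape
    if n < p + 2:
        raise RegressionRankError(f"need at least {p + 2} observations, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise RegressionRankError("covariate design matrix is rank deficient")
    Q, _ = np.linalg.qr(X)
    h = np.sum(Q**2, axis=1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    sse = float(e @ e)
    dof = n - p
    t = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt((sse / dof) * (1.0 - h))
        r = np.where(denom > 0, e / denom, 0.0)
        inner = dof - r**2  # s_(i)^2 = s^2 (n-p-r^2)/(n-p-1)
        t = r * np.sqrt(np.where(inner > 0, (dof - 1) / inner, np.inf))
        t = np.where(r == 0, 0.0, t)
    return t, dof - 1


def detect_outliers(
    values: np.ndarray,
    covariates: pd.DataFrame,
    cutoff_numerator: float = 4.0,
    subjects: list | None = None,
) -> OutlierResult:
    """Bonferroni studentized-residual outlier test adjusting for the covariates.

    Fits the variable on an intercept plus the covariate columns, computes
    externally studentized residuals, two-sided t p-values, multiplies by the
    number of tested observations (Bonferroni), and flags cells whose
    Bonferroni p-value is strictly below ``cutoff_numerator / n``.
    """
    x = np.asarray(values, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if subjects is None:
        subjects = list(covariates.index)
    ok = ~np.isnan(x) & ~np.isnan(cov).any(axis=1)
    n = int(ok.sum())
    k = cov.shape[1]
    if n < k + 3:
        raise RegressionRankError(
            f"need at least {k + 3} complete observations, got {n}"
        )
    X = np.column_stack([np.ones(n), cov[ok]])
    t, df = external_studentized_residuals(x[ok], X)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    bonf = np.minimum(1.0, n * p)
    cutoff = cutoff_numerator / n
    labels = [s for s, keep in zip(subjects, ok) if keep]
    flag = bonf < cutoff  # strict, as specified
    return OutlierResult(
        flagged=[labels[i] for i in np.flatnonzero(flag)],
        studentized_residual={labels[i]: float(t[i]) for i in np.flatnonzero(flag)},
        bonferroni_p={labels[i]: float(bonf[i]) for i in np.flatnonzero(flag)},
        cutoff_used=cutoff,
        n_used=n,
    )


def limited_range_filter(
    values: np.ndarray, threshold: float = 0.80
) -> tuple[bool, float]:
    """Modal proportion among non-missing entries; excluded iff >= threshold.

    An all-missing variable is excluded with modal proportion 1.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size == 0:
        return True, 1.0
    _, counts = np.unique(finite, return_counts=True)
    prop = counts.max() / finite.size
    return prop >= threshold, float(prop)


@dataclass
class PreprocessResult:
    """Everything the preprocessing stage produced."""

    data: pd.DataFrame  # transformed, outlier cells set missing, exclusions dropped
    transforms: dict  # variable_id -> TransformSpec
    outliers: OutlierReport
    exclusions: ExclusionReport


def preprocess_table(
    data: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: pd.DataFrame,
    cutoff_numerator: float = 4.0,
    range_threshold: float = 0.80,
) -> PreprocessResult:
    """Run transform -> outlier removal -> limited-range exclusion on a table.

    Transform overrides come from the metadata ``transform`` column (catalog
    name; empty means automatic selection).  Outlier cells are set missing
    cell-wise.  Exclusion uses the modal proportion of the cleaned values.
    """
    cov = covariates.loc[data.index, ["age", "gender"]]
    out = {}
    transforms: dict[str, TransformSpec] = {}
    outrep = OutlierReport()
    for vid in data.columns:
        override = None
        tag = str(meta.loc[vid, "transform"]) if "transform" in meta.columns else ""
        if tag and tag not in ("", "nan", "auto"):
            override = _fit_spec(data[vid].to_numpy(dtype=float), tag)
        excluded_now, _ = limited_range_filter(
            data[vid].to_numpy(dtype=float), range_threshold
        )
        if excluded_now:
            # Near-constant variables cannot be normalized; carry them through
            # untransformed so the exclusion report sees the raw values.
            out[vid] = data[vid].to_numpy(dtype=float)
            transforms[vid] = TransformSpec("identity")
            continue
        vals, spec = select_and_apply_transform(
            data[vid].to_numpy(dtype=float), override
        )
        transforms[vid] = spec
        res = detect_outliers(
            vals, cov, cutoff_numerator=cutoff_numerator, subjects=list(data.index)
        )
        outrep.per_variable[vid] = res
        pos = {s: i for i, s in enumerate(data.index)}
        for subj in res.flagged:
            vals[pos[subj]] = np.nan
            outrep.flagged.add((subj, vid))
        out[vid] = vals
    cleaned = pd.DataFrame(out, index=data.index)

    excl = ExclusionReport(threshold=range_threshold)
    for vid in cleaned.columns:
        excluded, prop = limited_range_filter(
            cleaned[vid].to_numpy(dtype=float), range_threshold
        )
        excl.modal_proportion[vid] = prop
        if excluded:
            excl.excluded_variables.add(vid)
    kept = [v for v in cleaned.columns if v not in excl.excluded_variables]
    return PreprocessResult(
        data=cleaned[kept], transforms=transforms, outliers=outrep, exclusions=excl
    )
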