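"""Covariate-adjusted Spearman correlation between two variable blocks.

The partial Spearman correlation is built by rank-residualization: both
variables are converted to average ranks over the pairwise-complete cases,
each rank vector is residualized on an intercept plus the covariates by least
squares, and the Pearson correlation of the two residual vectors is taken.
The p-value uses the t approximation rho*sqrt((n-k-2)/(1-rho^2)) on n-k-2
degrees of freedom (two-sided).  With no covariates this reduces exactly to
ordinary Spearman rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCorrelationError, RegressionRankError

__all__ = ["PartialCorrelation", "partial_spearman", "build_correlation_matrix"]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class PartialCorrelation:
    cognitive_id: str
    motor_id: str
    rho: float
    p_value: float
    n_used: int


def _residualize(v: np.ndarray, X: np.ndarray | None) -> np.ndarray:
    if X is None:
        return v - v.mean()
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _rho_pvalue(rx: np.ndarray, ry: np.ndarray, n: int, k: int) -> tuple[float, float]:
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # residual variance indistinguishable from zero at rank scale (~n^3)
    tol = (np.finfo(float).eps * n**2) ** 2 * n
    if sx <= tol or sy <= tol:
        raise DegenerateCorrelationError(
            "zero residual variance; correlation undefined"
        )
    rho = float(rx @ ry / np.sqrt(sx * sy))
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, max(p, _TINY)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    cognitive_id: str = "x",
    motor_id: str = "y",
) -> PartialCorrelation:
    """Spearman correlation of ``x`` and ``y`` adjusted for the covariates.

    Cases are pairwise-complete: a row enters if ``x``, ``y`` and every
    covariate are non-missing.  Requires at least k+3 complete cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    ok = ~np.isnan(x) & ~np.isnan(y)
    if cov is not None:
        ok &= ~np.isnan(cov).any(axis=1)
    n = int(ok.sum())
    k = 0 if cov is None else cov.shape[1]
    if n < k + 3:
        raise RegressionRankError(
            f"need at least {k + 3} pairwise-complete cases, got {n}"
        )
    rx = stats.rankdata(x[ok], method="average")
    ry = stats.rankdata(y[ok], method="average")
    X = None if cov is None else np.column_stack([np.ones(n), cov[ok]])
    rho, p = _rho_pvalue(_residualize(rx, X), _residualize(ry, X), n, k)
    return PartialCorrelation(cognitive_id, motor_id, rho, p, n)


def build_correlation_matrix(
    cognitive_block: pd.DataFrame,
    motor_block: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """All (cognitive, motor) partial Spearman correlations, tidy.

    One row per pair with columns ``cognitive_id, motor_id, rho, p, n_used``.
    Pairs with too few complete cases or a degenerate residual are kept with
    ``rho`` missing and ``p = 1`` (conservative), with a warning.
    """
    cov = np.asarray(covariates, dtype=float)
    k = cov.shape[1]
    n_all = len(cognitive_block)

    # Cache ranks/residuals for variables complete on the all-covariates-complete
    # case set; pairs of two complete variables share it.
    cov_ok = ~np.isnan(cov).any(axis=1)
    X_full = np.column_stack([np.ones(int(cov_ok.sum())), cov[cov_ok]])
    cache: dict[str, np.ndarray | None] = {}

    def full_case_residual(df, vid):
        if vid not in cache:
            v = df[vid].to_numpy(dtype=float)
            if np.isnan(v[cov_ok]).any():
                cache[vid] = None
            else:
                r = stats.rankdata(v[cov_ok], method="average")
                cache[vid] = _residualize(r, X_full)
        return cache[vid]

    rows = []
    for cid in cognitive_block.columns:
        xc = cognitive_block[cid].to_numpy(dtype=float)
        for mid in motor_block.columns:
            ym = motor_block[mid].to_numpy(dtype=float)
            rc = full_case_residual(cognitive_block, cid)
            rm = full_case_residual(motor_block, mid)
            try:
                if rc is not None and rm is not None:
                    n = len(rc)
                    rho, p = _rho_pvalue(rc, rm, n, k)
                    pc = PartialCorrelation(cid, mid, rho, p, n)
                else:
                    pc = partial_spearman(xc, ym, covariates, cid, mid)
            except (RegressionRankError, DegenerateCorrelationError) as err:
                warnings.warn(
                    f"pair ({cid}, {mid}) untestable ({err}); propagating p = 1"
                )
                pc = PartialCorrelation(cid, mid, np.nan, 1.0, 0)
            rows.append(pc)
    out = pd.DataFrame(
        {
            "cognitive_id": [r.cognitive_id for r in rows],
            "motor_id": [r.motor_id for r in rows],
            "rho": [r.rho for r in rows],
            "p": [r.p_value for r in rows],
            "n_used": [r.n_used for r in rows],
        }
    )
    assert len(out) == cognitive_block.shape[1] * motor_block.shape[1]
    return out
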