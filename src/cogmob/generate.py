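"""Synthetic cohort generator.

Emulates a community cohort of healthy adults carrying one cognitive block
(four domains: executive function, processing speed, memory, language) and one
motor block (six gait/TUG domains: variability, transition, turn, asymmetry,
rhythm, pace), with age and gender confounding both blocks, a configurable set
of planted cross-block associations, monotone non-Gaussian marginal
distortions, injected single-cell outliers and near-constant variables.

Cross-block dependence is induced per planted link by a shared standardized
latent factor, which gives exact control of the pairwise partial correlation
given the covariates.  Link magnitudes are specified on the Spearman scale;
the Gaussian latent loading uses the copula conversion ``2*sin(pi*rho/6)`` so
the population rank correlation matches the configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, InputError

__all__ = [
    "GeneratorConfig",
    "TruthSet",
    "generate_cohort",
    "describe_cohort",
    "DEFAULT_COGNITIVE_DOMAINS",
    "DEFAULT_MOTOR_DOMAINS",
]

# Default inventory mirrors a 124-subject cognitive-aging cohort: 30 cognitive
# measures across four domains and 21 accelerometer-derived motor measures
# across six gait/TUG domains.
DEFAULT_COGNITIVE_DOMAINS: tuple[tuple[str, int], ...] = (
    ("executive_function", 11),
    ("processing_speed", 7),
    ("memory", 5),
    ("language", 7),
)
DEFAULT_MOTOR_DOMAINS: tuple[tuple[str, int], ...] = (
    ("variability", 4),
    ("transition", 4),
    ("turn", 2),
    ("asymmetry", 4),
    ("rhythm", 2),
    ("pace", 5),
)

# Whether larger raw values indicate better performance, per motor domain.
_MOTOR_DIRECTION = {
    "variability": "lower_better",
    "transition": "higher_better",
    "turn": "lower_better",
    "asymmetry": "lower_better",
    "rhythm": "lower_better",
    "pace": "higher_better",
}

_DISTORTION_TAGS = ("identity", "exponential", "heavy-tail", "bounded")


@dataclass(frozen=True)
class GeneratorConfig:
    """Scenario parameters for :func:`generate_cohort`.

    Defaults mirror the reference cohort: 124 subjects aged 27-80
    (mean 61.5, SD 11.9), 56.5% female.
    """

    n_subjects: int = 124
    age_range: tuple[float, float] = (27.0, 80.0)
    age_mean: float = 61.51
    age_sd: float = 11.90
    prop_female: float = 0.565
    cognitive_domains: tuple[tuple[str, int], ...] = DEFAULT_COGNITIVE_DOMAINS
    motor_domains: tuple[tuple[str, int], ...] = DEFAULT_MOTOR_DOMAINS
    age_effect_cog: float = -0.25  # standardized slope per decade of age
    age_effect_motor: float = -0.25
    gender_effect: float = 0.2  # standardized mean shift for gender == 1 (female)
    planted_links: tuple[tuple[str, str, float], ...] = ()
    marginal_distortions: dict[str, str] = field(default_factory=dict)
    outlier_contamination: float = 0.0  # fraction of data cells displaced
    outlier_magnitude: float = 6.0  # residual SDs
    n_degenerate_vars: int = 0
    degenerate_prop: float = 0.85
    missing_fraction: float = 0.0
    seed: int = 0

    def cognitive_ids(self) -> list[str]:
        return [
            f"cog_{dom}_{i + 1}"
            for dom, k in self.cognitive_domains
            for i in range(k)
        ]

    def motor_ids(self) -> list[str]:
        ids = [
            f"mot_{dom}_{i + 1}" for dom, k in self.motor_domains for i in range(k)
        ]
        ids += [f"mot_degenerate_{i + 1}" for i in range(self.n_degenerate_vars)]
        return ids

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ConfigurationError("n_subjects", "must be >= 10")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range", "low must be below high")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigurationError("prop_female", "must be in [0, 1]")
        if not self.cognitive_domains or not self.motor_domains:
            raise ConfigurationError(
                "cognitive_domains" if not self.cognitive_domains else "motor_domains",
                "at least one domain is required",
            )
        declared = set(self.cognitive_ids()) | set(self.motor_ids())
        linked: set[str] = set()
        for cog, mot, rho in self.planted_links:
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError(
                    "planted_links", f"magnitude {rho} for ({cog}, {mot}) not in [0, 1)"
                )
            for vid in (cog, mot):
                if vid not in declared:
                    raise ConfigurationError(
                        "planted_links", f"undeclared variable id {vid!r}"
                    )
                if vid in linked:
                    raise ConfigurationError(
                        "planted_links",
                        f"variable {vid!r} appears in more than one link",
                    )
                linked.add(vid)
        for vid, tag in self.marginal_distortions.items():
            if vid not in declared:
                raise ConfigurationError(
                    "marginal_distortions", f"undeclared variable id {vid!r}"
                )
            if tag not in _DISTORTION_TAGS:
                raise ConfigurationError(
                    "marginal_distortions",
                    f"unknown tag {tag!r}; expected one of {_DISTORTION_TAGS}",
                )
        if not 0.0 <= self.outlier_contamination < 1.0:
            raise ConfigurationError("outlier_contamination", "must be in [0, 1)")
        if self.n_degenerate_vars < 0:
            raise ConfigurationError("n_degenerate_vars", "must be >= 0")
        if not 0.0 < self.degenerate_prop <= 1.0:
            raise ConfigurationError("degenerate_prop", "must be in (0, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction", "must be in [0, 1)")


@dataclass
class TruthSet:
    """Generator ground truth used to score downstream discoveries."""

    planted_links: set[tuple[str, str]]
    injected_outliers: set[tuple[str, str]]  # (subject_id, variable_id)
    degenerate_variables: set[str]

    def to_dict(self) -> dict:
        return {
            "planted_links": sorted(self.planted_links),
            "injected_outliers": sorted(self.injected_outliers),
            "degenerate_variables": sorted(self.degenerate_variables),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        return cls(
            planted_links={tuple(x) for x in d["planted_links"]},
            injected_outliers={tuple(x) for x in d["injected_outliers"]},
            degenerate_variables=set(d["degenerate_variables"]),
        )


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion so planted rank correlations hit their target."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _truncated_normal(rng, n, mean, sd, lo, hi):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _distort(values: np.ndarray, tag: str) -> np.ndarray:
    if tag == "identity":
        return values
    if tag == "exponential":
        return np.exp(values)
    if tag == "heavy-tail":
        return values**3
    if tag == "bounded":
        return expit(values)
    raise ConfigurationError("marginal_distortions", f"unknown tag {tag!r}")


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthSet]:
    """Generate one synthetic cohort.

    Returns
    -------
    table : DataFrame, subjects x variables (index ``subject_id``)
    meta : DataFrame with columns ``block``, ``domain``, ``direction``,
        ``transform`` indexed by variable id
    covariates : DataFrame with columns ``age``, ``gender`` (1 = female)
    truth : TruthSet
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = [f"S{i + 1:04d}" for i in range(n)]

    age = _truncated_normal(
        rng, n, config.age_mean, config.age_sd, *config.age_range
    )
    gender = (rng.random(n) < config.prop_female).astype(float)
    age_c = (age - age.mean()) / 10.0  # decades, centred
    gender_c = gender - gender.mean()

    link_of: dict[str, tuple[int, float]] = {}
    latents = rng.standard_normal((len(config.planted_links), n))
    for idx, (cog, mot, rho_s) in enumerate(config.planted_links):
        loading = np.sqrt(_spearman_to_pearson(rho_s))
        link_of[cog] = (idx, loading)
        link_of[mot] = (idx, loading)

    meta_rows = []
    residuals: dict[str, np.ndarray] = {}
    systematic: dict[str, np.ndarray] = {}

    def make_block(domains: Iterable[tuple[str, int]], block: str, beta_age: float):
        for dom, k in domains:
            for i in range(k):
                vid = f"{'cog' if block == 'cognitive' else 'mot'}_{dom}_{i + 1}"
                if vid in link_of:
                    idx, a = link_of[vid]
                    resid = a * latents[idx] + np.sqrt(1 - a**2) * rng.standard_normal(n)
                else:
                    resid = rng.standard_normal(n)
                direction = (
                    "higher_better"
                    if block == "cognitive"
                    else _MOTOR_DIRECTION.get(dom, "higher_better")
                )
                residuals[vid] = resid
                systematic[vid] = (
                    beta_age * age_c + config.gender_effect * gender_c
                )
                meta_rows.append((vid, block, dom, direction, ""))

    make_block(config.cognitive_domains, "cognitive", config.age_effect_cog)
    make_block(config.motor_domains, "motor", config.age_effect_motor)

    var_ids = list(residuals)

    # Single-cell outliers displace the residual (post-covariate) component so
    # that covariate-adjusted detection must find them.
    injected: set[tuple[str, str]] = set()
    if config.outlier_contamination > 0:
        n_cells = int(round(config.outlier_contamination * n * len(var_ids)))
        flat = rng.choice(n * len(var_ids), size=n_cells, replace=False)
        for cell in flat:
            si, vi = divmod(int(cell), len(var_ids))
            vid = var_ids[vi]
            # Displace away from zero so the net residual is >= the magnitude.
            sign = np.sign(residuals[vid][si]) or (1.0 if rng.random() < 0.5 else -1.0)
            residuals[vid] = residuals[vid].copy()
            residuals[vid][si] += sign * config.outlier_magnitude
            injected.add((subjects[si], vid))

    data = {}
    for vid in var_ids:
        z = systematic[vid] + residuals[vid]
        block, dom = next((b, d) for v, b, d, _, _ in meta_rows if v == vid)
        direction = next(dr for v, _, _, dr, _ in meta_rows if v == vid)
        if direction == "lower_better":
            z = -z
        data[vid] = _distort(z, config.marginal_distortions.get(vid, "identity"))

    # Near-constant variables: round(degenerate_prop * n) subjects share one value.
    degenerate: set[str] = set()
    for i in range(config.n_degenerate_vars):
        vid = f"mot_degenerate_{i + 1}"
        n_same = int(round(config.degenerate_prop * n))
        vals = np.abs(rng.standard_normal(n)) + 0.5  # never equal to the mode (0.0)
        same_idx = rng.choice(n, size=n_same, replace=False)
        vals[same_idx] = 0.0
        data[vid] = vals
        dom = config.motor_domains[0][0]
        meta_rows.append((vid, "motor", dom, "higher_better", ""))
        degenerate.add(vid)

    table = pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"))
    if config.missing_fraction > 0:
        mask = rng.random(table.shape) < config.missing_fraction
        table = table.mask(mask)

    meta = pd.DataFrame(
        meta_rows, columns=["variable_id", "block", "domain", "direction", "transform"]
    ).set_index("variable_id")
    covariates = pd.DataFrame(
        {"age": age, "gender": gender}, index=pd.Index(subjects, name="subject_id")
    )
    truth = TruthSet(
        planted_links={(c, m) for c, m, _ in config.planted_links},
        injected_outliers=injected,
        degenerate_variables=degenerate,
    )
    return table, meta, covariates, truth


def describe_cohort(table: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean/SD/min/max plus covariate summaries (demographics table)."""
    if table.empty:
        raise InputError("cohort table is empty")
    rows = []
    for name, col in list(covariates.items()) + list(table.items()):
        vals = col.dropna()
        rows.append(
            {
                "variable": name,
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                "min": vals.min() if len(vals) else np.nan,
                "max": vals.max() if len(vals) else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["age_range"] = list(d["age_range"])
    d["cognitive_domains"] = [list(x) for x in d["cognitive_domains"]]
    d["motor_domains"] = [list(x) for x in d["motor_domains"]]
    d["planted_links"] = [list(x) for x in d["planted_links"]]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in ("age_range",):
        if key in d:
            d[key] = tuple(d[key])
    for key in ("cognitive_domains", "motor_domains", "planted_links"):
        if key in d:
            d[key] = tuple(tuple(x) for x in d[key])
    return GeneratorConfig(**d)
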