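"""Monte-Carlo operating characteristics of the two-stage pipeline.

Replicates are generated from independent seed streams, run through the full
pipeline (transforms, outlier removal, exclusion, partial Spearman matrix,
Simes screening, within-family BH), and scored against the generator's truth
set.  Reported characteristics:

- family selection rate (per family and average),
- power: fraction of planted links appearing in the report,
- empirical_fdr: per-replicate proportion of reported pairs not planted
  (0 when nothing is reported, the standard FDR expectation convention),
- signal_family_fdr: within-family false-discovery proportion restricted to
  families that contain a planted link, averaged over those families and
  replicates — the quantity the within-family BH stage controls in the
  strong-selection regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InputError
from .generate import GeneratorConfig, generate_cohort
from .hierarchy import run_pipeline, simes_pvalue

__all__ = [
    "OperatingCharacteristics",
    "estimate_operating_characteristics",
    "simes_null_selection_rate",
    "null_scenario",
    "signal_scenario",
    "recovery_scenario",
]


@dataclass
class OperatingCharacteristics:
    n_replicates: int
    family_selection_rate: dict  # (motor_id, cognitive_domain) -> fraction
    mean_selection_rate: float
    empirical_fdr: float
    signal_family_fdr: float
    power: float
    all_links_recovered_rate: float = float("nan")
    monte_carlo_se: dict = field(default_factory=dict)
    n_replicates_with_rejections: int = 0

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "mean_selection_rate": self.mean_selection_rate,
            "family_selection_rate": {
                f"{m}|{d}": r for (m, d), r in self.family_selection_rate.items()
            },
            "empirical_fdr": self.empirical_fdr,
            "signal_family_fdr": self.signal_family_fdr,
            "power": self.power,
            "all_links_recovered_rate": self.all_links_recovered_rate,
            "monte_carlo_se": self.monte_carlo_se,
            "n_replicates_with_rejections": self.n_replicates_with_rejections,
        }


def _rate_se(r: float, n: int) -> float:
    return float(np.sqrt(r * (1.0 - r) / n)) if n else float("nan")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def estimate_operating_characteristics(
    gen_config: GeneratorConfig,
    n_replicates: int = 500,
    seed: int = 0,
    screening_alpha: float = 0.05,
    bh_q: float = 0.05,
    selection_adjusted_bh: bool = False,
) -> OperatingCharacteristics:
    """Run ``n_replicates`` independent full-pipeline replicates and score them."""
    if n_replicates < 100:
        raise InputError("need at least 100 replicates for rate estimates")
    seeds = _child_seeds(seed, n_replicates)
    sel_counts: dict[tuple[str, str], int] = {}
    fdp_values = []
    signal_fdp_values = []
    power_values = []
    all_found_values = []
    n_with_rejections = 0

    for s in seeds:
        cfg = replace(gen_config, seed=s)
        table, meta, cov, truth = generate_cohort(cfg)
        report = run_pipeline(
            table,
            meta,
            cov,
            screening_alpha=screening_alpha,
            bh_q=bh_q,
            selection_adjusted_bh=selection_adjusted_bh,
        )
        cog_domain = {v: meta.loc[v, "domain"] for v in meta.index}
        signal_families = {
            (m, cog_domain[c]) for c, m in truth.planted_links
        }
        for f in report.families:
            key = (f.motor_id, f.cognitive_domain)
            sel_counts[key] = sel_counts.get(key, 0) + int(f.selected)

        reported = {
            (r.cognitive_measure, r.motor_measure)
            for r in report.rows.itertuples(index=False)
        }
        n_rej = len(reported)
        if n_rej:
            n_with_rejections += 1
            false = len(reported - truth.planted_links)
            fdp_values.append(false / n_rej)
        else:
            fdp_values.append(0.0)

        # Within-family FDP restricted to signal-bearing families.
        for f in report.families:
            if (f.motor_id, f.cognitive_domain) not in signal_families:
                continue
            if not f.selected:
                signal_fdp_values.append(0.0)
                continue
            rej_pairs = {(c, f.motor_id) for c in f.rejected}
            if rej_pairs:
                v = len(rej_pairs - truth.planted_links)
                signal_fdp_values.append(v / len(rej_pairs))
            else:
                signal_fdp_values.append(0.0)

        if truth.planted_links:
            found = len(reported & truth.planted_links)
            power_values.append(found / len(truth.planted_links))
            all_found_values.append(float(found == len(truth.planted_links)))

    family_rate = {k: c / n_replicates for k, c in sel_counts.items()}
    mean_rate = float(np.mean(list(family_rate.values()))) if family_rate else 0.0
    fdr = float(np.mean(fdp_values))
    sig_fdr = float(np.mean(signal_fdp_values)) if signal_fdp_values else 0.0
    power = float(np.mean(power_values)) if power_values else float("nan")
    all_found = float(np.mean(all_found_values)) if all_found_values else float("nan")
    se = {
        "mean_selection_rate": _rate_se(mean_rate, n_replicates * max(1, len(family_rate))),
        "empirical_fdr": float(np.std(fdp_values, ddof=1) / np.sqrt(len(fdp_values)))
        if len(fdp_values) > 1
        else float("nan"),
        "signal_family_fdr": float(
            np.std(signal_fdp_values, ddof=1) / np.sqrt(len(signal_fdp_values))
        )
        if len(signal_fdp_values) > 1
        else float("nan"),
        "power": _rate_se(power, n_replicates) if power_values else float("nan"),
    }
    return OperatingCharacteristics(
        n_replicates=n_replicates,
        family_selection_rate=family_rate,
        mean_selection_rate=mean_rate,
        empirical_fdr=fdr,
        signal_family_fdr=sig_fdr,
        power=power,
        all_links_recovered_rate=all_found,
        monte_carlo_se=se,
        n_replicates_with_rejections=n_with_rejections,
    )


def simes_null_selection_rate(
    family_sizes=tuple(range(3, 15)),
    n_replicates: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Empirical per-family Simes selection rate under the global null.

    Draws independent Uniform(0,1) member p-values for families of the given
    sizes, applies the Simes screen at ``alpha`` (strict), and returns the
    fraction of families selected plus its Monte-Carlo standard error.
    """
    rng = np.random.default_rng(seed)
    selected = 0
    total = 0
    for _ in range(n_replicates):
        for m in family_sizes:
            p = rng.random(m)
            p = np.clip(p, np.finfo(float).tiny, 1.0)
            selected += simes_pvalue(p) < alpha
            total += 1
    rate = selected / total
    return float(rate), _rate_se(rate, total)


def null_scenario(
    n_subjects: int = 80, n_cog: int = 3, n_motor: int = 3
) -> GeneratorConfig:
    """Global null: no planted links, clean marginals."""
    return GeneratorConfig(
        n_subjects=n_subjects,
        cognitive_domains=(("executive_function", n_cog),),
        motor_domains=(("pace", n_motor),),
        planted_links=(),
    )


def signal_scenario(
    n_subjects: int = 500, link_strength: float = 0.5
) -> GeneratorConfig:
    """Strong-selection scenario: six planted links, each in its own family.

    Two cognitive domains of three variables and six motor variables give
    twelve families, six carrying one strong link each (selected with
    probability near one at n=500) and six null.
    """
    links = tuple(
        [(f"cog_executive_function_{i}", f"mot_pace_{i}", link_strength) for i in (1, 2, 3)]
        + [(f"cog_language_{i}", f"mot_turn_{i}", link_strength) for i in (1, 2, 3)]
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        cognitive_domains=(("executive_function", 3), ("language", 3)),
        motor_domains=(("pace", 3), ("turn", 3)),
        planted_links=links,
    )


def recovery_scenario(
    n_subjects: int = 500, link_strength: float = 0.5
) -> GeneratorConfig:
    """Three strong links among otherwise-null variables (recovery check)."""
    links = (
        ("cog_executive_function_1", "mot_pace_1", link_strength),
        ("cog_executive_function_2", "mot_pace_2", link_strength),
        ("cog_language_1", "mot_turn_1", link_strength),
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        cognitive_domains=(("executive_function", 3), ("language", 3)),
        motor_domains=(("pace", 3), ("turn", 3)),
        planted_links=links,
    )
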