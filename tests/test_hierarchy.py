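"""Family construction, Simes screening, within-family BH, full pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cogmob import (
    GeneratorConfig,
    HypothesisFamily,
    bh_within_family,
    build_correlation_matrix,
    generate_cohort,
    group_hypotheses,
    run_pipeline,
    screen_families,
    simes_pvalue,
)
from cogmob.errors import EmptyAnalysisError, InputError, MetadataError

# --------------------------------------------------------------------- Simes
def test_simes_hand_evaluated_examples():
    assert simes_pvalue([0.01, 0.04, 0.03]) == pytest.approx(0.03)
    assert simes_pvalue([0.2]) == 0.2
    assert simes_pvalue([1.0, 1.0, 1.0]) == 1.0


@pytest.mark.parametrize("bad", [[], [0.0, 0.5], [0.5, 1.2], [np.nan]])
def test_simes_rejects_invalid_input(bad):
    with pytest.raises(InputError):
        simes_pvalue(bad)


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=6))
def test_simes_matches_exhaustive_definition(ps):
    m = len(ps)
    srt = sorted(ps)
    brute = min(1.0, min(m * srt[i] / (i + 1) for i in range(m)))
    assert simes_pvalue(ps) == pytest.approx(brute, abs=1e-12)


def test_simes_level_under_uniform_null():
    rng = np.random.default_rng(6)
    hits = sum(
        simes_pvalue(rng.random(4).clip(1e-12)) < 0.05 for _ in range(4000)
    )
    rate = hits / 4000
    assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 4000)


# ------------------------------------------------------------------------ BH
def _family(ps):
    return HypothesisFamily(
        motor_id="m",
        motor_domain="pace",
        cognitive_domain="memory",
        members=[{"cognitive_id": f"c{i}", "rho": 0.1, "p": p, "n_used": 100}
                 for i, p in enumerate(ps)],
        selected=True,
    )


def test_bh_hand_evaluated_example():
    fam = _family([0.01, 0.02, 0.20])
    adj = bh_within_family(fam, q=0.05)
    assert adj == pytest.approx({"c0": 0.03, "c1": 0.03, "c2": 0.20})
    assert fam.rejected == {"c0", "c1"}


def test_bh_degenerate_cases():
    fam = _family([1.0, 1.0])
    bh_within_family(fam)
    assert fam.rejected == set()
    single = _family([0.04])
    adj = bh_within_family(single)
    assert adj["c0"] == pytest.approx(0.04) and single.rejected == {"c0"}


@settings(max_examples=300, deadline=None)
@given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=6))
def test_bh_matches_step_up_definition(ps):
    """Rejections equal the explicit step-up rule: reject the smallest i*
    p-values where i* is the largest i with p_(i) <= i q / m."""
    q = 0.05
    fam = _family(ps)
    bh_within_family(fam, q=q)
    srt = np.sort(ps)
    m = len(ps)
    below = [i + 1 for i in range(m) if srt[i] <= (i + 1) * q / m]
    k = max(below) if below else 0
    cutoff = srt[k - 1] if k else -1.0
    expected = {f"c{i}" for i, p in enumerate(ps) if p <= cutoff}
    assert fam.rejected == expected
    # adjusted p-values are monotone in the raw ordering
    order = np.argsort(ps, kind="stable")
    adj_sorted = [fam.adjusted_p[f"c{i}"] for i in order]
    assert all(a <= b + 1e-12 for a, b in zip(adj_sorted, adj_sorted[1:]))


@settings(max_examples=100, deadline=None)
@given(
    st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6),
    st.integers(0, 5),
    st.floats(0.1, 0.99),
)
def test_lowering_a_pvalue_never_loses_selection_or_rejections(ps, idx, frac):
    """Decreasing any member p-value keeps the family selected and keeps
    every previously rejected member rejected."""
    idx = idx % len(ps)
    fam1 = _family(ps)
    screen_families([fam1])
    bh_within_family(fam1)
    ps2 = list(ps)
    ps2[idx] = ps[idx] * frac
    fam2 = _family(ps2)
    screen_families([fam2])
    bh_within_family(fam2)
    if fam1.selected:
        assert fam2.selected
        assert fam1.rejected <= fam2.rejected


def test_screening_boundary_is_strict():
    low, high = _family([0.049]), _family([0.05])
    selected = screen_families([low, high], alpha=0.05)
    assert low.selected and not high.selected
    assert selected == [low]


# ------------------------------------------------------------------ families
def _matrix_and_meta(cog_domains, n_motor):
    rows = []
    meta_rows = []
    for dom, k in cog_domains:
        for i in range(k):
            meta_rows.append((f"cog_{dom}_{i}", "cognitive", dom))
    for j in range(n_motor):
        meta_rows.append((f"mot_{j}", "motor", "pace"))
    rng = np.random.default_rng(0)
    for dom, k in cog_domains:
        for i in range(k):
            for j in range(n_motor):
                rows.append(
                    {
                        "cognitive_id": f"cog_{dom}_{i}",
                        "motor_id": f"mot_{j}",
                        "rho": 0.0,
                        "p": float(rng.uniform(0.01, 1)),
                        "n_used": 100,
                    }
                )
    matrix = pd.DataFrame(rows)
    meta = pd.DataFrame(
        meta_rows, columns=["variable_id", "block", "domain"]
    ).set_index("variable_id")
    return matrix, meta


def test_family_count_is_motor_times_domains():
    matrix, meta = _matrix_and_meta(
        [("executive_function", 11), ("processing_speed", 7),
         ("memory", 5), ("language", 7)],
        21,
    )
    fams = group_hypotheses(matrix, meta)
    assert len(fams) == 84  # 21 motor variables x 4 cognitive domains
    sizes = {f.cognitive_domain: len(f.members) for f in fams}
    assert sizes == {"executive_function": 11, "processing_speed": 7,
                     "memory": 5, "language": 7}
    assert sum(len(f.members) for f in fams) == len(matrix)


def test_minimal_family_and_partition_after_exclusion():
    matrix, meta = _matrix_and_meta([("memory", 3)], 1)
    fams = group_hypotheses(matrix, meta)
    assert len(fams) == 1 and len(fams[0].members) == 3
    smaller = group_hypotheses(
        matrix[matrix.cognitive_id != "cog_memory_0"], meta
    )
    assert len(smaller) == 1 and len(smaller[0].members) == 2


def test_unknown_block_raises_metadata_error():
    matrix, meta = _matrix_and_meta([("memory", 2)], 1)
    meta.loc["cog_memory_0", "block"] = "mystery"
    with pytest.raises(MetadataError):
        group_hypotheses(matrix, meta)
    with pytest.raises(MetadataError):
        group_hypotheses(matrix, meta.drop(index="cog_memory_1"))


# ------------------------------------------------------------------ pipeline
def test_pipeline_report_schema_and_selection_log(small_cohort):
    table, meta, cov, _ = small_cohort
    report = run_pipeline(table, meta, cov)
    assert list(report.rows.columns) == [
        "cognitive_domain", "cognitive_measure", "motor_domain",
        "motor_measure", "rho", "p", "adjusted_p",
    ]
    # 3 motor variables x 2 cognitive domains
    assert len(report.families) == 6
    log = report.selection_log
    assert log["simes_p"].between(0, 1).all()
    assert (report.rows["adjusted_p"] <= 0.05).all()
    members = report.member_log
    assert len(members) == sum(len(f.members) for f in report.families)


def test_null_cohorts_usually_report_nothing():
    empty = 0
    for seed in range(25):
        cfg = GeneratorConfig(
            n_subjects=60,
            cognitive_domains=(("memory", 3),),
            motor_domains=(("pace", 2),),
            seed=seed,
        )
        table, meta, cov, _ = generate_cohort(cfg)
        report = run_pipeline(table, meta, cov)
        empty += len(report.rows) == 0
    # 2 families at alpha=0.05: ~90% of replicates should be empty
    assert empty >= 17


def test_planted_link_dominates_matrix(small_cohort):
    cfg = GeneratorConfig(
        n_subjects=1000,
        cognitive_domains=(("memory", 3),),
        motor_domains=(("pace", 3),),
        planted_links=(("cog_memory_1", "mot_pace_1", 0.5),),
        seed=21,
    )
    table, meta, cov, _ = generate_cohort(cfg)
    mat = build_correlation_matrix(
        table[[c for c in table if c.startswith("cog")]],
        table[[c for c in table if c.startswith("mot")]],
        cov,
    )
    top = mat.loc[mat["rho"].abs().idxmax()]
    assert (top.cognitive_id, top.motor_id) == ("cog_memory_1", "mot_pace_1")


def test_all_variables_excluded_raises():
    n = 30
    table = pd.DataFrame(
        {"cog_memory_1": np.ones(n), "mot_pace_1": np.zeros(n)},
        index=[f"S{i}" for i in range(n)],
    )
    meta = pd.DataFrame(
        {
            "block": ["cognitive", "motor"],
            "domain": ["memory", "pace"],
            "direction": ["higher_better"] * 2,
            "transform": ["", ""],
        },
        index=pd.Index(["cog_memory_1", "mot_pace_1"], name="variable_id"),
    )
    cov = pd.DataFrame(
        {"age": np.linspace(30, 70, n), "gender": np.tile([0.0, 1.0], n // 2)},
        index=table.index,
    )
    with pytest.raises(EmptyAnalysisError):
        run_pipeline(table, meta, cov)
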