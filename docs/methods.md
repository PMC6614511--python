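# Methods

## Statistical model and procedure

The pipeline tests for monotone association between a cognitive block and a
motor block, conditional on age and gender, in a cross-sectional cohort.

**Partial Spearman correlation.** For variables x and y with covariate
matrix C (age in years, gender as a 0/1 indicator), both variables are
converted to average ranks over the pairwise-complete cases, each rank
vector is residualized on an intercept plus C by ordinary least squares, and
ρ is the Pearson correlation of the residuals. The two-sided p-value uses
t = ρ·√((n−k−2)/(1−ρ²)) on n−k−2 degrees of freedom (k = 2 covariates). At
the cohort sizes this package targets (n ≈ 100–500) the t approximation is
accurate; no exact permutation option is provided. Note that the covariates
enter *unranked*: the construction is "rank the outcomes, adjust linearly".
Implementations that also rank the covariates (e.g. R's `ppcor`, or
`pingouin.partial_corr(method="spearman")`) define a slightly different
estimand; the test suite cross-checks our machinery against pingouin by
feeding it pre-ranked covariates so both routes agree to machine precision.
Pairs with fewer than k+3 complete cases, or with a degenerate residual,
propagate p = 1 (conservative) rather than aborting their family, keeping
family sizes constant.

**Hypothesis families and two-stage testing.** One family per (motor
variable, cognitive domain) pair; with the default inventory of 21 motor
variables and 4 cognitive domains this yields 84 families, each containing
that domain's 5–11 correlations. Stage one computes the Simes combination
min_i m·p_(i)/i per family and selects families strictly below α = 0.05
("smaller than", so a Simes p of exactly 0.05 is not selected). Stage two
applies the BH step-up separately within each selected family at q = 0.05,
with adjusted p-values monotone-enforced so that "adjusted p ≤ q" and
"rejected" coincide; BH ties are broken by a stable sort (p, then variable
id), which cannot change the rejection set. Plain per-family BH after
selection does **not** control the FDR over occasionally-selected null
families (the selective-inference effect); a hierarchical correction that
scales the within-family level by (#selected/#families) is available via
`selection_adjusted_bh=True` but is off by default, matching the plain
procedure. What the default procedure *does* control — and what the
acceptance suite measures — is the within-family FDR in families whose
selection is near-certain.

## Preprocessing rules

**Transform catalog.** {identity, log(x+s), √(x+s), 1/(x+s), Box–Cox,
rank-inverse-normal (Blom offsets, Φ⁻¹((r−3/8)/(n+1/4)))}, with automatic
shift s = 1 − min(x) whenever positivity (or non-negativity for √) fails,
and Box–Cox λ chosen by profile likelihood on the coarse grid −2(0.25)2.
Selection maximizes the Shapiro–Wilk W; ties break by catalog order, making
the choice fully deterministic. The reciprocal is order-reversing and is
multiplied by −1 after transformation, restoring the original ordering — so
every automatically selected transform is rank-preserving, and downstream
Spearman statistics are invariant to the choice. A per-variable override in
the metadata `transform` column applies a named catalog member verbatim.

A practical consequence: the rank-inverse-normal map produces exact normal
scores and therefore nearly always wins the Shapiro–Wilk contest, and it
maps any outlier to a bounded extreme score, so on auto-transformed data the
downstream outlier rule rarely fires. This is harmless for the rank-based
association stage (an extreme rank is just a rank) and the outlier test is
validated directly against oracles; users who want active outlier removal on
a particular variable should pin a parametric transform via the override.

**Outlier rule.** Per variable, OLS of the (transformed) values on intercept
+ age + gender; externally studentized residuals via the hat-matrix identity
t_i = r_i·√((n−p−1)/(n−p−r_i²)); two-sided t tail on n−k−2 df; Bonferroni
multiplication by n; a cell is flagged iff the Bonferroni p is strictly
below 4/n. The 4/n cutoff is used as printed even though it is more lenient
than the conventional 0.05; with n = 124 it equals 0.032. Detection is a
single pass (no iterative re-detection) and removal is cell-wise — the
flagged cell becomes missing, the subject's other variables survive — which
pairs with the pairwise-complete correlation design. Degenerate designs
raise a rank error; a point whose removal zeroes the residual variance gets
t = ±∞ and is always flagged.

**Limited-range filter.** A variable is excluded iff the proportion of
non-missing observations equal to its modal value is ≥ 0.80 (inclusive at
the boundary: 8 identical values out of 10 excludes; 98 of 124 ≈ 0.79
does not). All-missing variables are excluded with modal proportion 1.
Exclusion is evaluated on the cleaned (post-outlier) values; since catalog
transforms are injective the proportion is unaffected by the transform step.

## Synthetic cohort generator

The generator emulates the cohort the analysis assumes rather than any
particular dataset: n = 124 subjects by default, age truncated-normal
(mean 61.51, SD 11.90) on 27–80, gender Bernoulli(0.565) with 1 = female,
and a variable inventory of 30 cognitive measures (executive function 11,
processing speed 7, memory 5, language 7) and 21 motor measures
(variability 4, transition 4, turn 2, asymmetry 4, rhythm 2, pace 5).

Every variable receives a standardized age slope per decade (default −0.25
for both blocks, i.e. performance declines with age) and a gender mean shift
(default 0.2), so age/gender confound both blocks by construction. Planted
cross-block links add a shared standard-normal latent factor to both
members' residual components with loading √r, giving partial correlation r
given the covariates exactly; each variable may carry at most one link so
the variance bookkeeping stays exact. Link magnitudes are specified on the
Spearman scale and converted to the Gaussian loading via r = 2·sin(πρ/6)
(the Gaussian-copula identity), so the *population rank* correlation equals
the configured value. Marginal distortions (exp, cubic, logistic) are
strictly monotone, preserving all ranks. Injected outliers displace single
cells' residual components away from zero by 6 residual SD (default), so a
covariate-adjusted rule must find them; near-constant variables place one
value on exactly round(degenerate_prop·n) subjects. Default degenerate_prop
is 0.85, above the 0.80 exclusion boundary at n = 124 (0.80 itself yields
99/124 ≈ 0.798 and survives the filter — an instructive boundary case the
tests exercise). Missingness is off by default; an optional fraction drops
cells completely at random.

What the generator does **not** emulate: the raw accelerometer signal
processing that produces motor metrics, realistic within-block correlation
among measures of one domain (non-linked variables are conditionally
independent), longitudinal structure, and informative missingness. Passing
tests therefore demonstrate the *procedure's* operating characteristics
under its stated assumptions, not robustness to dependent hypotheses —
though Simes and BH are both known to remain valid under positive
dependence.

## Monte-Carlo harness and problem sizes

Operating characteristics are estimated from independent replicates driven
by `numpy.random.SeedSequence.spawn`, so one integer seed reproduces an
entire experiment. Conventions: a replicate with no rejections contributes
false-discovery proportion 0 (the standard FDR expectation convention; the
count of rejecting replicates is reported alongside); power is the fraction
of planted links appearing in the report; `signal_family_fdr` is the
within-family V/R averaged over signal-bearing families and replicates — the
quantity plain within-family BH controls when those families are selected
with probability ≈ 1 — while `empirical_fdr` pools all reported pairs and is
inflated by selection, as expected for the unadjusted procedure.

Default problem sizes were chosen so a full validation runs on a laptop in
minutes: the Simes level check uses 500–1000 replicates of family sizes
3–14; the FDR and recovery checks use 200–500 full-pipeline replicates of a
6-cognitive × 6-motor inventory at n = 500 with links of 0.5 (six links for
the FDR scenario — every motor variable in exactly one signal family — and
three for recovery). 500 replicates put the Monte-Carlo SE of a 0.05-level
rate near 0.01.

## Known limitations

- P-values rely on the t approximation for rank statistics; for n below ~30
  with heavy ties they are approximate.
- The transformation stage is a deterministic stand-in for what is, in
  practice, often a judgment call; it is deliberately rank-neutral.
- The default procedure's report-level FDR is not controlled across
  rarely-selected null families (see above); enable
  `selection_adjusted_bh` for the corrected variant.
- Gender is modeled as a binary covariate because the adjustment it feeds
  is a two-level linear term.
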