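"""Quantify the procedure's error rates by Monte Carlo.

Runs the full pipeline over independent synthetic replicates and scores the
reports against the generator's truth: family selection rate, within-family
false-discovery proportion and power.  A null scenario checks the Simes
screen's level; a signal scenario checks BH's FDR control and power.
(Replicate counts are kept small here so the example runs in seconds; the
test suite uses 500.)
"""

from cogmob import estimate_operating_characteristics
from cogmob.simulate import null_scenario, signal_scenario

oc_null = estimate_operating_characteristics(
    null_scenario(), n_replicates=200, seed=1
)
print("global null scenario (no planted links):")
print(f"  per-family selection rate: {oc_null.mean_selection_rate:.3f} "
      f"(target level 0.05, MC SE {oc_null.monte_carlo_se['mean_selection_rate']:.3f})")

oc_sig = estimate_operating_characteristics(
    signal_scenario(n_subjects=500), n_replicates=200, seed=2
)
print("strong-signal scenario (six 0.5 links at n=500):")
print(f"  power (planted links reported): {oc_sig.power:.3f}")
print(f"  within-signal-family FDP: {oc_sig.signal_family_fdr:.4f} (q = 0.05)")
print(f"  report-level FDR: {oc_sig.empirical_fdr:.4f}")
print()
print("The selection rate matches the Simes level, and the within-family FDP")
print("stays below q because BH is applied separately inside each reliably")
print("selected family.")
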