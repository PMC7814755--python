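"""Rank regression of tract integrity on self-reported pain.

Draws a 100-subject cohort with a pain-coupled tract (population Spearman
~0.3) and an uncoupled control tract, fits the covariate-adjusted rank
regression with Freedman-Lane permutation inference, and applies Bonferroni
and Benjamini-Hochberg control.
"""

from paintract import StatsConfig, adjust, generate_cohort, rank_regression
from paintract.phantom import DEFAULT_COUPLING_BETA
from paintract.stats import results_frame

cohort = generate_cohort(100, coupling={"AP": DEFAULT_COUPLING_BETA, "PN": 0.0},
                         seed=0)
cfg = StatsConfig(n_permutations=9_999, perm_seed=0)
results = [rank_regression(cohort, t, cfg) for t in ("AP", "PN")]
bon, fdr, log10_thr = adjust(results, cfg)

print(results_frame(results).to_string(index=False))
print(f"\nFDR decision boundary: log10(p) = {log10_thr:.4f}")
print("-> AP (coupled) shows a positive standardized slope with a small")
print("   permutation p; PN (control) does not survive either correction.")
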