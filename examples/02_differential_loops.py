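"""Differential chromatin looping between two cell types, with a label-shuffle check.

Simulates a 40-sample cohort where 10% of 2,000 loops differ between cell
types, runs the per-loop OLS differential analysis with sex as a covariate,
then repeats it on shuffled cell-type labels to show the pipeline's null is
clean.  A single held-out 'cell line' sample is screened for outlier loops.
"""

import numpy as np

from loopscape.diffstats import cohort_outlier_scan, ols_differential, permutation_null_check
from loopscape.synthetic_data import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=8, n_samples=40, n_loop_features=2000,
                       group_effect_fraction=0.1, group_effect_size=1.5,
                       n_genes=10, n_peaks=10, n_variants=5)
cohort = simulate_cohort(cfg)
meta = cohort.metadata.table

res = ols_differential(cohort.loop_strengths, meta["cell_type"], meta[["sex"]])
n_sig = int((res["q"] < 0.1).sum())
n_true = int((cohort.truth["loops"]["group_effect"] != 0).sum())
print(f"differential loops at FDR < 0.1: {n_sig} (of {n_true} with a true effect)")

counts = permutation_null_check(cohort.loop_strengths, meta["cell_type"],
                                meta[["sex"]], n_shuffles=3, seed=1)
print(f"significant loops after label shuffles: {counts}")
print("  -> near-zero counts mean the significant set is not an artifact")

query = cohort.loop_strengths.iloc[:, 0] + np.where(
    np.arange(2000) < 5, 6.0, 0.0)  # spike 5 loops in a pseudo cell line
query.name = "cell_line"
calls = cohort_outlier_scan(cohort.loop_strengths.iloc[:, 1:], query)
spiked = calls.set_index("feature_id")["flagged"].iloc[:5].sum()
print(f"outlier loops in the cell line (p < 0.05): {int(calls['flagged'].sum())} "
      f"of 2000; all {int(spiked)} of 5 spiked loops flagged")
print("  -> single-sample z-score screen: the unadjusted p < 0.05 rule flags")
print("     ~5% of unremarkable loops too, so it ranks candidates rather than")
print("     controlling an error rate")
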