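"""Correlate loop strength with gene expression by positional pair class.

Builds a small cohort where a gene whose TSS sits inside a loop anchor is
causally coupled to that loop's strength, then shows that anchor-overlap
pairs correlate more strongly than distal background pairs.
"""

import numpy as np
import pandas as pd

from loopscape.core_io import GenomicInterval, Loop
from loopscape.pairing_correlation import classify_loop_feature_pair, correlate_loops_with_features

rng = np.random.default_rng(12)
n = 50
samples = [f"S{k}" for k in range(n)]
loop = Loop("L", GenomicInterval("chr1", 1_000_000, 1_010_000),
            GenomicInterval("chr1", 1_500_000, 1_510_000))

latent = rng.normal(0, 1, n)
strengths = pd.DataFrame({s: [30 + 5 * latent[k]] for k, s in enumerate(samples)},
                         index=["L"])
expr = pd.DataFrame(
    {s: [40 + 5 * latent[k] + rng.normal(), 40 + rng.normal(), 40 + rng.normal()]
     for k, s in enumerate(samples)},
    index=["anchor_gene", "spanned_gene", "distal_gene"],
)
tss = {"anchor_gene": 1_005_000, "spanned_gene": 1_250_000,
       "distal_gene": 1_510_000 + 3_000_000}

for gene, point in tss.items():
    print(f"{gene}: class = {classify_loop_feature_pair(loop, point)}")

out = correlate_loops_with_features(strengths, [loop], expr, tss,
                                    feature_kind="gene")
print("\nPearson correlation of expression with loop strength:")
print(out[["feature_id", "pair_class", "r", "p"]].round(3).to_string(index=False))
print("  -> the causally coupled anchor gene correlates strongly; background")
print("     genes inside or far from the span do not")
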