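"""LD r^2 against a target variant and expression heatmap preparation.

Uses the synthetic bundle's genotype dosage and expression matrices.
"""

import numpy as np

from snpannot import FixtureConfig, expression_heatmap_prep, generate_bundle, ld_r2

bundle, truth = generate_bundle(FixtureConfig(seed=5))

target = sorted(truth.tier)[0]
res = ld_r2(bundle.genotypes, target)
r2 = {k: v for k, v in res.r2.items() if not np.isnan(v)}
top = sorted(r2.items(), key=lambda kv: -kv[1])[:3]
print(f"LD against {target} over {len(bundle.genotypes)} samples:")
for rsid, val in top:
    print(f"  {rsid}: r^2 = {val:.3f}")
print("(the target correlates perfectly with itself; unlinked synthetic")
print(" variants have r^2 near 0)")

scaled, gene_order, tissue_order, flagged = expression_heatmap_prep(
    bundle.expression.iloc[:12]
)
print(f"\nscaled {scaled.shape[0]} genes x {scaled.shape[1]} tissues; "
      f"{len(flagged)} constant genes flagged")
print("first 5 genes in clustered display order:", gene_order[:5])
print("tissue display order:", tissue_order)
print("\nRows are z-scaled per gene; row/column orders come from average-")
print("linkage hierarchical clustering, ready for heatmap rendering.")
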