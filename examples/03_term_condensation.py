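"""Condense a redundant set of ontology terms.

Computes information content and Lin similarities over a synthetic ontology,
clusters the terms with Ward-D2 + dynamic tree cut, masks redundant terms,
and prints per-cluster word frequencies.
"""

import numpy as np

from snpannot import (
    FixtureConfig,
    cluster_wordclouds,
    dynamic_cut,
    generate_bundle,
    hclust_ward,
    information_content,
    revigo_reduce,
    similarity_matrix,
)

bundle, _ = generate_bundle(FixtureConfig(seed=5))
ont = bundle.ontology
ic = information_content(ont, bundle.annotations)

terms = sorted(t for t in ont.terms
               if ont.namespace[t] == "BP" and t in ic and ic[t] > 0)[:20]
sim = similarity_matrix(terms, ic, ont)
dist = 1.0 - sim
np.fill_diagonal(dist, 0.0)

labels = dynamic_cut(hclust_ward(dist), sim, min_cluster_size=3)
print(f"{len(terms)} terms -> {len(set(labels))} clusters (dynamic tree cut)")

pvals = list(np.linspace(1e-6, 0.01, len(terms)))
red = revigo_reduce(terms, sim, pvals, cutoff=0.7)
print(f"redundancy masking kept {len(red.kept)} terms, masked {len(red.masked)}")

words = cluster_wordclouds({t: ont.names[t] for t in terms},
                           {t: int(l) for t, l in zip(terms, labels)})
for cluster, freq in words.items():
    top = list(freq.items())[:3]
    print(f"cluster {cluster}: top words {top}")
print("\nClusters group semantically similar terms (high Lin similarity);")
print("the word counts summarize what each cluster is about.")
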