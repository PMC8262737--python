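"""Annotate a SNP set end to end against a synthetic resource bundle.

Builds a bundle with planted ground truth, writes it to disk, runs the full
pipeline (tiered mapping -> trait fractions -> SV proximity -> sampling-
corrected enrichment -> term condensation) and prints the headline tables.
"""

import tempfile
from pathlib import Path

import pandas as pd

from snpannot import FixtureConfig, RunConfig, generate_bundle, run_annotation, write_bundle

tmp = Path(tempfile.mkdtemp())
cfg = FixtureConfig(seed=3)
bundle, truth = generate_bundle(cfg)
write_bundle(bundle, tmp / "bundle")

snp_file = tmp / "snps.txt"
snp_file.write_text("\n".join(sorted(truth.tier)) + "\n")

out = run_annotation(RunConfig(
    input_path=snp_file, bundle_path=tmp / "bundle", output_dir=tmp / "out",
    tissues=cfg.eqtl_tissues, sources=("GO_BP", "REACT"), iterations=200, seed=7,
))

summary = pd.read_csv(out / "summary.tsv", sep="\t")
print("Mapping summary (how each variant was linked to genes):")
print(summary.to_string(index=False))

traits = pd.read_csv(out / "traits.tsv", sep="\t")
print("\nTop catalog traits (fraction of input SNPs supporting each trait,")
print("averaged over the gene-sampling iterations):")
print(traits.head(3).to_string(index=False))

enr = pd.read_csv(out / "enrichment_GO_BP.tsv", sep="\t", comment="#")
print("\nTop enriched ontology terms (sampling-averaged hypergeometric P, BH q):")
print(enr.head(3)[["term", "name", "mean_p", "q_value", "mean_overlap"]].to_string(index=False))
print(f"\nPlanted enriched terms: {sorted(truth.planted_terms['GO_BP'])}")
print("A small mean_p for the planted terms shows the sampling-corrected test")
print("recovers the signal the generator buried in the mapped genes.")
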