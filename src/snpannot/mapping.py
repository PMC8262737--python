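"""Tiered variant-to-gene mapping.

A variant is linked to likely affected genes by the first rule that yields
at least one gene, in strict precedence order:

1. **coding** — the variant carries a coding-consequence record (matched by
   rsID first, then by exact chromosome + position);
2. **eqtl** — the variant is a significant eQTL in one of the selected
   tissues; the mapped genes are the union over those tissues;
3. **positional** — genes within an expanding window around the variant,
   scanning d = 50, 100, ..., 500 kb and stopping at the first d with a hit;
   all genes within that d are returned.

If no gene lies within 500 kb the variant is *unmapped* — a value, not an
error; unmapped variants stay in SV-proximity and direct-rsID catalog
lookups but are excluded from gene-based stages.

Distance is to the nearest gene-body boundary (0 inside the body),
strand-agnostic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import ResourceBundle, Variant

WINDOW_STEPS_KB = tuple(range(50, 501, 50))


@dataclass
class VariantGeneMapping:
    variant: Variant
    tier: str  # coding | eqtl | positional | unmapped
    genes: tuple[str, ...]  # sorted, deduplicated
    window_kb: int | None = None  # positional tier only
    tissues_used: tuple[str, ...] = ()


@dataclass
class MappingSummary:
    tier_counts: dict[str, int]
    genes_per_variant: dict[int, int]  # histogram: #genes -> #variants
    total_distinct_genes: int


def gene_distance(variant: Variant, gene_chrom: str, gene_start: int, gene_end: int) -> int:
    """Distance from a variant to a gene body: 0 inside, else nearest boundary.

    Strand-agnostic; raises if the gene is on a different chromosome
    (callers filter by chromosome first).
    """
    if gene_chrom != variant.chrom:
        raise ConfigError(
            f"gene on {gene_chrom} compared with variant on {variant.chrom}"
        )
    if gene_start <= variant.pos <= gene_end:
        return 0
    return min(abs(variant.pos - gene_start), abs(variant.pos - gene_end))


class _GeneIndex:
    """Per-chromosome arrays of gene coordinates for vectorized distance scans."""

    def __init__(self, genes: pd.DataFrame):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in genes.groupby("chrom"):
            self.by_chrom[chrom] = (
                sub["start"].to_numpy(int),
                sub["end"].to_numpy(int),
                sub["symbol"].to_numpy(object),
            )

    def distances(self, variant: Variant) -> tuple[np.ndarray, np.ndarray]:
        entry = self.by_chrom.get(variant.chrom)
        if entry is None:
            return np.empty(0, int), np.empty(0, object)
        starts, ends, symbols = entry
        inside = (starts <= variant.pos) & (variant.pos <= ends)
        d = np.minimum(np.abs(variant.pos - starts), np.abs(variant.pos - ends))
        d[inside] = 0
        return d, symbols


def map_variant(
    variant: Variant,
    bundle: ResourceBundle,
    tissues: list[str],
    _index: _GeneIndex | None = None,
) -> VariantGeneMapping:
    """Map one variant through the coding -> eQTL -> positional cascade."""
    if not tissues:
        raise ConfigError("at least one eQTL tissue must be selected")
    # tier i: coding, by rsid then by chrom+pos
    coding = bundle.coding
    if len(coding):
        hit = coding[(coding["rsid"] == variant.rsid) & (coding["consequence_class"] == "coding")]
        if hit.empty:
            hit = coding[
                (coding["chrom"] == variant.chrom)
                & (coding["pos"] == variant.pos)
                & (coding["consequence_class"] == "coding")
            ]
        if not hit.empty:
            return VariantGeneMapping(
                variant=variant, tier="coding", genes=tuple(sorted(set(hit["gene"])))
            )
    # tier ii: eQTL union over selected tissues
    eq = bundle.eqtls
    if len(eq):
        tset = set(tissues)
        hit = eq[(eq["rsid"] == variant.rsid) & (eq["tissue"].isin(tset))]
        if not hit.empty:
            return VariantGeneMapping(
                variant=variant,
                tier="eqtl",
                genes=tuple(sorted(set(hit["gene"]))),
                tissues_used=tuple(sorted(set(hit["tissue"]))),
            )
    # tier iii: expanding positional windows
    index = _index if _index is not None else _GeneIndex(bundle.genes)
    d, symbols = index.distances(variant)
    if len(d):
        dmin = int(d.min())
        for window_kb in WINDOW_STEPS_KB:
            if dmin <= window_kb * 1000:
                genes = tuple(sorted(set(symbols[d <= window_kb * 1000])))
                return VariantGeneMapping(
                    variant=variant, tier="positional", genes=genes, window_kb=window_kb
                )
    return VariantGeneMapping(variant=variant, tier="unmapped", genes=())


def map_all(
    variants: list[Variant], bundle: ResourceBundle, tissues: list[str]
) -> tuple[list[VariantGeneMapping], MappingSummary]:
    """Map every variant (input order preserved) and summarize tier counts."""
    if not variants:
        raise ConfigError("map_all requires at least one variant")
    index = _GeneIndex(bundle.genes)
    mappings = [map_variant(v, bundle, tissues, _index=index) for v in variants]
    tier_counts = Counter(m.tier for m in mappings)
    hist = Counter(len(m.genes) for m in mappings)
    distinct = set()
    for m in mappings:
        distinct.update(m.genes)
    summary = MappingSummary(
        tier_counts=dict(sorted(tier_counts.items())),
        genes_per_variant=dict(sorted(hist.items())),
        total_distinct_genes=len(distinct),
    )
    return mappings, summary


def mappings_frame(mappings: list[VariantGeneMapping]) -> pd.DataFrame:
    """Tabular view used by the report writers (mapping.tsv)."""
    rows = [
        {
            "variant": m.variant.rsid,
            "chrom": m.variant.chrom,
            "pos": m.variant.pos,
            "tier": m.tier,
            "window_kb": "" if m.window_kb is None else m.window_kb,
            "genes": ",".join(m.genes),
            "tissues_used": ",".join(m.tissues_used),
        }
        for m in mappings
    ]
    return pd.DataFrame(rows)
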