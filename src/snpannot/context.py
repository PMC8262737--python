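"""Trait-catalog overlap with sampling correction, and SV proximity.

A variant that maps to several genes would otherwise over-contribute to
gene-mediated trait support, so trait fractions are estimated by repeatedly
(default 500 iterations) sampling *one* gene per variant and averaging the
per-iteration fractions.  Direct rsID support does not depend on the sample
and is counted identically in every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import Variant
from .mapping import VariantGeneMapping

DEFAULT_SV_WINDOW_BP = 10_000


@dataclass
class TraitFraction:
    trait: str
    mean_fraction: float
    sd_fraction: float
    supporting_snps_direct: int


@dataclass
class SvOverlap:
    variant: Variant
    sv_index: int  # row index into the bundle's SV table
    distance: int  # bp from variant to the SV interval, 0 if it spans the variant


def sample_gene_assignments(
    mappings: list[VariantGeneMapping], iterations: int, seed: int
) -> list[dict[str, str]]:
    """Draw one gene per variant per iteration, uniformly over its mapped set.

    Returns one ``{rsid: gene}`` dict per iteration.  The stream is the
    shared sampling stream: enrichment and trait fractions called with the
    same seed see the same draws.
    """
    if iterations < 1:
        raise ConfigError("iterations must be >= 1")
    empty = [m.variant.rsid for m in mappings if not m.genes]
    if empty:
        raise ConfigError(f"cannot sample genes for unmapped variants: {empty}")
    rng = np.random.default_rng([seed % (2**31), 101])
    gene_lists = [m.genes for m in mappings]  # already sorted tuples
    rsids = [m.variant.rsid for m in mappings]
    out = []
    for _ in range(iterations):
        out.append({
            rsid: genes[int(rng.integers(0, len(genes)))] if len(genes) > 1 else genes[0]
            for rsid, genes in zip(rsids, gene_lists)
        })
    return out


def trait_fractions(
    variants: list[Variant],
    mappings: list[VariantGeneMapping],
    catalog: pd.DataFrame,
    iterations: int = 500,
    seed: int = 0,
) -> list[TraitFraction]:
    """Fraction of input SNPs supporting each catalog trait, sampling-corrected.

    Per iteration a SNP supports a trait if its rsID appears in the catalog
    for that trait, OR its sampled gene is among the trait's reported genes
    (the two routes are OR-ed; a SNP counts once).  The denominator is the
    full input SNP count, including unmapped variants (which can still
    support traits directly).  Traits with mean fraction 0 are omitted;
    results are sorted by descending mean fraction, ties by trait name.
    """
    n = len(variants)
    if n == 0:
        raise ConfigError("trait_fractions requires at least one variant")

    trait_rsids: dict[str, set[str]] = {}
    trait_genes: dict[str, set[str]] = {}
    for row in catalog.itertuples(index=False):
        trait_rsids.setdefault(row.trait, set()).add(row.rsid)
        trait_genes.setdefault(row.trait, set()).update(row.reported_genes)
    traits = sorted(trait_rsids)

    direct: dict[str, set[str]] = {
        t: {v.rsid for v in variants if v.rsid in trait_rsids[t]} for t in traits
    }

    mapped = [m for m in mappings if m.genes]
    samples = sample_gene_assignments(mapped, iterations, seed) if mapped else [
        {} for _ in range(iterations)
    ]

    # integer supporter counts per iteration: keeps the degenerate
    # (single-gene) case exactly seed- and iteration-count-invariant
    counts = {t: np.zeros(iterations, dtype=np.int64) for t in traits}
    for it, sample in enumerate(samples):
        for t in traits:
            supporters = set(direct[t])
            genes = trait_genes[t]
            if genes:
                supporters.update(r for r, g in sample.items() if g in genes)
            counts[t][it] = len(supporters)

    out = []
    for t in traits:
        c = counts[t]
        if not c.any():
            continue
        out.append(TraitFraction(
            trait=t,
            mean_fraction=float(c.mean()) / n,
            sd_fraction=float(c.std(ddof=0)) / n,
            supporting_snps_direct=len(direct[t]),
        ))
    out.sort(key=lambda r: (-r.mean_fraction, r.trait))
    return out


def sv_proximity(
    variants: list[Variant],
    svs: pd.DataFrame,
    window_bp: int = DEFAULT_SV_WINDOW_BP,
) -> list[SvOverlap]:
    """All (variant, SV) pairs whose closed intervals intersect within the window.

    An SV is reported for a variant at position ``pos`` iff
    ``sv.start <= pos + window_bp and sv.end >= pos - window_bp``.
    """
    if window_bp < 0:
        raise ConfigError("window_bp must be >= 0")
    out = []
    for v in variants:
        sub = svs[svs["chrom"] == v.chrom]
        for idx, sv in sub.iterrows():
            if sv.start <= v.pos + window_bp and sv.end >= v.pos - window_bp:
                if sv.start <= v.pos <= sv.end:
                    dist = 0
                else:
                    dist = int(min(abs(v.pos - sv.start), abs(v.pos - sv.end)))
                out.append(SvOverlap(variant=v, sv_index=int(idx), distance=dist))
    return out


def trait_fractions_frame(fractions: list[TraitFraction]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "trait": f.trait,
            "mean_fraction": round(f.mean_fraction, 6),
            "sd_fraction": round(f.sd_fraction, 6),
            "supporting_snps_direct": f.supporting_snps_direct,
        }
        for f in fractions
    ])


def sv_overlap_frame(
    overlaps: list[SvOverlap], svs: pd.DataFrame,
    mapped_genes: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    rows = []
    for o in overlaps:
        sv = svs.loc[o.sv_index]
        rows.append({
            "variant": o.variant.rsid,
            "chrom": o.variant.chrom,
            "pos": o.variant.pos,
            "sv_start": int(sv.start),
            "sv_end": int(sv.end),
            "sv_type": sv.sv_type,
            "max_allele_size_diff": int(sv.max_allele_size_diff),
            "study": sv.study,
            "distance": o.distance,
            "mapped_genes": ",".join((mapped_genes or {}).get(o.variant.rsid, ())),
        })
    return pd.DataFrame(rows)
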