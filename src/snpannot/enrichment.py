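"""Sampling-corrected gene-set over-representation analysis.

Each iteration draws one gene per variant (the same sampling stream used by
the trait-fraction analysis), deduplicates the draw into a query set, and
tests every term of a gene-set source with a one-sided hypergeometric
upper-tail test.  Per-term P-values are averaged arithmetically across
iterations; Benjamini-Hochberg FDR is applied once, to the averaged
values, per source.  The testing universe is all genes appearing in the
source's annotation corpus (the union of its term gene sets), mirroring the
"annotated genes" default of standard over-representation services.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .exceptions import ConfigError
from .io import GeneSetSource
from .mapping import VariantGeneMapping
from .context import sample_gene_assignments


@dataclass
class EnrichmentConfig:
    iterations: int = 500
    seed: int = 0
    min_term_size: int = 3
    max_term_size: int = 1000
    fdr_plot_threshold: float = 0.10

    def validate(self) -> None:
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if not 1 <= self.min_term_size <= self.max_term_size:
            raise ConfigError("term size bounds must satisfy 1 <= min <= max")
        if not 0 < self.fdr_plot_threshold <= 1:
            raise ConfigError("fdr_plot_threshold must be in (0, 1]")


@dataclass
class EnrichmentResult:
    source: str
    term: str
    term_name: str
    mean_p: float
    q_value: float
    mean_overlap: float
    term_size: int
    query_size: float  # mean per-iteration deduplicated query size
    universe_size: int


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = universe size, K = term size, n = query size, k = observed overlap.
    Computed in log space via the survival function; returns a value in
    (0, 1] (k = 0 gives exactly 1).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ConfigError(
            f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich_once(
    gene_set: set[str],
    source: GeneSetSource,
    universe: set[str],
    terms: list[str] | None = None,
) -> dict[str, tuple[int, float]]:
    """Per-term (overlap, p) for one deduplicated query gene set.

    ``gene_set`` must be a subset of the universe; ``terms`` restricts to a
    pre-filtered term list (size bounds applied by the caller).
    """
    if not universe:
        raise ConfigError("empty testing universe")
    extra = gene_set - universe
    if extra:
        raise ConfigError(f"query genes outside the universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(gene_set)
    out = {}
    for term in (terms if terms is not None else sorted(source.term_to_genes)):
        tg = source.term_to_genes[term] & universe
        k = len(gene_set & tg)
        out[term] = (k, hypergeom_upper_tail(k, len(tg), n, N))
    return out


def bh_fdr(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotone enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("P-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def sampled_enrichment(
    mappings: list[VariantGeneMapping],
    source: GeneSetSource,
    config: EnrichmentConfig,
    term_names: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Run the sampling-corrected over-representation analysis for one source.

    Results are sorted by ascending mean P-value, ties broken by term id.
    """
    config.validate()
    mapped = [m for m in mappings if m.genes]
    if not mapped:
        raise ConfigError("all variants are unmapped; nothing to enrich")

    universe: set[str] = set()
    for genes in source.term_to_genes.values():
        universe.update(genes)
    terms = sorted(
        t for t, g in source.term_to_genes.items()
        if config.min_term_size <= len(g & universe) <= config.max_term_size
    )
    if not terms:
        raise ConfigError("no terms survive the size bounds")

    samples = sample_gene_assignments(mapped, config.iterations, config.seed)
    # aggregate over *distinct* sampled gene sets: faster, and exact when the
    # sampling degenerates (all single-gene variants -> one distinct set)
    weights: dict[frozenset, int] = {}
    for sample in samples:
        sig = frozenset(sample.values()) & frozenset(universe)
        weights[sig] = weights.get(sig, 0) + 1
    per_set = {sig: enrich_once(set(sig), source, universe, terms=terms)
               for sig in weights}

    it = config.iterations
    if len(weights) == 1:
        (res,) = per_set.values()
        mean_p = np.array([res[t][1] for t in terms])
        mean_k = {t: float(res[t][0]) for t in terms}
        n_sum = float(len(next(iter(weights)))) * it
    else:
        p_sum = {t: 0.0 for t in terms}
        k_sum = {t: 0.0 for t in terms}
        n_sum = 0.0
        for sig, w in weights.items():
            n_sum += w * len(sig)
            for t, (k, p) in per_set[sig].items():
                p_sum[t] += w * p
                k_sum[t] += w * k
        mean_p = np.array([p_sum[t] / it for t in terms])
        mean_k = {t: k_sum[t] / it for t in terms}
    qvals = bh_fdr(mean_p)
    names = term_names or {}
    results = [
        EnrichmentResult(
            source=source.source_name,
            term=t,
            term_name=names.get(t, t),
            mean_p=float(mean_p[i]),
            q_value=float(qvals[i]),
            mean_overlap=mean_k[t],
            term_size=len(source.term_to_genes[t] & universe),
            query_size=n_sum / it,
            universe_size=len(universe),
        )
        for i, t in enumerate(terms)
    ]
    results.sort(key=lambda r: (r.mean_p, r.term))
    return results
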