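import itertools
import math

import numpy as np
import pytest

from snpannot import (
    EnrichmentConfig,
    Variant,
    VariantGeneMapping,
    bh_fdr,
    enrich_once,
    hypergeom_upper_tail,
    sampled_enrichment,
)
from snpannot.io import GeneSetSource
from snpannot.exceptions import ConfigError


def upper_tail_by_enumeration(k, K, n, N):
    """Exact P(X >= k) by summing the hypergeometric pmf via binomials."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_forced_full_draw(self):
        assert hypergeom_upper_tail(3, 3, 3, 3) == pytest.approx(1.0)

    def test_known_value(self):
        # N=10, K=5, n=4, k=4: only C(5,4) of C(10,4) draws qualify = 5/210
        assert hypergeom_upper_tail(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-9)

    def test_matches_enumeration_all_small_instances(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(K, n) + 1):
                        expected = upper_tail_by_enumeration(k, K, n, N)
                        got = hypergeom_upper_tail(k, K, n, N)
                        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (
                            k, K, n, N
                        )

    def test_bounds_violation_fatal(self):
        with pytest.raises(ConfigError):
            hypergeom_upper_tail(5, 4, 4, 10)
        with pytest.raises(ConfigError):
            hypergeom_upper_tail(1, 11, 4, 10)


class TestEnrichOnce:
    SOURCE = GeneSetSource("S", {
        "t1": frozenset({"A", "B", "C"}),
        "t2": frozenset({"D", "E"}),
        "t3": frozenset({"A", "D", "F", "G"}),
    })
    UNIVERSE = frozenset("ABCDEFG")

    def test_disjoint_term_p_is_one(self):
        res = enrich_once({"A", "B"}, self.SOURCE, set(self.UNIVERSE))
        assert res["t2"] == (0, 1.0)

    def test_exact_term_match_is_most_significant(self):
        res = enrich_once({"A", "B", "C"}, self.SOURCE, set(self.UNIVERSE))
        assert res["t1"][0] == 3
        assert res["t1"][1] == min(p for _, p in res.values())
        assert res["t1"][1] == pytest.approx(
            upper_tail_by_enumeration(3, 3, 3, 7), rel=1e-9
        )

    def test_query_outside_universe_fatal(self):
        with pytest.raises(ConfigError):
            enrich_once({"Z"}, self.SOURCE, set(self.UNIVERSE))

    def test_empty_universe_fatal(self):
        with pytest.raises(ConfigError):
            enrich_once(set(), self.SOURCE, set())


class TestBhFdr:
    def test_hand_computed_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passthrough(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, size=50)
        q = bh_fdr(p)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_matches_reference_step_up_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(1e-8, 1, size=int(rng.integers(1, 40)))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_invalid_p_fatal(self):
        with pytest.raises(ConfigError):
            bh_fdr([0.5, 0.0])


def mk_mapping(rsid, genes):
    return VariantGeneMapping(
        variant=Variant(rsid, "1", 1000), tier="eqtl", genes=tuple(sorted(genes))
    )


class TestSampledEnrichment:
    def test_single_gene_variants_equal_single_shot(self, bundle):
        source = bundle.gene_set_sources["GO_BP"]
        universe = set().union(*source.term_to_genes.values())
        genes = sorted(universe)[:15]
        mappings = [mk_mapping(f"rs{i}", [g]) for i, g in enumerate(genes)]
        cfg = EnrichmentConfig(iterations=5, seed=1, min_term_size=1)
        res_a = sampled_enrichment(mappings, source, cfg)
        cfg_b = EnrichmentConfig(iterations=3, seed=777, min_term_size=1)
        res_b = sampled_enrichment(mappings, source, cfg_b)
        # degenerate sampling: identical for any seed / iteration count
        assert [(r.term, r.mean_p) for r in res_a] == [(r.term, r.mean_p) for r in res_b]
        terms = [r.term for r in res_a]
        single = enrich_once(set(genes) & universe, source, universe, terms=terms)
        for r in res_a:
            assert r.mean_p == pytest.approx(single[r.term][1], rel=1e-12)
            assert r.mean_overlap == pytest.approx(single[r.term][0])

    def test_planted_term_attains_smallest_mean_p(self, bundle, ground_truth, variants,
                                                  default_config):
        from snpannot import map_all

        mappings, _ = map_all(variants, bundle, list(default_config.eqtl_tissues))
        cfg = EnrichmentConfig(iterations=100, seed=2)
        res = sampled_enrichment(mappings, bundle.gene_set_sources["REACT"], cfg)
        assert res[0].term in ground_truth.planted_terms["REACT"]

    def test_iterations_one_reproducible(self, bundle):
        source = bundle.gene_set_sources["GO_BP"]
        universe = sorted(set().union(*source.term_to_genes.values()))
        mappings = [mk_mapping(f"rs{i}", universe[3 * i: 3 * i + 3]) for i in range(8)]
        cfg = EnrichmentConfig(iterations=1, seed=9)
        a = sampled_enrichment(mappings, source, cfg)
        b = sampled_enrichment(mappings, source, cfg)
        assert [(r.term, r.mean_p, r.mean_overlap) for r in a] == [
            (r.term, r.mean_p, r.mean_overlap) for r in b
        ]

    def test_results_sorted_by_mean_p_then_term(self, bundle, variants, default_config):
        from snpannot import map_all

        mappings, _ = map_all(variants, bundle, list(default_config.eqtl_tissues))
        cfg = EnrichmentConfig(iterations=20, seed=4)
        res = sampled_enrichment(mappings, bundle.gene_set_sources["GO_BP"], cfg)
        keys = [(r.mean_p, r.term) for r in res]
        assert keys == sorted(keys)

    def test_all_unmapped_fatal(self):
        m = VariantGeneMapping(variant=Variant("rs1", "1", 5), tier="unmapped", genes=())
        with pytest.raises(ConfigError):
            sampled_enrichment([m], GeneSetSource("S", {"t": frozenset({"A", "B", "C"})}),
                               EnrichmentConfig(iterations=2, seed=0))
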