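import numpy as np
import pandas as pd
import pytest

from snpannot import (
    Variant,
    VariantGeneMapping,
    sample_gene_assignments,
    sv_proximity,
    trait_fractions,
)
from snpannot.exceptions import ConfigError


def mk_mapping(rsid, genes, chrom="1", pos=1000):
    return VariantGeneMapping(
        variant=Variant(rsid, chrom, pos), tier="eqtl", genes=tuple(sorted(genes))
    )


def mk_catalog(rows):
    """rows: (rsid, trait, reported_genes tuple, pvalue)"""
    df = pd.DataFrame(rows, columns=["rsid", "trait", "reported_genes", "pvalue"])
    return df


class TestSampleGeneAssignments:
    def test_single_gene_forced(self):
        samples = sample_gene_assignments([mk_mapping("rs1", ["G1"])], 20, seed=1)
        assert all(s["rs1"] == "G1" for s in samples)

    def test_two_genes_near_uniform(self):
        m = mk_mapping("rs1", ["G1", "G2"])
        n = 10_000
        samples = sample_gene_assignments([m], n, seed=2)
        freq = sum(s["rs1"] == "G1" for s in samples) / n
        sigma = np.sqrt(0.25 / n)
        assert abs(freq - 0.5) <= 3 * sigma

    def test_same_seed_identical_sequence(self):
        ms = [mk_mapping("rs1", ["G1", "G2", "G3"]), mk_mapping("rs2", ["G4", "G5"])]
        a = sample_gene_assignments(ms, 100, seed=5)
        b = sample_gene_assignments(ms, 100, seed=5)
        assert a == b

    def test_zero_iterations_fatal(self):
        with pytest.raises(ConfigError):
            sample_gene_assignments([mk_mapping("rs1", ["G1"])], 0, seed=1)

    def test_unmapped_variant_fatal(self):
        with pytest.raises(ConfigError):
            sample_gene_assignments([mk_mapping("rs1", [])], 10, seed=1)


class TestTraitFractions:
    def test_direct_support_exact_fraction(self):
        variants = [Variant(f"rs{i}", "1", 100 * i) for i in range(1, 5)]
        mappings = [mk_mapping(v.rsid, ["G1"]) for v in variants]
        catalog = mk_catalog([
            ("rs1", "T", (), 1e-8),
            ("rs2", "T", (), 1e-8),
        ])
        out = trait_fractions(variants, mappings, catalog, iterations=7, seed=3)
        (tf,) = out
        assert tf.trait == "T"
        assert tf.mean_fraction == pytest.approx(0.5)
        assert tf.sd_fraction == 0.0
        assert tf.supporting_snps_direct == 2

    def test_single_gene_variants_seed_invariant(self):
        variants = [Variant("rs1", "1", 100), Variant("rs2", "1", 200)]
        mappings = [mk_mapping("rs1", ["G1"]), mk_mapping("rs2", ["G2"])]
        catalog = mk_catalog([("rs900", "T", ("G1",), 1e-8)])
        a = trait_fractions(variants, mappings, catalog, iterations=50, seed=1)
        b = trait_fractions(variants, mappings, catalog, iterations=50, seed=999)
        assert [(t.trait, t.mean_fraction, t.sd_fraction) for t in a] == [
            (t.trait, t.mean_fraction, t.sd_fraction) for t in b
        ]
        assert a[0].mean_fraction == pytest.approx(0.5)

    def test_gene_mediated_bernoulli_expectation(self):
        # one SNP mapped to {G1, G2}, only G1 supports trait T: mean ~ 0.5/n
        variants = [Variant("rs1", "1", 100), Variant("rs2", "1", 200)]
        mappings = [mk_mapping("rs1", ["G1", "G2"]), mk_mapping("rs2", ["G9"])]
        catalog = mk_catalog([("rs800", "T", ("G1",), 1e-8)])
        n_iter = 500
        (tf,) = trait_fractions(variants, mappings, catalog, iterations=n_iter, seed=11)
        expectation = 0.5 / 2
        sigma = np.sqrt(0.25 / n_iter) / 2  # binomial sd of the per-iteration fraction mean
        assert abs(tf.mean_fraction - expectation) <= 3 * sigma

    def test_unmapped_variants_count_in_denominator_and_direct(self):
        variants = [Variant("rs1", "1", 100), Variant("rs2", "1", 200)]
        mappings = [mk_mapping("rs1", ["G1"])]  # rs2 unmapped
        catalog = mk_catalog([("rs2", "T", (), 1e-8)])
        (tf,) = trait_fractions(variants, mappings, catalog, iterations=5, seed=1)
        assert tf.mean_fraction == pytest.approx(0.5)
        assert tf.supporting_snps_direct == 1

    def test_zero_mean_traits_omitted(self):
        variants = [Variant("rs1", "1", 100)]
        mappings = [mk_mapping("rs1", ["G1"])]
        catalog = mk_catalog([("rs999", "T", ("OTHER",), 1e-8)])
        assert trait_fractions(variants, mappings, catalog, iterations=5, seed=1) == []

    def test_order_invariance(self, bundle, variants, default_config):
        from snpannot import map_all

        mappings, _ = map_all(variants, bundle, list(default_config.eqtl_tissues))
        a = trait_fractions(variants, mappings, bundle.catalog, iterations=30, seed=5)
        rev = trait_fractions(
            variants[::-1], mappings[::-1], bundle.catalog.iloc[::-1],
            iterations=30, seed=5,
        )
        assert {t.trait: t.supporting_snps_direct for t in a} == {
            t.trait: t.supporting_snps_direct for t in rev
        }
        # mean fractions agree to sampling tolerance (same marginal distribution)
        am = {t.trait: t.mean_fraction for t in a}
        rm = {t.trait: t.mean_fraction for t in rev}
        for trait in am:
            assert abs(am[trait] - rm[trait]) < 0.1


class TestSvProximity:
    def test_examples_and_boundary(self):
        v = [Variant("rs1", "1", 100_000)]
        svs = pd.DataFrame([
            {"chrom": "1", "start": 109_000, "end": 115_000, "sv_type": "deletion",
             "max_allele_size_diff": 10, "study": "s"},
            {"chrom": "1", "start": 110_001, "end": 120_000, "sv_type": "deletion",
             "max_allele_size_diff": 10, "study": "s"},
            {"chrom": "1", "start": 95_000, "end": 105_000, "sv_type": "cnv",
             "max_allele_size_diff": 10, "study": "s"},
        ])
        out = sv_proximity(v, svs)
        hit_idx = {o.sv_index for o in out}
        assert hit_idx == {0, 2}  # window is closed at pos+10000; 110001 misses
        spanning = next(o for o in out if o.sv_index == 2)
        assert spanning.distance == 0

    def test_matches_brute_force_on_fixture(self, bundle, variants):
        out = sv_proximity(variants, bundle.svs)
        got = {(o.variant.rsid, o.sv_index) for o in out}
        expected = set()
        for v in variants:
            for idx, sv in bundle.svs.iterrows():
                if sv.chrom == v.chrom and sv.start <= v.pos + 10_000 and sv.end >= v.pos - 10_000:
                    expected.add((v.rsid, int(idx)))
        assert got == expected
        assert expected, "fixture must produce at least one SV overlap"

    def test_zero_window(self):
        v = [Variant("rs1", "1", 100)]
        svs = pd.DataFrame([
            {"chrom": "1", "start": 100, "end": 100, "sv_type": "insertion",
             "max_allele_size_diff": 1, "study": "s"},
            {"chrom": "1", "start": 101, "end": 200, "sv_type": "insertion",
             "max_allele_size_diff": 1, "study": "s"},
        ])
        out = sv_proximity(v, svs, window_bp=0)
        assert {o.sv_index for o in out} == {0}

    def test_negative_window_fatal(self):
        with pytest.raises(ConfigError):
            sv_proximity([], pd.DataFrame(columns=["chrom", "start", "end"]), window_bp=-1)
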