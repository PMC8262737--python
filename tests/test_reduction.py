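import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from snpannot import (
    classical_mds,
    cluster_wordclouds,
    dynamic_cut,
    hclust_ward,
    information_content,
    lin_similarity,
    revigo_reduce,
    similarity_matrix,
)
from snpannot.exceptions import ConfigError, DataError
from .conftest import random_dag


class TestInformationContent:
    def test_root_ic_zero(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        assert ic["R"] == pytest.approx(0.0)

    def test_hand_counted_toy_values(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        # A: propagated genes {g1 (via C), g2} of 10 -> -ln 0.2
        assert ic["A"] == pytest.approx(-np.log(0.2), abs=1e-9)
        assert ic["C"] == pytest.approx(-np.log(0.1), abs=1e-9)

    def test_monotone_along_every_edge(self, bundle):
        ic = information_content(bundle.ontology, bundle.annotations)
        for child, parents in bundle.ontology.parents.items():
            if child not in ic:
                continue
            for p in parents:
                assert ic.counts[child] <= ic.counts[p]
                assert ic[child] >= ic[p] - 1e-12

    def test_unannotated_term_raises_on_access(self, toy_dag):
        ont, ann = toy_dag
        ann = {g: t for g, t in ann.items() if "B2" not in t}
        ic = information_content(ont, ann)
        with pytest.raises(DataError, match="infinite IC"):
            ic["B2"]


class TestLinSimilarity:
    def test_self_similarity_is_one(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        assert lin_similarity("A", "A", ic, ont) == pytest.approx(1.0)

    def test_siblings_under_root_zero(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        assert lin_similarity("B1", "B2", ic, ont) == 0.0

    def test_parent_child_hand_value(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        expected = 2 * (-np.log(0.2)) / (-np.log(0.2) - np.log(0.1))
        assert lin_similarity("A", "C", ic, ont) == pytest.approx(expected, abs=1e-6)
        # 2*ln(5) / (ln(5) + ln(10)) by hand
        assert expected == pytest.approx(0.82283, abs=1e-4)

    def test_cross_namespace_error(self):
        from snpannot import Ontology

        ont = Ontology(
            terms={"R", "A", "M"},
            names={t: t for t in ("R", "A", "M")},
            namespace={"R": "BP", "A": "BP", "M": "MF"},
            parents={"R": set(), "A": {"R"}, "M": set()},
        )
        ann = {"g1": frozenset({"A"}), "g2": frozenset({"M"}), "g3": frozenset({"R"})}
        ic = information_content(ont, ann)
        with pytest.raises(ConfigError):
            lin_similarity("A", "M", ic, ont)

    def test_agrees_with_brute_force_mica_on_random_dags(self):
        """Oracle: enumerate common ancestors by naive closure, IC by naive
        propagation; compare the full Lin value on 20 random DAGs."""
        rng = np.random.default_rng(2024)
        for trial in range(20):
            n = int(rng.integers(5, 51))
            ont, ann = random_dag(rng, n)
            ic = information_content(ont, ann)

            def naive_ancestors(t):
                out = {t}
                frontier = [t]
                while frontier:
                    x = frontier.pop()
                    for p in ont.parents[x]:
                        if p not in out:
                            out.add(p)
                            frontier.append(p)
                return out

            # naive IC: count genes whose annotation closure includes t
            closures = {g: set().union(*(naive_ancestors(t) for t in ts))
                        for g, ts in ann.items()}
            root = next(t for t in ont.terms if not ont.parents[t])
            root_count = sum(1 for c in closures.values() if root in c)
            terms = sorted(ont.terms)
            picks = rng.choice(len(terms), size=min(8, len(terms)), replace=False)
            for i in picks:
                for j in picks:
                    t1, t2 = terms[int(i)], terms[int(j)]
                    if t1 not in ic or t2 not in ic:
                        continue
                    naive_ic = {}
                    for t in naive_ancestors(t1) & naive_ancestors(t2):
                        cnt = sum(1 for c in closures.values() if t in c)
                        if cnt:
                            naive_ic[t] = -np.log(cnt / root_count)
                    denom = ic[t1] + ic[t2]
                    expected = (2 * max(naive_ic.values()) / denom) if denom > 0 else 0.0
                    got = lin_similarity(t1, t2, ic, ont)
                    assert got == pytest.approx(min(max(expected, 0), 1), abs=1e-9)


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal_in_range(self, bundle):
        ic = information_content(bundle.ontology, bundle.annotations)
        terms = sorted(t for t in bundle.ontology.terms
                       if bundle.ontology.namespace[t] == "BP" and t in ic
                       and ic[t] > 0)[:15]
        sim = similarity_matrix(terms, ic, bundle.ontology)
        assert np.array_equal(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)
        assert (sim >= 0).all() and (sim <= 1).all()

    def test_entries_match_pairwise_calls(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        terms = ["A", "C", "B1"]
        sim = similarity_matrix(terms, ic, ont)
        for i, t1 in enumerate(terms):
            for j, t2 in enumerate(terms):
                assert sim[i, j] == pytest.approx(lin_similarity(t1, t2, ic, ont))

    def test_too_few_terms_fatal(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ont, ann)
        with pytest.raises(ConfigError):
            similarity_matrix(["A"], ic, ont)


def block_similarity(sizes, within=0.9, between=0.05):
    n = sum(sizes)
    sim = np.full((n, n), between)
    start = 0
    labels = []
    for b, s in enumerate(sizes):
        sim[start:start + s, start:start + s] = within
        labels += [b] * s
        start += s
    np.fill_diagonal(sim, 1.0)
    return sim, np.array(labels)


class TestHclustWard:
    def test_first_merge_closest_pair(self):
        # 1-D points {0, 1, 10}: exhaustive merge-cost comparison puts {0,1} first
        pts = np.array([[0.0], [1.0], [10.0]])
        dist = squareform(pdist(pts))
        tree = hclust_ward(dist)
        assert set(tree[0, :2].astype(int)) == {0, 1}

    def test_duplicate_points_merge_at_zero(self):
        pts = np.array([[0.0], [0.0], [5.0]])
        tree = hclust_ward(squareform(pdist(pts)))
        assert tree[0, 2] == pytest.approx(0.0)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 2))
        tree = hclust_ward(squareform(pdist(pts)))
        heights = tree[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_asymmetric_matrix_fatal(self):
        with pytest.raises(ConfigError):
            hclust_ward(np.array([[0, 1], [2, 0]], dtype=float))


class TestDynamicCut:
    @pytest.mark.parametrize("sizes", [(10, 10), (8, 8, 8, 8, 8)])
    def test_planted_partition_recovery(self, sizes):
        from sklearn.metrics import rand_score

        sim, truth = block_similarity(sizes)
        dist = 1 - sim
        np.fill_diagonal(dist, 0)
        labels = dynamic_cut(hclust_ward(dist), sim)
        assert rand_score(truth, labels) == 1.0
        assert len(set(labels)) == len(sizes)

    def test_all_equal_similarities_single_cluster(self):
        sim = np.full((12, 12), 0.5)
        np.fill_diagonal(sim, 1.0)
        dist = 1 - sim
        np.fill_diagonal(dist, 0)
        labels = dynamic_cut(hclust_ward(dist), sim)
        assert len(set(labels)) == 1

    def test_small_clusters_merged_into_similar_neighbor(self):
        sim, truth = block_similarity((10, 2))  # second block below min size
        dist = 1 - sim
        np.fill_diagonal(dist, 0)
        labels = dynamic_cut(hclust_ward(dist), sim, min_cluster_size=3)
        assert len(set(labels)) == 1  # only one viable cluster remains


class TestClassicalMds:
    def test_exactly_euclidean_2d_reproduced(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(15, 2))
        dist = squareform(pdist(pts))
        coords = classical_mds(dist)
        recon = squareform(pdist(coords))
        assert np.allclose(recon, dist, atol=1e-6)

    def test_procrustes_alignment_to_original(self):
        from scipy.spatial import procrustes

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(10, 2))
        coords = classical_mds(squareform(pdist(pts)))
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-10


class TestRevigoReduce:
    def test_redundant_pair_masked_to_smaller_p(self):
        sim = np.array([[1.0, 0.95], [0.95, 1.0]])
        red = revigo_reduce(["t1", "t2"], sim, [0.01, 0.001])
        assert red.kept == ["t2"]
        assert red.masked == {"t1": "t2"}

    def test_nothing_masked_below_cutoff(self):
        sim = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 0.1], [0.3, 0.1, 1.0]])
        red = revigo_reduce(["a", "b", "c"], sim, [0.1, 0.2, 0.3])
        assert sorted(red.kept) == ["a", "b", "c"]
        assert red.masked == {}

    def test_representative_has_smaller_or_equal_p(self):
        rng = np.random.default_rng(12)
        n = 20
        raw = rng.uniform(0.4, 1.0, size=(n, n))
        sim = (raw + raw.T) / 2
        np.fill_diagonal(sim, 1.0)
        pvals = list(rng.uniform(1e-6, 0.05, size=n))
        terms = [f"t{i:02d}" for i in range(n)]
        red = revigo_reduce(terms, sim, pvals)
        pmap = dict(zip(terms, pvals))
        for masked, rep in red.masked.items():
            assert pmap[rep] <= pmap[masked]
            i, j = terms.index(masked), terms.index(rep)
            assert sim[i, j] >= 0.7

    def test_first_term_always_kept(self):
        sim = np.full((3, 3), 0.99)
        np.fill_diagonal(sim, 1.0)
        red = revigo_reduce(["a", "b", "c"], sim, [0.3, 0.2, 0.1])
        assert red.kept == ["c"]
        assert set(red.masked) == {"a", "b"}


class TestClusterWordclouds:
    def test_word_counting(self):
        names = {"t1": "amyloid beta clearance", "t2": "amyloid formation"}
        labels = {"t1": 0, "t2": 0}
        out = cluster_wordclouds(names, labels)
        assert out[0]["amyloid"] == 2
        assert list(out[0])[0] == "amyloid"  # top word first

    def test_stopwords_dropped(self):
        out = cluster_wordclouds({"t": "regulation of the process"}, {"t": 0})
        assert out[0] == {}

    def test_order_invariance(self):
        names = {"a": "lipid transport", "b": "lipid binding", "c": "cell cycle"}
        out1 = cluster_wordclouds(names, {"a": 0, "b": 0, "c": 1})
        out2 = cluster_wordclouds(names, {"c": 1, "b": 0, "a": 0})
        assert out1 == out2
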