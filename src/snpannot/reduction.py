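"""Condensing enriched ontology terms.

Enriched-term lists are typically long and redundant.  This module
implements the two complementary condensation routes:

* **redundancy masking** — terms are processed by ascending P-value; a term
  whose Lin similarity to an already-kept term reaches the cutoff is masked
  behind that keeper.  Kept terms are embedded in 2-D by classical
  multidimensional scaling (eigen-decomposition of the double-centered
  squared-distance matrix).
* **term-based clustering** — Ward-D2 hierarchical clustering of the Lin
  distance matrix, with an adaptive (dynamic) tree cut and per-cluster word
  frequencies for wordcloud display.

Semantic similarity is Lin's measure,
``2 * IC(MICA) / (IC(t1) + IC(t2))``, with information content computed
from an annotation corpus with counts propagated to ancestors along is_a
edges, per namespace, in natural log units.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .exceptions import ConfigError, DataError
from .io import Ontology

DEFAULT_STOPWORDS = frozenset({
    "of", "the", "to", "in", "a", "an", "and", "or", "by", "via", "for",
    "process", "regulation", "positive", "negative", "root",
})


@dataclass
class ICTable:
    """Per-term information content (nats) over an annotation corpus."""

    ic: dict[str, float]
    counts: dict[str, int]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise DataError(
                f"term {term} has no propagated annotations (infinite IC)"
            ) from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic


@dataclass
class RevigoReduction:
    kept: list[str]
    masked: dict[str, str]  # masked term -> representative kept term
    coordinates: dict[str, tuple[float, float]]  # kept term -> 2-D embedding


@dataclass
class TermClustering:
    merge_tree: np.ndarray  # scipy linkage matrix
    labels: dict[str, int]
    n_clusters: int
    word_frequencies: dict[int, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Information content and Lin similarity
# ---------------------------------------------------------------------------


def information_content(
    ontology: Ontology, annotations: dict[str, frozenset[str]]
) -> ICTable:
    """IC from annotation counts propagated to ancestors, per namespace.

    A gene annotated to term t counts once for t and for every ancestor of
    t.  p(t) = count(t) / count(namespace root); IC = -ln p(t).  Terms with
    zero propagated count are absent from the table and raise on access.
    """
    genes_of: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            if t not in ontology.terms:
                raise DataError(f"annotation references unknown term {t}")
            for anc in ontology.ancestors(t):
                genes_of.setdefault(anc, set()).add(gene)
    counts = {t: len(g) for t, g in genes_of.items()}
    roots = ontology.roots()
    ic: dict[str, float] = {}
    for t, c in counts.items():
        root = roots[ontology.namespace[t]]
        root_count = counts.get(root, 0)
        if root_count == 0:
            continue
        ic[t] = float(-np.log(c / root_count))
    return ICTable(ic=ic, counts=counts, corpus_size=len(annotations))


def lin_similarity(t1: str, t2: str, ic: ICTable, ontology: Ontology) -> float:
    """Lin similarity: 2*IC(MICA) / (IC(t1)+IC(t2)); 0 when both ICs are 0.

    MICA is the common ancestor with maximal IC.  Cross-namespace pairs are
    an error.
    """
    if ontology.namespace[t1] != ontology.namespace[t2]:
        raise ConfigError(f"cross-namespace pair: {t1} ({ontology.namespace[t1]}) "
                          f"vs {t2} ({ontology.namespace[t2]})")
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    mica_ic = max((ic[t] for t in common if t in ic), default=0.0)
    return float(np.clip(2.0 * mica_ic / denom, 0.0, 1.0))


def similarity_matrix(
    terms: list[str], ic: ICTable, ontology: Ontology
) -> np.ndarray:
    """Dense symmetric Lin similarity matrix over an ordered term list."""
    if len(terms) < 2:
        raise ConfigError("similarity matrix requires at least 2 terms")
    missing = [t for t in terms if t not in ic]
    if missing:
        raise DataError(f"terms without finite IC: {missing}")
    n = len(terms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = lin_similarity(terms[i], terms[j], ic, ontology)
    return sim


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def hclust_ward(dist: np.ndarray) -> np.ndarray:
    """Ward-D2 agglomeration on a precomputed symmetric distance matrix.

    Returns a scipy linkage matrix.  Heights follow the Lance-Williams
    update on the supplied distances, matching ward.D2 on a distance input.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1] or dist.shape[0] < 2:
        raise ConfigError("distance matrix must be square with n >= 2")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ConfigError("distance matrix must be symmetric with zero diagonal")
    return linkage(squareform(dist, checks=False), method="ward")


def _subtree_heights(node) -> list[float]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if not n.is_leaf():
            out.append(n.dist)
            stack.append(n.left)
            stack.append(n.right)
    return out


def dynamic_cut(
    tree: np.ndarray,
    similarity: np.ndarray,
    min_cluster_size: int = 3,
) -> np.ndarray:
    """Adaptive dendrogram cut: split a branch when its top merge height is
    an outlier relative to its internal merge heights.

    Recursive descent from the root: a branch is split into its two
    children when its own merge height exceeds the mean + 1 SD of the merge
    heights strictly below it; otherwise the branch becomes one cluster.
    Clusters smaller than ``min_cluster_size`` are then merged into the
    cluster with the highest average inter-cluster similarity.  Returns an
    integer label per leaf (0..k-1, numbered by first leaf appearance).
    """
    root = to_tree(tree)
    n = root.get_count()
    labels = np.full(n, -1, dtype=int)
    clusters: list[list[int]] = []

    def assign(node) -> None:
        if node.is_leaf():
            clusters.append([node.id])
            return
        inner = _subtree_heights(node.left) + _subtree_heights(node.right)
        if inner:
            mean, sd = float(np.mean(inner)), float(np.std(inner))
            # relative slack absorbs ulp-level height jitter on ties
            if node.dist > mean + sd + 1e-8 * max(node.dist, 1.0):
                assign(node.left)
                assign(node.right)
                return
        clusters.append(sorted(node.pre_order(lambda x: x.id)))

    assign(root)

    # merge undersized clusters into their most similar neighbor
    sim = np.asarray(similarity, dtype=float)
    while len(clusters) > 1:
        sizes = [len(c) for c in clusters]
        small = [i for i, s in enumerate(sizes) if s < min_cluster_size]
        if not small:
            break
        i = min(small, key=lambda j: (sizes[j], j))
        best, best_sim = -1, -np.inf
        for j, other in enumerate(clusters):
            if j == i:
                continue
            s = float(sim[np.ix_(clusters[i], other)].mean())
            if s > best_sim:
                best, best_sim = j, s
        merged = sorted(clusters[i] + clusters[best])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, best)]
        clusters.append(merged)

    clusters.sort(key=lambda c: min(c))
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


# ---------------------------------------------------------------------------
# Redundancy masking and embedding
# ---------------------------------------------------------------------------


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigen-decomposes, and returns the
    top components scaled by the square root of their (positive)
    eigenvalues.  Components whose eigenvalue is non-positive come out as
    zero columns.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    coords = np.zeros((n, n_components))
    for c in range(min(n_components, n)):
        lam = w[order[c]]
        if lam > 0:
            coords[:, c] = v[:, order[c]] * np.sqrt(lam)
    return coords


def revigo_reduce(
    terms: list[str],
    sim: np.ndarray,
    pvals: list[float],
    cutoff: float = 0.7,
) -> RevigoReduction:
    """Greedy redundancy masking plus classical-MDS embedding of kept terms.

    Terms are visited by ascending P-value (ties by term id); a term is
    masked when its similarity to some already-kept term reaches ``cutoff``
    (the most similar such keeper, ties to the earlier-kept one, becomes
    its representative).  The first term is always kept.
    """
    if len(terms) != len(pvals) or np.asarray(sim).shape != (len(terms), len(terms)):
        raise ConfigError("terms, similarity matrix and P-values must align")
    order = sorted(range(len(terms)), key=lambda i: (pvals[i], terms[i]))
    kept_idx: list[int] = []
    masked: dict[str, str] = {}
    for i in order:
        sims_to_kept = [(float(sim[i, k]), -order.index(k), k) for k in kept_idx]
        over = [s for s in sims_to_kept if s[0] >= cutoff]
        if over:
            _, _, rep = max(over)
            masked[terms[i]] = terms[rep]
        else:
            kept_idx.append(i)
    kept = [terms[i] for i in kept_idx]
    coordinates: dict[str, tuple[float, float]] = {}
    if len(kept_idx) >= 2:
        sub = 1.0 - np.asarray(sim)[np.ix_(kept_idx, kept_idx)]
        np.fill_diagonal(sub, 0.0)
        coords = classical_mds(sub, n_components=2)
        for t, xy in zip(kept, coords):
            coordinates[t] = (float(xy[0]), float(xy[1]))
    elif kept:
        coordinates[kept[0]] = (0.0, 0.0)
    return RevigoReduction(kept=kept, masked=masked, coordinates=coordinates)


# ---------------------------------------------------------------------------
# Wordclouds
# ---------------------------------------------------------------------------


def cluster_wordclouds(
    term_names: dict[str, str],
    labels: dict[str, int],
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
) -> dict[int, dict[str, int]]:
    """Per-cluster word counts of term names (lowercased, stopwords dropped).

    Words within a cluster are ordered by descending count, then
    alphabetically.  Counts are invariant to term order.
    """
    out: dict[int, Counter] = {}
    for term, label in labels.items():
        name = term_names.get(term)
        if name is None:
            raise ConfigError(f"term {term} has no name")
        words = [
            w for w in re.split(r"[^0-9a-zA-Z]+", name.lower())
            if w and w not in stopwords
        ]
        out.setdefault(label, Counter()).update(words)
    result = {}
    for label in sorted(out):
        counts = out[label]
        result[label] = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return result
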