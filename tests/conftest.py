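import numpy as np
import pytest

from snpannot import FixtureConfig, Variant, generate_bundle


@pytest.fixture(scope="session")
def default_config():
    return FixtureConfig(seed=3)


@pytest.fixture(scope="session")
def bundle_gt(default_config):
    return generate_bundle(default_config)


@pytest.fixture(scope="session")
def bundle(bundle_gt):
    return bundle_gt[0]


@pytest.fixture(scope="session")
def ground_truth(bundle_gt):
    return bundle_gt[1]


@pytest.fixture(scope="session")
def variants(bundle, ground_truth):
    return [
        Variant(r, bundle.rsid_index[r][0], bundle.rsid_index[r][1])
        for r in sorted(ground_truth.tier)
    ]


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    from snpannot import write_bundle

    path = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, path)
    return path


def exhaustive_nearest(bundle, variant):
    """Independent brute-force nearest-gene scan (test oracle).

    Returns (min distance, {gene: distance}) over the variant's chromosome,
    using plain python arithmetic, no package mapping code.
    """
    dists = {}
    for row in bundle.genes.itertuples(index=False):
        if row.chrom != variant.chrom:
            continue
        if row.start <= variant.pos <= row.end:
            d = 0
        else:
            d = min(abs(variant.pos - row.start), abs(variant.pos - row.end))
        dists[row.symbol] = d
    return (min(dists.values()) if dists else None), dists


@pytest.fixture(scope="session")
def toy_dag():
    """Tiny hand-checkable ontology + annotations.

    10 corpus genes; term A is annotated (after propagation) by 2 of them,
    its child C by 1, siblings B1/B2 share only the root.
    """
    from snpannot import Ontology

    terms = {"R", "A", "C", "B1", "B2"}
    parents = {"R": set(), "A": {"R"}, "C": {"A"}, "B1": {"R"}, "B2": {"R"}}
    names = {t: t for t in terms}
    namespace = {t: "BP" for t in terms}
    ont = Ontology(terms=terms, names=names, namespace=namespace, parents=parents)
    annotations = {
        "g1": frozenset({"C"}),
        "g2": frozenset({"A"}),
        "g3": frozenset({"B1"}),
        "g4": frozenset({"B2"}),
    }
    # six more genes annotated only at the root to make the corpus 10
    for i in range(5, 11):
        annotations[f"g{i}"] = frozenset({"R"})
    return ont, annotations


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random rooted DAG + random annotations, built independently of the
    package's fixture generator (test oracle input)."""
    from snpannot import Ontology

    ids = [f"X:{i:03d}" for i in range(n_terms)]
    parents = {ids[0]: set()}
    for i in range(1, n_terms):
        k = 1 if (i == 1 or rng.random() < 0.7) else 2
        picks = rng.choice(i, size=k, replace=False)
        parents[ids[i]] = {ids[int(p)] for p in picks}
    ont = Ontology(
        terms=set(ids),
        names={t: t for t in ids},
        namespace={t: "BP" for t in ids},
        parents=parents,
    )
    genes = [f"gene{i}" for i in range(3 * n_terms)]
    annotations = {}
    for g in genes:
        n_ann = int(rng.integers(1, 4))
        picks = rng.choice(n_terms, size=n_ann, replace=False)
        annotations[g] = frozenset(ids[int(p)] for p in picks)
    return ont, annotations
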