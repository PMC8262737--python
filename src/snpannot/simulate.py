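"""Synthetic resource bundles with planted ground truth.

Every downstream stage of the annotation pipeline (tiered variant-to-gene
mapping, trait-catalog fractions, SV proximity, sampling-corrected
enrichment, term condensation, regional profiles) is exercised against
bundles built here.  The generator controls the geometry precisely:

* the genome is divided into fixed-width *slots*, one gene (sometimes a
  tight pair of genes) per slot, with inter-slot spacing wide enough that a
  variant's nearest gene is always the gene of its own slot;
* positional variants are planted at an exact distance from their slot gene,
  inside a chosen 50 kb window ring, so the expected expanding-window size
  is forced by construction;
* coding and eQTL variants receive the corresponding records (some coding
  variants also receive decoy eQTLs to exercise tier precedence);
* selected ontology terms get gene sets over-sampled from the mapped genes,
  planting a true enrichment signal;
* catalog traits are supported by chosen variants directly (rsID rows) and
  indirectly (reported-gene rows);
* half of the structural variants are placed within 10 kb of chosen
  variants, the rest far from every variant.

No attempt is made at biological realism (LD structure, MAF spectra)
beyond what the downstream statistics require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import Ontology, GeneSetSource, ResourceBundle, SV_TYPES

# Minimum slot width: a variant may sit up to 500 kb from its slot gene and
# must still be >500 kb from the neighboring slot's gene.
_MIN_SLOT = 1_200_000

_WORD_POOL = [
    "amyloid", "immune", "cell", "transport", "signaling", "response",
    "metabolic", "clearance", "activation", "migration", "protein", "lipid",
    "membrane", "synaptic", "inflammatory", "endocytosis", "phagocytosis",
    "cholesterol", "microglial", "neuronal", "binding", "assembly",
]

_STUDIES = ["longread_study_A", "longread_study_B", "longread_study_C"]


@dataclass
class FixtureConfig:
    """Knobs of the synthetic bundle generator.

    Defaults describe a compact genome that still exercises every mapping
    tier, all ten 50 kb window rings and both enrichment regimes.
    """

    n_chromosomes: int = 4
    chrom_length: int = 120_000_000
    n_genes: int = 300
    n_variants: int = 80
    fraction_coding: float = 0.15
    fraction_eqtl: float = 0.25
    eqtl_tissues: tuple[str, ...] = ("Blood", "Brain_Cortex")
    n_terms_per_namespace: int = 40
    genes_per_term: tuple[int, int] = (3, 12)
    n_traits: int = 6
    n_svs: int = 20
    seed: int = 0
    # extras beyond the core knobs
    n_unmapped: int = 2
    positional_rings: tuple[int, ...] = tuple(range(1, 11))
    paired_gene_slots: bool = True
    n_planted_terms: int = 8
    n_samples: int = 40
    n_expression_tissues: int = 8

    def validate(self) -> None:
        if self.fraction_coding + self.fraction_eqtl > 1:
            raise ConfigError("fraction_coding + fraction_eqtl must be <= 1")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_variants",
                     "n_terms_per_namespace", "n_traits", "n_svs"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_unmapped < 0:
            raise ConfigError("n_unmapped must be >= 0")
        if not self.positional_rings or any(not 1 <= k <= 10 for k in self.positional_rings):
            raise ConfigError("positional_rings must be window indices in 1..10")
        lo, hi = self.genes_per_term
        if not 1 <= lo <= hi:
            raise ConfigError("genes_per_term must be a (lo, hi) range with lo >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by variant rsID where applicable."""

    tier: dict[str, str] = field(default_factory=dict)
    genes: dict[str, frozenset[str]] = field(default_factory=dict)
    window_kb: dict[str, int | None] = field(default_factory=dict)
    tissues: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_terms: dict[str, set[str]] = field(default_factory=dict)  # source -> terms
    trait_support: dict[str, set[str]] = field(default_factory=dict)  # trait -> direct rsids
    sv_support: dict[int, set[str]] = field(default_factory=dict)  # sv row -> rsids within 10 kb


def _rng(seed: int, component: int) -> np.random.Generator:
    # Fixed per-component child streams: adding a new fixture component
    # never perturbs the existing ones.
    return np.random.default_rng([seed % (2**31), component])


def generate_bundle(config: FixtureConfig) -> tuple[ResourceBundle, GroundTruth]:
    """Build a deterministic, internally consistent bundle plus its ground truth."""
    config.validate()
    gt = GroundTruth()

    # ---- slot geometry -------------------------------------------------
    rng_genes = _rng(config.seed, 1)
    if config.paired_gene_slots:
        # every 4th slot (index % 4 == 3) holds two genes
        n_gene_slots = next(
            s for s in range(1, config.n_genes + 1) if s + s // 4 >= config.n_genes
        )
    else:
        n_gene_slots = config.n_genes
    total_slots = n_gene_slots + config.n_unmapped
    slots_per_chrom = math.ceil(total_slots / config.n_chromosomes)
    slot_width = config.chrom_length // slots_per_chrom
    if slot_width < _MIN_SLOT:
        raise ConfigError(
            f"genes do not fit: slot width {slot_width} bp < {_MIN_SLOT} bp; "
            "increase chrom_length or n_chromosomes, or reduce n_genes"
        )
    chroms = [str(i + 1) for i in range(config.n_chromosomes)]

    def slot_coords(slot: int) -> tuple[str, int]:
        chrom = chroms[slot // slots_per_chrom]
        start = (slot % slots_per_chrom) * slot_width
        return chrom, start

    # ---- genes ---------------------------------------------------------
    gene_rows = []
    slot_genes: list[list[int]] = [[] for _ in range(total_slots)]  # slot -> gene row idx
    gi = 0
    slot = 0
    while gi < config.n_genes:
        chrom, s0 = slot_coords(slot)
        center = s0 + slot_width // 2
        length = int(rng_genes.integers(5_000, 30_000))
        gene_rows.append(("GENE%04d" % (gi + 1), chrom, center, center + length,
                          "+" if rng_genes.random() < 0.5 else "-"))
        slot_genes[slot].append(gi)
        gi += 1
        paired = config.paired_gene_slots and (slot % 4 == 3) and gi < config.n_genes
        if paired:
            gap = int(rng_genes.integers(5_000, 20_000))
            length2 = int(rng_genes.integers(5_000, 30_000))
            start2 = center + length + gap
            gene_rows.append(("GENE%04d" % (gi + 1), chrom, start2, start2 + length2,
                              "+" if rng_genes.random() < 0.5 else "-"))
            slot_genes[slot].append(gi)
            gi += 1
        slot += 1
    gene_slots = list(range(slot))  # slots that contain >= 1 gene
    empty_slots = list(range(slot, total_slots))
    genes = pd.DataFrame(gene_rows, columns=["symbol", "chrom", "start", "end", "strand"])

    # ---- variants ------------------------------------------------------
    rng_var = _rng(config.seed, 2)
    n_coding = round(config.fraction_coding * config.n_variants)
    n_eqtl = round(config.fraction_eqtl * config.n_variants)
    n_unmapped = min(config.n_unmapped, len(empty_slots))
    n_positional = config.n_variants - n_coding - n_eqtl - n_unmapped
    if n_positional < 0:
        raise ConfigError("tier fractions plus n_unmapped exceed n_variants")

    variant_rows = []  # rsid, chrom, pos, maf
    coding_rows = []
    eqtl_rows = []
    vi = 0

    def new_rsid() -> str:
        nonlocal vi
        vi += 1
        return f"rs{1000 + vi}"

    # coding tier: variant inside a gene body; every third one gets a second
    # coding gene at the same position, every second one a decoy eQTL.
    for i in range(n_coding):
        row = genes.iloc[i % len(genes)]
        rsid = new_rsid()
        pos = int(rng_var.integers(row.start, row.end + 1))
        variant_rows.append((rsid, row.chrom, pos, rng_var.uniform(0.01, 0.5)))
        planted = {row.symbol}
        coding_rows.append((row.chrom, pos, rsid, row.symbol, "coding"))
        if i % 3 == 2:
            other = genes.iloc[(i + 7) % len(genes)].symbol
            if other not in planted:
                coding_rows.append((row.chrom, pos, rsid, other, "coding"))
                planted.add(other)
        if i % 2 == 1:
            decoy = genes.iloc[(i + 13) % len(genes)].symbol
            eqtl_rows.append((rsid, decoy, config.eqtl_tissues[0],
                              10.0 ** rng_var.uniform(-12, -4)))
        gt.tier[rsid] = "coding"
        gt.genes[rsid] = frozenset(planted)
        gt.window_kb[rsid] = None

    # eQTL tier: variant just outside a gene, with 1-3 eQTL records.
    for i in range(n_eqtl):
        row = genes.iloc[(i * 3 + 1) % len(genes)]
        rsid = new_rsid()
        pos = max(1, int(row.start) - 2_000 - i)
        variant_rows.append((rsid, row.chrom, pos, rng_var.uniform(0.01, 0.5)))
        k = int(rng_var.integers(1, 4))
        target_idx = rng_var.choice(len(genes), size=k, replace=False)
        targets = set()
        tissues = set()
        for j, t in enumerate(target_idx):
            tissue = config.eqtl_tissues[(i + j) % len(config.eqtl_tissues)]
            eqtl_rows.append((rsid, genes.iloc[int(t)].symbol, tissue,
                              10.0 ** rng_var.uniform(-12, -4)))
            targets.add(genes.iloc[int(t)].symbol)
            tissues.add(tissue)
        gt.tier[rsid] = "eqtl"
        gt.genes[rsid] = frozenset(targets)
        gt.window_kb[rsid] = None
        gt.tissues[rsid] = tuple(sorted(tissues))

    # positional tier: planted at an exact ring distance from the slot's
    # rightmost gene boundary.
    for i in range(n_positional):
        s = gene_slots[i % len(gene_slots)]
        ring = config.positional_rings[i % len(config.positional_rings)]
        members = slot_genes[s]
        right_end = max(int(genes.iloc[g].end) for g in members)
        d = int(rng_var.integers(50_000 * (ring - 1) + 1, 50_000 * ring + 1))
        rsid = new_rsid()
        chrom = genes.iloc[members[0]].chrom
        variant_rows.append((rsid, chrom, right_end + d, rng_var.uniform(0.01, 0.5)))
        gt.tier[rsid] = "positional"

    # unmapped: centered in gene-free slots, >500 kb from any gene.
    for i in range(n_unmapped):
        s = empty_slots[i]
        chrom, s0 = slot_coords(s)
        rsid = new_rsid()
        variant_rows.append((rsid, chrom, s0 + slot_width // 2, rng_var.uniform(0.01, 0.5)))
        gt.tier[rsid] = "unmapped"
        gt.genes[rsid] = frozenset()
        gt.window_kb[rsid] = None

    variants = pd.DataFrame(variant_rows, columns=["rsid", "chrom", "pos", "maf"])

    # positional / unmapped ground truth by exhaustive distance scan
    for rsid, chrom, pos, _ in variant_rows:
        if gt.tier[rsid] not in ("positional", "unmapped"):
            continue
        sub = genes[genes["chrom"] == chrom]
        inside = (sub["start"] <= pos) & (pos <= sub["end"])
        dist = np.where(
            inside, 0, np.minimum(np.abs(pos - sub["start"]), np.abs(pos - sub["end"]))
        )
        if len(dist) == 0 or dist.min() > 500_000:
            gt.tier[rsid] = "unmapped"
            gt.genes[rsid] = frozenset()
            gt.window_kb[rsid] = None
            continue
        window = 50 * math.ceil(max(int(dist.min()), 1) / 50_000)
        gt.window_kb[rsid] = window
        gt.genes[rsid] = frozenset(sub.loc[dist <= window * 1000, "symbol"])

    coding = pd.DataFrame(coding_rows, columns=["chrom", "pos", "rsid", "gene", "consequence_class"])
    if coding.empty:
        coding = pd.DataFrame(columns=["chrom", "pos", "rsid", "gene", "consequence_class"])
    eqtls = pd.DataFrame(eqtl_rows, columns=["rsid", "gene", "tissue", "pvalue"])
    if eqtls.empty:
        eqtls = pd.DataFrame(columns=["rsid", "gene", "tissue", "pvalue"])

    mapped_genes = sorted(set().union(*gt.genes.values()) if gt.genes else set())
    all_symbols = list(genes["symbol"])

    # ---- ontology + annotations + gene-set sources ---------------------
    rng_ont = _rng(config.seed, 3)
    ontology, term_names = _build_ontology(config, rng_ont)

    rng_gs = _rng(config.seed, 4)
    lo, hi = config.genes_per_term
    term_to_genes: dict[str, frozenset[str]] = {}
    for term in sorted(ontology.terms):
        size = int(rng_gs.integers(lo, hi + 1))
        size = min(size, len(all_symbols))
        picks = rng_gs.choice(len(all_symbols), size=size, replace=False)
        term_to_genes[term] = frozenset(all_symbols[int(i)] for i in picks)

    bp_terms = sorted(t for t in ontology.terms if ontology.namespace[t] == "BP"
                      and ontology.parents.get(t))
    gt.planted_terms["GO_BP"] = set()
    if config.n_planted_terms and mapped_genes:
        for j in range(min(config.n_planted_terms, len(bp_terms))):
            term = bp_terms[(j * 7 + 3) % len(bp_terms)]
            size = min(hi, max(lo, len(mapped_genes) // 3))
            n_from_mapped = max(1, int(round(size * 0.8)))
            picks = rng_gs.choice(len(mapped_genes), size=min(n_from_mapped, len(mapped_genes)),
                                  replace=False)
            chosen = {mapped_genes[int(i)] for i in picks}
            while len(chosen) < size:
                chosen.add(all_symbols[int(rng_gs.integers(0, len(all_symbols)))])
            term_to_genes[term] = frozenset(chosen)
            gt.planted_terms["GO_BP"].add(term)

    # annotation corpus = direct term gene sets (keeps IC finite everywhere)
    annotations: dict[str, set[str]] = {}
    for term, gset in term_to_genes.items():
        for g in gset:
            annotations.setdefault(g, set()).add(term)
    annotations_frozen = {g: frozenset(t) for g, t in annotations.items()}

    go_bp_source = GeneSetSource(
        "GO_BP", {t: g for t, g in term_to_genes.items() if ontology.namespace[t] == "BP"}
    )
    # A Reactome-like source with its own term ids, outside the ontology.
    react: dict[str, frozenset[str]] = {}
    n_react = max(10, config.n_terms_per_namespace // 2)
    for i in range(n_react):
        size = int(rng_gs.integers(lo, hi + 1))
        picks = rng_gs.choice(len(all_symbols), size=min(size, len(all_symbols)), replace=False)
        react[f"RCT:{i + 1:04d}"] = frozenset(all_symbols[int(j)] for j in picks)
    gt.planted_terms["REACT"] = set()
    if config.n_planted_terms and mapped_genes:
        term = f"RCT:{5:04d}"
        size = min(hi, max(lo, len(mapped_genes) // 3))
        picks = rng_gs.choice(len(mapped_genes), size=min(size, len(mapped_genes)), replace=False)
        react[term] = frozenset(mapped_genes[int(i)] for i in picks)
        gt.planted_terms["REACT"].add(term)
    react_source = GeneSetSource("REACT", react)

    # ---- trait catalog -------------------------------------------------
    rng_cat = _rng(config.seed, 5)
    catalog_rows = []
    rsids = list(variants["rsid"])
    for t in range(config.n_traits):
        trait = f"trait_{t + 1:03d}"
        n_direct = int(rng_cat.integers(1, max(2, config.n_variants // 8)))
        picks = rng_cat.choice(len(rsids), size=min(n_direct, len(rsids)), replace=False)
        direct = {rsids[int(i)] for i in picks}
        gt.trait_support[trait] = direct
        for r in sorted(direct):
            catalog_rows.append((r, trait, "", 10.0 ** rng_cat.uniform(-20, -5.05)))
        # gene-mediated rows carry external rsIDs but name mapped genes
        if mapped_genes:
            n_gene_rows = int(rng_cat.integers(1, 4))
            for j in range(n_gene_rows):
                k = int(rng_cat.integers(1, 4))
                picks = rng_cat.choice(len(mapped_genes), size=min(k, len(mapped_genes)),
                                       replace=False)
                gene_list = ",".join(sorted(mapped_genes[int(i)] for i in picks))
                catalog_rows.append((f"rs99{t:02d}{j:02d}", trait, gene_list,
                                     10.0 ** rng_cat.uniform(-20, -5.05)))
    catalog = pd.DataFrame(catalog_rows, columns=["rsid", "trait", "reported_genes", "pvalue"])
    catalog["reported_genes"] = catalog["reported_genes"].map(
        lambda s: tuple(g for g in s.split(",") if g)
    )

    # ---- structural variants -------------------------------------------
    rng_sv = _rng(config.seed, 6)
    sv_rows = []
    sv_types = sorted(SV_TYPES)
    n_near = config.n_svs // 2
    positions = variants[["rsid", "chrom", "pos"]].values.tolist()
    for i in range(n_near):
        rsid, chrom, pos = positions[i % len(positions)]
        start = max(1, int(pos) + int(rng_sv.integers(-9_000, 1_000)))
        length = int(rng_sv.integers(500, 50_000))
        sv_rows.append((chrom, start, start + length, sv_types[i % len(sv_types)],
                        int(rng_sv.integers(50, 5_000)), _STUDIES[i % 3]))
    for i in range(config.n_svs - n_near):
        for _ in range(200):
            chrom = chroms[int(rng_sv.integers(0, len(chroms)))]
            start = int(rng_sv.integers(1, config.chrom_length - 60_000))
            length = int(rng_sv.integers(500, 50_000))
            end = start + length
            clear = all(
                c != chrom or not (start <= p + 15_000 and end >= p - 15_000)
                for _, c, p in positions
            )
            if clear:
                break
        sv_rows.append((chrom, start, end, sv_types[(i + 3) % len(sv_types)],
                        int(rng_sv.integers(50, 5_000)), _STUDIES[i % 3]))
    svs = pd.DataFrame(sv_rows, columns=["chrom", "start", "end", "sv_type",
                                         "max_allele_size_diff", "study"])
    # ground truth by exhaustive closed-interval scan
    for idx, sv in svs.iterrows():
        near = {
            r for r, c, p in positions
            if c == sv.chrom and sv.start <= p + 10_000 and sv.end >= p - 10_000
        }
        if near:
            gt.sv_support[int(idx)] = near

    # ---- expression & genotypes ----------------------------------------
    rng_expr = _rng(config.seed, 7)
    tissues = list(config.eqtl_tissues) + [
        f"Tissue_{i + 1:02d}" for i in range(max(0, config.n_expression_tissues
                                                 - len(config.eqtl_tissues)))
    ]
    base = rng_expr.lognormal(mean=1.0, sigma=0.5, size=(len(all_symbols), len(tissues)))
    # two expression programs so bi-directional clustering has structure
    half_g, half_t = len(all_symbols) // 2, len(tissues) // 2
    base[:half_g, :half_t] *= 4.0
    base[half_g:, half_t:] *= 4.0
    expression = pd.DataFrame(np.round(base, 4), index=all_symbols, columns=tissues)
    expression.index.name = "gene"

    rng_gen = _rng(config.seed, 8)
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    dosages = {
        row.rsid: rng_gen.binomial(2, row.maf, size=config.n_samples)
        for row in variants.itertuples(index=False)
    }
    genotypes = pd.DataFrame(dosages, index=samples)
    genotypes.index.name = "sample"

    rsid_index = {
        row.rsid: (row.chrom, int(row.pos), round(float(row.maf), 6))
        for row in variants.itertuples(index=False)
    }

    bundle = ResourceBundle(
        genes=genes,
        coding=coding,
        eqtls=eqtls,
        catalog=catalog,
        svs=svs,
        ontology=ontology,
        gene_set_sources={"GO_BP": go_bp_source, "REACT": react_source},
        rsid_index=rsid_index,
        annotations=annotations_frozen,
        expression=expression,
        genotypes=genotypes,
    )
    return bundle, gt


def _build_ontology(config: FixtureConfig, rng: np.random.Generator) -> tuple[Ontology, dict]:
    """Rooted random-attachment DAG per namespace; single root each."""
    terms: set[str] = set()
    names: dict[str, str] = {}
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for ns in ("BP", "MF"):
        ids = [f"SYN:{ns}:{i + 1:05d}" for i in range(config.n_terms_per_namespace)]
        root = ids[0]
        terms.add(root)
        names[root] = f"{ns.lower()} root"
        namespace[root] = ns
        parents[root] = set()
        for i, term in enumerate(ids[1:], start=1):
            terms.add(term)
            k = min(i, 1 if rng.random() < 0.6 else 2)
            picks = rng.choice(i, size=k, replace=False)
            parents[term] = {ids[int(p)] for p in picks}
            namespace[term] = ns
            w = rng.choice(len(_WORD_POOL), size=int(rng.integers(2, 4)), replace=False)
            names[term] = " ".join(_WORD_POOL[int(j)] for j in w)
    ont = Ontology(terms=terms, names=names, namespace=namespace, parents=parents)
    ont.validate()
    return ont, names


def generate_association_study(
    region: tuple[str, int, int],
    peak_pos: int,
    peak_strength: float,
    n_snps: int,
    seed: int,
) -> pd.DataFrame:
    """A regional association table with a smooth planted peak plus noise.

    The -log10(P) backbone is a Gaussian bump of height ``peak_strength``
    centered on ``peak_pos``; SNP positions are an even grid over the region
    (seed-independent), so two seeds share the backbone and differ only in
    noise.  Output uses a generic sniffable 3-column dialect.
    """
    chrom, start, end = region
    if not start <= peak_pos <= end:
        raise ConfigError("peak_pos must lie inside the region")
    if n_snps < 10:
        raise ConfigError("n_snps must be >= 10 for a defined profile")
    rng = np.random.default_rng([seed % (2**31), 9])
    pos = np.linspace(start, end, n_snps).round().astype(int)
    sigma = (end - start) / 8
    backbone = peak_strength * np.exp(-((pos - peak_pos) ** 2) / (2 * sigma**2))
    neglog = np.clip(backbone + rng.normal(0, 0.3, size=n_snps), 0.0, None)
    return pd.DataFrame({
        "chrom": [chrom] * n_snps,
        "pos": pos,
        "p": 10.0 ** (-neglog),
    })


def write_ground_truth(gt: GroundTruth, directory) -> None:
    """Emit ground truth as TSV (per-variant) plus JSON (terms/traits/SVs)."""
    import json
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "ground_truth.tsv", "w") as fh:
        fh.write("rsid\ttier\twindow_kb\tgenes\n")
        for rsid in sorted(gt.tier):
            w = gt.window_kb.get(rsid)
            fh.write(
                f"{rsid}\t{gt.tier[rsid]}\t{'' if w is None else w}\t"
                f"{','.join(sorted(gt.genes.get(rsid, ())))}\n"
            )
    extra = {
        "planted_terms": {k: sorted(v) for k, v in gt.planted_terms.items()},
        "trait_support": {k: sorted(v) for k, v in gt.trait_support.items()},
        "sv_support": {str(k): sorted(v) for k, v in gt.sv_support.items()},
    }
    with open(directory / "ground_truth_extra.json", "w") as fh:
        json.dump(extra, fh, indent=1, sort_keys=True)
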