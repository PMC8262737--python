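"""Input handling: query parsing, resource-bundle I/O and association-file sniffing.

The annotation pipeline consumes a *resource bundle*: a directory of plain
TSV tables emulating the public annotation sources a variant-annotation
server would hold locally (gene coordinates, coding-consequence calls,
tissue eQTLs, a trait-association catalog, structural-variant call sets, an
OBO ontology with gene annotations, gene-set sources, and optional
expression / genotype matrices).  All coordinates are 1-based inclusive
(VCF convention); chromosome names are normalized by stripping any
``chr`` prefix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .exceptions import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

# Catalog inclusion rule: only associations below this P-value are retained.
CATALOG_P_THRESHOLD = 9e-6

_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_COORD_RE = re.compile(r"^(?:chr)?([0-9]{1,2}|[XYM]|MT)[:\s\t]+(\d+)$", re.IGNORECASE)

SV_TYPES = {
    "insertion",
    "deletion",
    "inversion",
    "cnv",
    "duplication",
    "satellite",
    "mobile_element",
    "other",
}


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome naming: strip a leading ``chr``, uppercase X/Y/MT."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in {"X", "Y", "MT", "M"}:
        return "MT" if c.upper() in {"MT", "M"} else c.upper()
    return c


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantQuery:
    """One line of user input: either an rsID or a chrom:pos coordinate."""

    raw: str
    kind: str  # "rsid" | "coordinate"
    rsid: str | None = None
    chrom: str | None = None
    pos: int | None = None


@dataclass(frozen=True)
class Variant:
    """A resolved query variant with 1-based genomic coordinates."""

    rsid: str
    chrom: str
    pos: int
    maf: float | None = None


@dataclass
class Ontology:
    """A rooted DAG of terms connected by is_a edges, one root per namespace."""

    terms: set[str]
    names: dict[str, str]
    namespace: dict[str, str]  # term -> BP | MF | CC | other
    parents: dict[str, set[str]]  # is_a edges, child -> parents
    _ancestor_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of *term* including itself (reflexive closure)."""
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.terms:
            raise DataError(f"unknown ontology term: {term}")
        out: set[str] = {term}
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def roots(self) -> dict[str, str]:
        """Namespace -> root term (the unique term without parents)."""
        roots: dict[str, str] = {}
        for t in self.terms:
            if not self.parents.get(t):
                ns = self.namespace[t]
                if ns in roots:
                    raise DataError(f"namespace {ns} has more than one root")
                roots[ns] = t
        return roots

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise DataError(f"term {child} has unknown parent {p}")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("ontology is_a graph contains a cycle")
        self.roots()  # raises on multiple roots per namespace


@dataclass
class GeneSetSource:
    """A named collection of term -> gene-set mappings (GO-like, Reactome-like)."""

    source_name: str
    term_to_genes: dict[str, frozenset[str]]


@dataclass
class ColumnMap:
    """Recognized chromosome / position / P-value columns of an association file."""

    chrom_col: str
    pos_col: str
    pvalue_col: str
    dialect: str  # plink1 | plink2 | generic


@dataclass
class ResourceBundle:
    """All annotation tables the pipeline consumes, loaded and validated."""

    genes: pd.DataFrame  # symbol, chrom, start, end, strand
    coding: pd.DataFrame  # chrom, pos, rsid, gene, consequence_class
    eqtls: pd.DataFrame  # rsid, gene, tissue, pvalue
    catalog: pd.DataFrame  # rsid, trait, reported_genes (tuple), pvalue
    svs: pd.DataFrame  # chrom, start, end, sv_type, max_allele_size_diff, study
    ontology: Ontology
    gene_set_sources: dict[str, GeneSetSource]
    rsid_index: dict[str, tuple[str, int, float | None]]  # rsid -> (chrom, pos, maf)
    annotations: dict[str, frozenset[str]] = field(default_factory=dict)  # gene -> terms
    expression: pd.DataFrame | None = None  # gene x tissue
    genotypes: pd.DataFrame | None = None  # sample x variant dosage
    warnings: list[str] = field(default_factory=list)

    @property
    def chromosomes(self) -> set[str]:
        return set(self.genes["chrom"].unique())


# ---------------------------------------------------------------------------
# Variant query parsing and resolution
# ---------------------------------------------------------------------------


def parse_variant_queries(text: str) -> list[VariantQuery]:
    """Parse a multiline SNP list: one rsID or chrom:pos token per line.

    Coordinates accept ``chr1:123``, ``1:123``, ``1 123`` and ``1\\t123``.
    Blank lines are ignored.  Lines matching neither pattern are collected
    and raised together; if *every* non-blank line fails, that is also fatal.
    """
    queries: list[VariantQuery] = []
    errors: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        if _RSID_RE.match(token):
            queries.append(VariantQuery(raw=token, kind="rsid", rsid=token.lower()))
            continue
        m = _COORD_RE.match(token)
        if m:
            queries.append(
                VariantQuery(
                    raw=token,
                    kind="coordinate",
                    chrom=normalize_chrom(m.group(1)),
                    pos=int(m.group(2)),
                )
            )
            continue
        errors.append(f"line {lineno}: unrecognized variant token {token!r}")
    if errors:
        raise DataError("invalid variant list:\n" + "\n".join(errors))
    return queries


def resolve_variants(
    queries: list[VariantQuery], bundle: ResourceBundle
) -> tuple[list[Variant], list[str]]:
    """Resolve queries to genomic coordinates via the bundle's rsID index.

    rsID queries are looked up in the index (case-insensitive); coordinate
    queries pass through with a synthesized ``chrom:pos`` identifier.
    Unresolved rsIDs are reported, not fatal; duplicates are collapsed with
    a warning.  Zero resolved variants is fatal.
    """
    variants: list[Variant] = []
    unresolved: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for q in queries:
        if q.kind == "rsid":
            key = q.rsid  # already lowercased
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            hit = bundle.rsid_index.get(key)
            if hit is None:
                unresolved.append(q.raw)
            else:
                chrom, pos, maf = hit
                variants.append(Variant(rsid=key, chrom=chrom, pos=pos, maf=maf))
        else:
            key = f"{q.chrom}:{q.pos}"
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            variants.append(Variant(rsid=key, chrom=q.chrom, pos=q.pos))
    if n_dup:
        logger.warning("deduplicated %d repeated variant queries", n_dup)
    if not variants:
        raise DataError("no variant query could be resolved to coordinates")
    return variants, unresolved


# ---------------------------------------------------------------------------
# Association-file column sniffing
# ---------------------------------------------------------------------------

_CHROM_NAMES = {"CHR", "CHROM", "#CHROM", "CHROMOSOME"}
_POS_NAMES = {"BP", "POS", "POSITION", "BP_HG19"}
_P_NAMES = {"P", "PVAL", "P_VALUE", "PVALUE", "P_BOLT_LMM"}

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT", "M"}


def _is_chrom_value(v: str) -> bool:
    return normalize_chrom(v) in _VALID_CHROMS


def _as_float(v: str) -> float | None:
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def _is_int_like(v: str) -> bool:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return False
    return f == int(f)


def sniff_association_columns(
    header: list[str], sample_rows: list[list[str]]
) -> ColumnMap:
    """Recognize chromosome / position / P-value columns of a summary-stat file.

    Name-based matching runs first (case-insensitive, PLINK 1.9 and 2.0
    header vocabularies); any role still unassigned falls back to a content
    heuristic over ``sample_rows``.  Two equally plausible candidates for a
    role are a fatal ambiguity — no silent guessing.
    """
    if not header or not sample_rows:
        raise ConfigError("sniffing requires a header and at least one sample row")
    upper = [h.upper() for h in header]

    def find_by_name(names: set[str]) -> str | None:
        hits = [header[i] for i, h in enumerate(upper) if h in names]
        if len(hits) > 1:
            raise FormatError(f"ambiguous header: multiple columns match {sorted(names)}")
        return hits[0] if hits else None

    chrom_col = find_by_name(_CHROM_NAMES)
    pos_col = find_by_name(_POS_NAMES)
    p_col = find_by_name(_P_NAMES)

    claimed = {c for c in (chrom_col, pos_col, p_col) if c is not None}

    def column_values(name: str) -> list[str]:
        i = header.index(name)
        return [str(r[i]) for r in sample_rows if i < len(r)]

    # Content heuristics fill roles in a fixed order (chrom, pos, p) so that a
    # column claimed by an earlier role cannot shadow a later one.
    if chrom_col is None:
        cands = [
            h
            for h in header
            if h not in claimed and all(_is_chrom_value(v) for v in column_values(h))
        ]
        if not cands:
            raise FormatError("unrecognized association format: no chromosome column")
        if len(cands) > 1:
            raise FormatError(
                f"ambiguous chromosome column candidates: {cands}; rename headers"
            )
        chrom_col = cands[0]
        claimed.add(chrom_col)

    if pos_col is None:
        int_cols = [
            h
            for h in header
            if h not in claimed and all(_is_int_like(v) for v in column_values(h))
        ]
        if not int_cols:
            raise FormatError("unrecognized association format: no position column")
        ranges = {}
        for h in int_cols:
            vals = [float(v) for v in column_values(h)]
            ranges[h] = max(vals) - min(vals) if len(vals) > 1 else max(vals)
        best = max(ranges.values())
        cands = [h for h in int_cols if ranges[h] == best]
        if len(cands) > 1:
            raise FormatError(f"ambiguous position column candidates: {cands}")
        pos_col = cands[0]
        claimed.add(pos_col)

    if p_col is None:
        cands = []
        for h in header:
            if h in claimed:
                continue
            vals = [_as_float(v) for v in column_values(h)]
            if vals and all(v is not None and 0 < v <= 1 for v in vals):
                cands.append(h)
        if not cands:
            raise FormatError("unrecognized association format: no P-value column")
        if len(cands) > 1:
            raise FormatError(f"ambiguous P-value column candidates: {cands}")
        p_col = cands[0]

    if len({chrom_col, pos_col, p_col}) != 3:
        raise FormatError("chromosome, position and P-value columns must be distinct")

    if {"CHR", "BP", "P"} <= set(upper):
        dialect = "plink1"
    elif "#CHROM" in upper and "POS" in upper:
        dialect = "plink2"
    else:
        dialect = "generic"
    return ColumnMap(chrom_col=chrom_col, pos_col=pos_col, pvalue_col=p_col, dialect=dialect)


def read_association_file(path: str | Path) -> tuple[pd.DataFrame, ColumnMap]:
    """Read a whitespace/tab-delimited association file and sniff its columns.

    Returns the full table plus the recognized column map.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    header = list(df.columns)
    sample = df.head(50).values.tolist()
    cmap = sniff_association_columns(header, sample)
    return df, cmap


# ---------------------------------------------------------------------------
# Bundle loading / writing
# ---------------------------------------------------------------------------

_MANDATORY_TABLES = {
    "genes": "genes.tsv",
    "coding": "coding.tsv",
    "eqtl": "eqtl.tsv",
    "catalog": "catalog.tsv",
    "sv": "sv.tsv",
    "rsid_index": "rsid_index.tsv",
    "ontology": "ontology.obo",
    "annotations": "annotations.gaf.tsv",
}


def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    return df


def _drop_malformed(
    df: pd.DataFrame, numeric_cols: list[str], name: str, warnings: list[str]
) -> pd.DataFrame:
    """Skip rows whose numeric fields do not parse, with a counted warning.

    Structural problems (missing columns, bad headers) are fatal elsewhere;
    single bad rows in large dumps are tolerated but never silent.
    """
    bad = pd.Series(False, index=df.index)
    for col in numeric_cols:
        bad |= pd.to_numeric(df[col], errors="coerce").isna()
    n_bad = int(bad.sum())
    if n_bad:
        msg = f"{name}: skipped {n_bad} malformed rows"
        logger.warning(msg)
        warnings.append(msg)
        df = df[~bad].reset_index(drop=True)
    return df


def read_obo_ontology(path: str | Path) -> Ontology:
    """Load an OBO file into the package's lightweight ontology structure."""
    graph = obonet.read_obo(str(path))
    terms: set[str] = set()
    names: dict[str, str] = {}
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    ns_map = {"biological_process": "BP", "molecular_function": "MF", "cellular_component": "CC"}
    for node, data in graph.nodes(data=True):
        terms.add(node)
        names[node] = data.get("name", node)
        raw_ns = data.get("namespace", "other")
        namespace[node] = ns_map.get(raw_ns, raw_ns if raw_ns in {"BP", "MF", "CC"} else "other")
        parents[node] = set()
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    ont = Ontology(terms=terms, names=names, namespace=namespace, parents=parents)
    ont.validate()
    return ont


def load_bundle(directory: str | Path, catalog_p_threshold: float = CATALOG_P_THRESHOLD) -> ResourceBundle:
    """Load and validate a resource bundle directory.

    Catalog rows at or above the P-value inclusion threshold (default 9e-6,
    strict ``<``) are dropped at load time and the dropped count is logged.
    Missing mandatory tables and dangling gene references are fatal.
    """
    directory = Path(directory)
    warnings: list[str] = []
    for key, fname in _MANDATORY_TABLES.items():
        if not (directory / fname).exists():
            raise FormatError(f"bundle is missing mandatory table: {fname}")

    genes = _read_tsv(directory / "genes.tsv", ["symbol", "chrom", "start", "end", "strand"])
    genes = _drop_malformed(genes, ["start", "end"], "genes.tsv", warnings)
    genes["chrom"] = genes["chrom"].map(normalize_chrom)
    genes["start"] = genes["start"].astype(int)
    genes["end"] = genes["end"].astype(int)
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "symbol"].tolist()
        raise DataError(f"genes with start > end: {bad}")
    dup = genes["symbol"][genes["symbol"].duplicated()].tolist()
    if dup:
        raise DataError(f"duplicate gene symbols in bundle: {sorted(set(dup))}")
    gene_symbols = set(genes["symbol"])

    coding = _read_tsv(directory / "coding.tsv", ["chrom", "pos", "rsid", "gene", "consequence_class"])
    coding = _drop_malformed(coding, ["pos"], "coding.tsv", warnings)
    coding["chrom"] = coding["chrom"].map(normalize_chrom)
    coding["pos"] = coding["pos"].astype(int)
    coding["rsid"] = coding["rsid"].fillna("").str.lower()
    bad = sorted(
        set(coding.loc[coding["consequence_class"] == "coding", "gene"]) - gene_symbols
    )
    if bad:
        raise DataError(f"coding records reference unknown genes: {bad}")

    eqtls = _read_tsv(directory / "eqtl.tsv", ["rsid", "gene", "tissue", "pvalue"])
    eqtls = _drop_malformed(eqtls, ["pvalue"], "eqtl.tsv", warnings)
    eqtls["rsid"] = eqtls["rsid"].str.lower()
    eqtls["pvalue"] = eqtls["pvalue"].astype(float)
    if (eqtls["pvalue"] <= 0).any():
        raise DataError("eQTL records with non-positive P-values")
    bad = sorted(set(eqtls["gene"]) - gene_symbols)
    if bad:
        raise DataError(f"eQTL records reference unknown genes: {bad}")

    catalog = _read_tsv(directory / "catalog.tsv", ["rsid", "trait", "reported_genes", "pvalue"])
    catalog = _drop_malformed(catalog, ["pvalue"], "catalog.tsv", warnings)
    catalog["rsid"] = catalog["rsid"].str.lower()
    catalog["pvalue"] = catalog["pvalue"].astype(float)
    n_before = len(catalog)
    catalog = catalog[catalog["pvalue"] < catalog_p_threshold].reset_index(drop=True)
    n_dropped = n_before - len(catalog)
    if n_dropped:
        msg = f"catalog: dropped {n_dropped} associations with P >= {catalog_p_threshold:g}"
        logger.info(msg)
        warnings.append(msg)
    catalog["reported_genes"] = catalog["reported_genes"].fillna("").map(
        lambda s: tuple(g for g in str(s).split(",") if g)
    )

    svs = _read_tsv(directory / "sv.tsv", ["chrom", "start", "end", "sv_type", "max_allele_size_diff", "study"])
    svs = _drop_malformed(svs, ["start", "end", "max_allele_size_diff"], "sv.tsv", warnings)
    svs["chrom"] = svs["chrom"].map(normalize_chrom)
    svs["start"] = svs["start"].astype(int)
    svs["end"] = svs["end"].astype(int)
    svs["max_allele_size_diff"] = svs["max_allele_size_diff"].astype(int)
    if (svs["start"] > svs["end"]).any():
        raise DataError("SV records with start > end")
    if (svs["max_allele_size_diff"] < 0).any():
        raise DataError("SV records with negative allele-size difference")
    bad_types = sorted(set(svs["sv_type"]) - SV_TYPES)
    if bad_types:
        raise DataError(f"unknown SV types: {bad_types}")

    idx_df = _read_tsv(directory / "rsid_index.tsv", ["rsid", "chrom", "pos"])
    idx_df["chrom"] = idx_df["chrom"].map(normalize_chrom)
    rsid_index: dict[str, tuple[str, int, float | None]] = {}
    has_maf = "maf" in idx_df.columns
    for row in idx_df.itertuples(index=False):
        maf = float(row.maf) if has_maf and not pd.isna(row.maf) else None
        rsid_index[str(row.rsid).lower()] = (row.chrom, int(row.pos), maf)

    ontology = read_obo_ontology(directory / "ontology.obo")

    gaf = _read_tsv(directory / "annotations.gaf.tsv", ["gene", "term"])
    bad = sorted(set(gaf["term"]) - ontology.terms)
    if bad:
        raise DataError(f"annotations reference unknown ontology terms: {bad[:10]}")
    annotations: dict[str, frozenset[str]] = {
        gene: frozenset(sub["term"]) for gene, sub in gaf.groupby("gene")
    }

    gene_set_sources: dict[str, GeneSetSource] = {}
    for path in sorted(directory.glob("genesets_*.tsv")):
        source_name = path.stem[len("genesets_"):]
        gs = _read_tsv(path, ["term", "gene"])
        term_to_genes = {t: frozenset(sub["gene"]) for t, sub in gs.groupby("term")}
        empty = [t for t, g in term_to_genes.items() if not g]
        if empty:
            raise DataError(f"{path.name}: empty gene sets for terms {empty}")
        gene_set_sources[source_name] = GeneSetSource(source_name, term_to_genes)

    expression = None
    if (directory / "expression.tsv").exists():
        expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
    genotypes = None
    if (directory / "genotypes.tsv").exists():
        genotypes = pd.read_csv(directory / "genotypes.tsv", sep="\t", index_col=0)

    return ResourceBundle(
        genes=genes,
        coding=coding,
        eqtls=eqtls,
        catalog=catalog,
        svs=svs,
        ontology=ontology,
        gene_set_sources=gene_set_sources,
        rsid_index=rsid_index,
        annotations=annotations,
        expression=expression,
        genotypes=genotypes,
        warnings=warnings,
    )


def write_bundle(bundle: ResourceBundle, directory: str | Path) -> None:
    """Write a bundle back to the on-disk layout ``load_bundle`` reads.

    Round-trip safe: loading the written directory reproduces the bundle
    field by field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.genes.to_csv(directory / "genes.tsv", sep="\t", index=False)
    bundle.coding.to_csv(directory / "coding.tsv", sep="\t", index=False)
    bundle.eqtls.to_csv(directory / "eqtl.tsv", sep="\t", index=False)
    cat = bundle.catalog.copy()
    cat["reported_genes"] = cat["reported_genes"].map(
        lambda g: ",".join(g) if isinstance(g, (tuple, list)) else str(g)
    )
    cat.to_csv(directory / "catalog.tsv", sep="\t", index=False)
    bundle.svs.to_csv(directory / "sv.tsv", sep="\t", index=False)

    with open(directory / "rsid_index.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\tmaf\n")
        for rsid in sorted(bundle.rsid_index):
            chrom, pos, maf = bundle.rsid_index[rsid]
            fh.write(f"{rsid}\t{chrom}\t{pos}\t{'' if maf is None else repr(maf)}\n")

    write_obo(bundle.ontology, directory / "ontology.obo")

    with open(directory / "annotations.gaf.tsv", "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(bundle.annotations):
            for term in sorted(bundle.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")

    for name in sorted(bundle.gene_set_sources):
        src = bundle.gene_set_sources[name]
        with open(directory / f"genesets_{name}.tsv", "w") as fh:
            fh.write("term\tgene\n")
            for term in sorted(src.term_to_genes):
                for gene in sorted(src.term_to_genes[term]):
                    fh.write(f"{term}\t{gene}\n")

    if bundle.expression is not None:
        bundle.expression.to_csv(directory / "expression.tsv", sep="\t")
    if bundle.genotypes is not None:
        bundle.genotypes.to_csv(directory / "genotypes.tsv", sep="\t")


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Serialize the ontology in standard OBO stanza format."""
    ns_map = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for term in sorted(ontology.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {ontology.names[term]}\n")
            ns = ontology.namespace[term]
            fh.write(f"namespace: {ns_map.get(ns, ns)}\n")
            for parent in sorted(ontology.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {ontology.names.get(parent, parent)}\n")
            fh.write("\n")
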