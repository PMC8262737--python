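"""End-to-end orchestration of the annotation pipeline and region reports.

``run_annotation`` drives mapping -> trait catalog -> SV proximity ->
sampling-corrected enrichment -> term condensation and writes a directory
of TSV tables plus a machine-readable ``manifest.json``.  All outputs are
sorted canonically and contain nothing volatile, so two runs with the same
bundle and seed are byte-identical.  Outputs are staged in a temporary
sibling directory and moved into place only on success, so a failed run
leaves no partial output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .exceptions import ConfigError, DataError
from .io import (
    ResourceBundle,
    load_bundle,
    parse_variant_queries,
    read_association_file,
    resolve_variants,
)
from .mapping import map_all, mappings_frame
from .context import sv_overlap_frame, sv_proximity, trait_fractions, trait_fractions_frame
from .enrichment import EnrichmentConfig, sampled_enrichment
from .reduction import (
    cluster_wordclouds,
    dynamic_cut,
    hclust_ward,
    information_content,
    revigo_reduce,
    similarity_matrix,
)
from .region import expression_heatmap_prep, ld_r2, pvalue_profile

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str | Path
    bundle_path: str | Path
    output_dir: str | Path
    tissues: tuple[str, ...] = ("Blood",)
    sources: tuple[str, ...] = ("GO_BP",)
    iterations: int = 500
    seed: int = 0
    fdr_threshold: float = 0.10
    revigo_cutoff: float = 0.7
    min_cluster_size: int = 3


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed and the stage name."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, meta: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in meta or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_annotation(config: RunConfig) -> Path:
    """Run the full annotation pipeline; returns the output directory."""
    out_dir = Path(config.output_dir)
    stage = "load"
    staging = out_dir.parent / (out_dir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        bundle = load_bundle(config.bundle_path)
        warnings = list(bundle.warnings)

        unknown = [s for s in config.sources if s not in bundle.gene_set_sources]
        if unknown:
            raise ConfigError(f"unknown gene-set sources: {unknown}; "
                              f"bundle offers {sorted(bundle.gene_set_sources)}")

        stage = "resolve"
        queries = parse_variant_queries(Path(config.input_path).read_text())
        variants, unresolved = resolve_variants(queries, bundle)
        # canonical variant order: makes every downstream table (and the
        # shared sampling stream) independent of input file ordering
        variants.sort(key=lambda v: (v.chrom, v.pos, v.rsid))
        if unresolved:
            warnings.append(f"unresolved rsIDs: {','.join(unresolved)}")

        stage = "mapping"
        mappings, summary = map_all(variants, bundle, list(config.tissues))
        _write_tsv(mappings_frame(mappings), staging / "mapping.tsv")
        summary_rows = (
            [{"metric": f"tier_{t}", "value": c} for t, c in summary.tier_counts.items()]
            + [{"metric": f"variants_with_{k}_genes", "value": c}
               for k, c in summary.genes_per_variant.items()]
            + [{"metric": "total_distinct_genes", "value": summary.total_distinct_genes}]
        )
        _write_tsv(pd.DataFrame(summary_rows), staging / "summary.tsv")

        stage = "traits"
        fractions = trait_fractions(
            variants, mappings, bundle.catalog,
            iterations=config.iterations, seed=stage_seed(config.seed, "sampling"),
        )
        _write_tsv(trait_fractions_frame(fractions), staging / "traits.tsv")

        stage = "sv"
        overlaps = sv_proximity(variants, bundle.svs)
        gene_lookup = {m.variant.rsid: m.genes for m in mappings}
        sv_df = sv_overlap_frame(overlaps, bundle.svs, mapped_genes=gene_lookup)
        if not sv_df.empty:
            sv_df = sv_df.sort_values(["variant", "sv_start"]).reset_index(drop=True)
        _write_tsv(sv_df, staging / "sv_overlap.tsv")

        stage = "enrichment"
        ecfg = EnrichmentConfig(
            iterations=config.iterations,
            seed=stage_seed(config.seed, "sampling"),
            fdr_plot_threshold=config.fdr_threshold,
        )
        enrichment_by_source = {}
        for source_name in config.sources:
            source = bundle.gene_set_sources[source_name]
            results = sampled_enrichment(
                mappings, source, ecfg, term_names=bundle.ontology.names
            )
            enrichment_by_source[source_name] = results
            df = pd.DataFrame([
                {
                    "term": r.term, "name": r.term_name,
                    "mean_p": f"{r.mean_p:.6g}", "q_value": f"{r.q_value:.6g}",
                    "mean_overlap": f"{r.mean_overlap:.4f}",
                    "term_size": r.term_size, "universe_size": r.universe_size,
                }
                for r in results
            ])
            meta = [
                f"source={source_name} universe=annotated_genes "
                f"correction=benjamini-hochberg iterations={config.iterations}",
            ]
            _write_tsv(df, staging / f"enrichment_{source_name}.tsv", meta=meta)
            sig = df[[float(q) < config.fdr_threshold for q in df["q_value"]]]
            _write_tsv(sig, staging / f"enrichment_{source_name}.significant.tsv", meta=meta)

        stage = "reduction"
        _run_reduction(config, bundle, enrichment_by_source, staging, warnings)

        stage = "manifest"
        manifest = {
            "tool_version": __version__,
            "config": {
                "input": str(config.input_path),
                "bundle": str(config.bundle_path),
                "tissues": list(config.tissues),
                "sources": list(config.sources),
                "iterations": config.iterations,
                "seed": config.seed,
                "fdr_threshold": config.fdr_threshold,
            },
            "bundle_tables": {
                "genes": len(bundle.genes),
                "coding": len(bundle.coding),
                "eqtl": len(bundle.eqtls),
                "catalog": len(bundle.catalog),
                "sv": len(bundle.svs),
                "ontology_terms": len(bundle.ontology.terms),
            },
            "n_input_queries": len(queries),
            "n_resolved": len(variants),
            "unresolved": sorted(unresolved),
            "tier_counts": summary.tier_counts,
            "warnings": warnings,
            "output_checksums": {
                p.name: _sha256(p) for p in sorted(staging.iterdir())
            },
        }
        with open(staging / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        shutil.rmtree(staging, ignore_errors=True)
        if isinstance(exc, (ConfigError, DataError)):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    return out_dir


def _run_reduction(config, bundle, enrichment_by_source, staging: Path,
                   warnings: list[str]) -> None:
    """Term condensation for ontology-backed sources with enough enriched terms."""
    ic = None
    cluster_rows, revigo_rows, word_rows, sim_frames = [], [], [], []
    for source_name, results in enrichment_by_source.items():
        enriched = [r for r in results
                    if r.q_value < config.fdr_threshold and r.term in bundle.ontology.terms]
        if len(enriched) < 3:
            warnings.append(
                f"{source_name}: {len(enriched)} ontology terms below FDR "
                f"{config.fdr_threshold:g}; term condensation skipped"
            )
            continue
        if ic is None:
            ic = information_content(bundle.ontology, bundle.annotations)
        terms = [r.term for r in enriched]
        pvals = [r.mean_p for r in enriched]
        sim = similarity_matrix(terms, ic, bundle.ontology)
        dist = 1.0 - sim
        import numpy as np
        np.fill_diagonal(dist, 0.0)
        tree = hclust_ward(dist)
        labels = dynamic_cut(tree, sim, min_cluster_size=config.min_cluster_size)
        red = revigo_reduce(terms, sim, pvals, cutoff=config.revigo_cutoff)
        words = cluster_wordclouds(
            {t: bundle.ontology.names[t] for t in terms},
            {t: int(l) for t, l in zip(terms, labels)},
        )
        for t, lab, p in zip(terms, labels, pvals):
            cluster_rows.append({"source": source_name, "term": t,
                                 "name": bundle.ontology.names[t],
                                 "cluster": int(lab), "mean_p": f"{p:.6g}"})
        for t in terms:
            if t in red.masked:
                revigo_rows.append({"source": source_name, "term": t, "status": "masked",
                                    "representative": red.masked[t], "x": "", "y": ""})
            else:
                x, y = red.coordinates.get(t, (0.0, 0.0))
                revigo_rows.append({"source": source_name, "term": t, "status": "kept",
                                    "representative": "", "x": f"{x:.6f}", "y": f"{y:.6f}"})
        for lab in sorted(words):
            for w, c in words[lab].items():
                word_rows.append({"source": source_name, "cluster": lab,
                                  "word": w, "count": c})
        sim_df = pd.DataFrame(sim.round(6), index=terms, columns=terms)
        sim_df.insert(0, "term", terms)
        sim_frames.append(sim_df)
    _write_tsv(pd.DataFrame(cluster_rows), staging / "clusters.tsv")
    _write_tsv(pd.DataFrame(revigo_rows), staging / "revigo.tsv")
    _write_tsv(pd.DataFrame(word_rows), staging / "wordclouds.tsv")
    if sim_frames:
        _write_tsv(pd.concat(sim_frames), staging / "similarity_matrix.tsv")
    else:
        _write_tsv(pd.DataFrame(), staging / "similarity_matrix.tsv")


# ---------------------------------------------------------------------------
# Region report
# ---------------------------------------------------------------------------


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse a ``chr:start-end`` region string into (chrom, start, end)."""
    import re

    m = re.match(r"^(?:chr)?([0-9XYM]+|MT)[:\s](\d+)-(\d+)$", text.strip(), re.IGNORECASE)
    if not m:
        raise ConfigError(f"cannot parse region {text!r}; expected chr:start-end")
    start, end = int(m.group(2)), int(m.group(3))
    if end <= start:
        raise ConfigError("region end must exceed region start")
    from .io import normalize_chrom

    return normalize_chrom(m.group(1)), start, end


def region_report(
    region: str | tuple[str, int, int],
    study_files: list[str | Path],
    output_dir: str | Path,
    n_bins: int = 20,
    degree: int = 3,
    bundle: ResourceBundle | None = None,
    ld_target: str | None = None,
    heatmap: bool = False,
) -> Path:
    """Per-study P-value profiles over one region, optional LD and heatmap prep."""
    import numpy as np

    chrom, start, end = parse_region(region) if isinstance(region, str) else region
    if not study_files:
        raise ConfigError("at least one study file is required")
    out_dir = Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    for i, path in enumerate(study_files, start=1):
        df, cmap = read_association_file(path)
        from .io import normalize_chrom

        chroms = df[cmap.chrom_col].map(normalize_chrom)
        sub = df[chroms == chrom]
        pos = sub[cmap.pos_col].astype(float).to_numpy()
        pvals = sub[cmap.pvalue_col].astype(float).to_numpy()
        inside = (pos >= start) & (pos <= end)
        if not inside.any():
            raise DataError(f"{path}: no association points in {chrom}:{start}-{end}")
        neglog = -np.log10(np.clip(pvals[inside], 1e-300, 1.0))
        fit = pvalue_profile(pos[inside], neglog, (start, end), n_bins=n_bins, degree=degree)
        name = Path(path).stem
        _write_tsv(
            pd.DataFrame({"pos": fit.grid_pos.round().astype(int),
                          "fitted_neglog10p": fit.grid_fit.round(6)}),
            out_dir / f"profile_{i:02d}_{name}.tsv",
            meta=[f"study={name} region={chrom}:{start}-{end} "
                  f"bins={n_bins} degree={degree} dialect={cmap.dialect}"],
        )

    if ld_target is not None:
        if bundle is None or bundle.genotypes is None:
            logger.warning("LD requested but no genotype matrix available; skipped")
        elif ld_target not in bundle.genotypes.columns:
            logger.warning("LD target %s absent from genotypes; skipped", ld_target)
        else:
            res = ld_r2(bundle.genotypes, ld_target)
            _write_tsv(
                pd.DataFrame(
                    [{"variant": k, "r2": "" if np.isnan(v) else f"{v:.6f}"}
                     for k, v in sorted(res.r2.items())]
                ),
                out_dir / "ld.tsv",
                meta=[f"target={ld_target}"],
            )

    if heatmap:
        if bundle is None or bundle.expression is None:
            logger.warning("heatmap requested but no expression matrix available; skipped")
        else:
            genes_in = bundle.genes[
                (bundle.genes["chrom"] == chrom)
                & (bundle.genes["end"] >= start)
                & (bundle.genes["start"] <= end)
            ]["symbol"]
            expr = bundle.expression.loc[bundle.expression.index.intersection(genes_in)]
            if expr.shape[0] < 2:
                logger.warning("fewer than 2 region genes with expression; heatmap skipped")
            else:
                scaled, gene_order, tissue_order, flagged = expression_heatmap_prep(expr)
                scaled.round(6).loc[gene_order, tissue_order].to_csv(
                    out_dir / "heatmap_scaled.tsv", sep="\t"
                )
                with open(out_dir / "heatmap_orders.tsv", "w") as fh:
                    fh.write("axis\trank\tlabel\n")
                    for r, g in enumerate(gene_order):
                        fh.write(f"gene\t{r}\t{g}\n")
                    for r, t in enumerate(tissue_order):
                        fh.write(f"tissue\t{r}\t{t}\n")
    return out_dir
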