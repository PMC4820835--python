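"""End-to-end pipeline orchestration, manifest, and per-gene reports.

``run_pipeline`` chains the synthetic generator (or pre-existing input
TSVs), ingest/symbolization, PPM integration, differential-expression
annotation, the partner network, protein/RNA signatures and clustering,
writing every stage's tables and exclusion reports plus a manifest that
suffices to reproduce any artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cluster, ingest, integrate, partners, profiles, protein_rna, synthetic
from .config import ConfigError, PipelineConfig


def root_scale(value, exponent: float = 4.0):
    """Display coordinate: value**(1/exponent); 0 maps to 0.

    A root scale spans many orders of magnitude like a log scale while
    keeping differences that grow with magnitude, as on a linear scale.
    """
    arr = np.asarray(value, dtype=float)
    if (arr < 0).any():
        raise ValueError("root scale is defined for non-negative values")
    out = arr ** (1.0 / exponent)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def run_pipeline(config: PipelineConfig, outdir: str | Path, input_dir: str | Path | None = None) -> dict:
    """Run all stages in dependency order; returns the artifact manifest.

    With ``input_dir`` unset, synthetic inputs are generated from
    ``config.synthetic`` and written under ``outdir/inputs``.  Every stage
    writes its outputs (TSV/JSON) under ``outdir``; the manifest records
    the configuration, seed and package version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if input_dir is None:
        scfg = config.synthetic
        sources, meta, alias, truth = synthetic.generate_proteome_sources(scfg)
        rna, rna_meta = synthetic.generate_rna_table(scfg, truth)
        input_dir = outdir / "inputs"
        synthetic.write_inputs(input_dir, sources, meta, alias, truth, rna, rna_meta)
    input_dir = Path(input_dir)
    if not input_dir.exists():
        raise FileNotFoundError(f"input directory not found: {input_dir}")

    source_paths = sorted(input_dir.glob("source_*.tsv"))
    for required in ["sample_meta.tsv", "aliases.tsv"]:
        if not (input_dir / required).exists():
            raise FileNotFoundError(f"missing input file: {input_dir / required}")
    tables = [ingest.read_source_table(p) for p in source_paths]
    alias_map = ingest.read_alias_map(input_dir / "aliases.tsv")
    meta = ingest.read_sample_meta(input_dir / "sample_meta.tsv")

    # --- ingest + integrate -------------------------------------------------
    aggregated, rejects = ingest.aggregate_sources(tables, alias_map)
    rejects.to_csv(outdir / "reject_report.tsv", sep="\t", index=False)
    units = {t.name: t.unit for t in tables}
    ematrix, exclusions = integrate.integrate_sources(
        aggregated,
        units,
        meta,
        min_genes=config.min_genes_per_sample,
        max_gene_count=config.max_gene_count,
    )
    ematrix.write(outdir / "entity_matrix")
    exclusions.to_csv(outdir / "sample_exclusions.tsv", sep="\t", index=False)

    # --- expression profiles (normal-entity track) --------------------------
    normal = ematrix.normal()
    log_matrix, shift_params = profiles.log_shift(normal)
    breadth = profiles.expression_breadth(normal)
    breadth.to_csv(outdir / "expression_breadth.tsv", sep="\t")
    fc = profiles.fold_changes(normal, abundance_floor=config.abundance_floor)
    annotation = profiles.call_differential_expression(
        fc, cutoff=config.de_cutoff, abundance_floor=config.abundance_floor
    )
    annotation.pairs.to_csv(outdir / "de_annotation.tsv", sep="\t", index=False)
    census = profiles.pattern_census(annotation, list(normal.index), list(normal.columns))
    (outdir / "pattern_census.json").write_text(
        json.dumps(
            {k: v for k, v in census.items() if k != "groups"}
            | {"n_genes": len(normal.index)},
            indent=1,
            sort_keys=True,
        )
    )
    sweep = profiles.threshold_sweep(fc, [2, 4, 6, 8, 10])
    sweep.to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)
    hk = profiles.housekeeping_score(normal, ematrix.entity_meta)
    hk.to_csv(outdir / "housekeeping_scores.tsv", sep="\t")

    # --- partner network ----------------------------------------------------
    corr, corr_excluded = partners.pairwise_correlations(log_matrix)
    null_r = partners.permutation_null(log_matrix, seed=config.seed, n_pairs=10_000)
    enrich_table, enrich_p = partners.distribution_enrichment(corr.to_numpy(), np.asarray(null_r))
    enrich_table.to_csv(outdir / "correlation_enrichment.tsv", sep="\t", index=False)

    rna_log = None
    if (input_dir / "rna.tsv").exists():
        rna = pd.read_csv(input_dir / "rna.tsv", sep="\t")
        rna_meta = pd.read_csv(input_dir / "rna_meta.tsv", sep="\t")
        rna_avg = protein_rna.average_rna(rna, rna_meta)
        rna_log, _ = profiles.log_shift(rna_avg)
    graph = partners.build_partner_graph(corr, cutoff=config.partner_cutoff, rna_matrix=rna_log)
    graph.edges.to_csv(outdir / "partner_edges.tsv", sep="\t", index=False)
    diagnostics = partners.cutoff_diagnostics(corr, [0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    diagnostics.to_csv(outdir / "partner_cutoff_diagnostics.tsv", sep="\t", index=False)

    # --- protein/RNA signatures ---------------------------------------------
    signature = None
    if (input_dir / "rna.tsv").exists():
        scales = protein_rna.CopyNumberScales(
            protein_factor=config.protein_copy_factor, rna_factor=config.rna_copy_factor
        )
        shared = [t for t in rna_avg.columns if t in set(normal.columns)]
        pcopies = protein_rna.to_copy_numbers(normal[shared], scales, "protein")
        rcopies = protein_rna.to_copy_numbers(rna_avg[shared], scales, "rna")
        ratios, ratio_excluded = protein_rna.pr_ratio(pcopies, rcopies, shared)
        pr_corr, pr_missing = protein_rna.pr_correlation(pcopies, rcopies, shared)
        signature = protein_rna.pr_signature(ratios, pr_corr, pcopies)
        signature.to_csv(outdir / "pr_signature.tsv", sep="\t")

    # --- clustering ---------------------------------------------------------
    k_grid = [k for k in config.kmeans_k_grid if k <= max(2, log_matrix.shape[0] - 1)]
    kres = cluster.kmeans_select_k(
        log_matrix, k_grid=k_grid, repeats=config.kmeans_repeats, seed=config.seed
    )
    kres.assignment.to_csv(outdir / "gene_clusters.tsv", sep="\t")
    kres.silhouette_by_k.to_csv(outdir / "silhouette_by_k.tsv", sep="\t", index=False)
    tissue_res = cluster.hierarchical_cluster(log_matrix.T, distance="one-minus-pearson")
    newick = cluster.linkage_to_newick(
        tissue_res.linkage_matrix, list(tissue_res.assignment.index)
    )
    (outdir / "tissue_dendrogram.nwk").write_text(newick + "\n")
    scores, evr, _ = cluster.pca_project(log_matrix, n_components=min(5, *log_matrix.shape))
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {
            "ingest": {
                "n_sources": len(tables),
                "n_rejected_rows": int(len(rejects)),
            },
            "integrate": {
                "n_genes": int(ematrix.matrix.shape[0]),
                "n_entities": int(ematrix.matrix.shape[1]),
                "n_normal_entities": int(normal.shape[1]),
                "n_excluded_samples": int(len(exclusions)),
                "log_shift": shift_params.shift,
            },
            "profiles": {
                "n_de_pairs": int(len(annotation.pairs)),
                "n_distinct_patterns": census["n_distinct_patterns"],
                "n_nonzero_patterns": census["n_nonzero_patterns"],
            },
            "partners": {
                "n_edges": int(len(graph.edges)),
                "n_elite_edges": int(graph.edges["elite"].sum()) if len(graph.edges) else 0,
                "enrichment_p": enrich_p,
                "n_zero_variance_genes": len(corr_excluded),
            },
            "protein_rna": (
                {
                    "n_signature_genes": int(len(signature)),
                }
                if signature is not None
                else None
            ),
            "cluster": {
                "kmeans_k": kres.k,
                "pca_explained_variance": [float(x) for x in evr],
            },
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def gene_report(gene: str, artifact_dir: str | Path, exponent: float = 4.0) -> dict:
    """Per-gene summary from pipeline artifacts.

    Returns the expression bar data (PPM and root-scaled), the list of
    entities where the gene is differentially expressed, the partner list
    (elite first, then descending r), and the protein/RNA signature.
    """
    artifact_dir = Path(artifact_dir)
    ematrix = integrate.EntityMatrix.read(artifact_dir / "entity_matrix")
    if gene not in ematrix.matrix.index:
        raise KeyError(f"unknown gene: {gene}")
    vec = ematrix.normal().loc[gene]
    de = pd.read_csv(artifact_dir / "de_annotation.tsv", sep="\t")
    de_list = de[de["gene"] == gene].sort_values("fold_change", ascending=False)
    edges = pd.read_csv(artifact_dir / "partner_edges.tsv", sep="\t")
    mine = edges[(edges["gene_a"] == gene) | (edges["gene_b"] == gene)].copy()
    if len(mine):
        mine["partner"] = np.where(mine["gene_a"] == gene, mine["gene_b"], mine["gene_a"])
        mine = mine.sort_values(["elite", "r"], ascending=[False, False])
        partner_list = mine[["partner", "r", "elite"]].to_dict("records")
    else:
        partner_list = []
    sig_path = artifact_dir / "pr_signature.tsv"
    signature = None
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t", index_col=0)
        if gene in sig.index:
            signature = sig.loc[gene].to_dict()
    return {
        "gene": gene,
        "expression_ppm": vec.to_dict(),
        "expression_root_scale": {e: root_scale(v, exponent) for e, v in vec.items()},
        "differential_expression": de_list[["entity", "fold_change"]].to_dict("records"),
        "partners": partner_list,
        "pr_signature": signature,
    }


def gene_chart(gene: str, artifact_dir: str | Path, out_path: str | Path, exponent: float = 4.0) -> None:
    """Export the root-scaled expression bar chart for one gene (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = gene_report(gene, artifact_dir, exponent)
    entities = list(report["expression_root_scale"])
    heights = [report["expression_root_scale"][e] for e in entities]
    fig, ax = plt.subplots(figsize=(max(6, len(entities) * 0.15), 3))
    ax.bar(range(len(entities)), heights, color="#33648d")
    ax.set_xticks(range(len(entities)))
    ax.set_xticklabels(entities, rotation=90, fontsize=4)
    ax.set_ylabel(f"PPM^(1/{exponent:g})")
    ax.set_title(gene)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
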