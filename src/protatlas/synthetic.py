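"""Synthetic multi-source proteome and RNA inputs with known ground truth.

Emulates the structure of mined MS-proteomics abundance sources and a
multi-individual bulk RNA-seq compendium: several sources with partially overlapping gene
content and different abundance units (arbitrary iBAQ intensity vs
mole-fraction PPM), duplicate curations of the same experiment, many-to-many
protein/gene identifier maps, per-sample log-normal abundance distributions,
planted co-expression modules, tissue-specific spikes, housekeeping genes,
Bernoulli zero-dropout sparsity, and RNA vectors with planted per-gene
protein/RNA copy-number ratios and protein-RNA correlations.

The planted gene x entity profile is column-normalized to PPM (each entity
sums to 1e6) before sources sample from it, so a zero-noise, full-overlap,
no-dropout run of the integration pipeline reproduces the planted profile
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SyntheticConfig

CATEGORY_TISSUE = "normal tissue"
CATEGORY_CELL = "in-vivo cell"
CATEGORY_FLUID = "body fluid"
CATEGORY_CELL_LINE = "cell line"


@dataclass
class SourceTable:
    """Protein-level abundances from one source (long format).

    ``data`` columns: protein_id, sample_id, value.  ``unit`` is uniform
    within the source ("iBAQ" or "PPM").
    """

    name: str
    unit: str
    data: pd.DataFrame


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator.

    ``entity_profile`` is the planted gene x entity PPM matrix (columns sum
    to 1e6); all recovery checks compare against it.
    """

    entity_profile: pd.DataFrame
    entity_categories: dict[str, str]
    module_assignment: dict[str, int]
    tissue_specific_genes: dict[str, str]
    housekeeping_genes: list[str]
    planted_fold_changes: dict[str, dict[str, float]]
    planted_pr_ratio: dict[str, float]
    planted_pr_correlation: dict[str, float]
    rna_entities: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["entity_profile"] = {
            "index": list(self.entity_profile.index),
            "columns": list(self.entity_profile.columns),
            "values": self.entity_profile.to_numpy().tolist(),
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        ep = d.pop("entity_profile")
        profile = pd.DataFrame(ep["values"], index=ep["index"], columns=ep["columns"])
        d["module_assignment"] = {g: int(m) for g, m in d["module_assignment"].items()}
        return cls(entity_profile=profile, **d)


def _entity_names(config: SyntheticConfig) -> tuple[list[str], dict[str, str]]:
    n_tissue = config.n_entities - config.n_fluid_entities - config.n_cell_entities
    names, cats = [], {}
    for i in range(n_tissue):
        name = f"tissue_{i + 1:02d}"
        names.append(name)
        cats[name] = CATEGORY_TISSUE
    for i in range(config.n_cell_entities):
        name = f"cell_{i + 1:02d}"
        names.append(name)
        cats[name] = CATEGORY_CELL
    for i in range(config.n_fluid_entities):
        name = f"fluid_{i + 1:02d}"
        names.append(name)
        cats[name] = CATEGORY_FLUID
    return names, cats


def _truncated_normal(rng, lo: float, hi: float, mu: float, sigma: float, size: int) -> np.ndarray:
    """Draw N(mu, sigma) conditioned on [lo, hi] (rejection; sigma may be 0)."""
    if sigma == 0:
        return np.full(size, min(max(mu, lo), hi))
    out = rng.normal(mu, sigma, size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
    return np.clip(out, lo, hi)


def _planted_profile(config: SyntheticConfig, rng) -> tuple[pd.DataFrame, SyntheticTruth]:
    genes = [f"GS{i + 1:04d}" for i in range(config.n_genes)]
    entities, categories = _entity_names(config)
    tissue_entities = [e for e in entities if categories[e] != CATEGORY_FLUID]
    fluid_entities = [e for e in entities if categories[e] == CATEGORY_FLUID]
    mu, sigma = config.lognormal_mu_sigma

    order = rng.permutation(config.n_genes)
    pos = 0
    module_assignment: dict[str, int] = {}
    for j, count in enumerate(config.module_gene_counts):
        for gi in order[pos : pos + count]:
            module_assignment[genes[gi]] = j
        pos += count
    n_ts = int(round(config.tissue_specific_fraction * config.n_genes))
    n_ts = min(n_ts, config.n_genes - pos)
    ts_idx = order[pos : pos + n_ts]
    pos += n_ts
    n_hk = int(round(config.housekeeping_fraction * config.n_genes))
    n_hk = min(n_hk, config.n_genes - pos)
    hk_idx = order[pos : pos + n_hk]

    base = rng.normal(mu, sigma, config.n_genes)
    dev = rng.normal(0.0, config.entity_effect_sigma, (config.n_genes, config.n_entities))

    # planted co-expression modules: a module gene's per-entity deviation
    # decomposes into a shared profile plus private noise with the same total
    # variance every other gene carries, so the within-module correlation is
    # rho while per-sample abundance marginals stay log-normal
    rho = config.module_within_correlation
    sigma_m = config.entity_effect_sigma * np.sqrt(rho)
    sigma_w = config.entity_effect_sigma * np.sqrt(max(1.0 - rho, 0.0))
    for j in range(config.n_modules):
        profile = rng.normal(0.0, sigma_m, config.n_entities)
        members = [gi for gi, g in enumerate(genes) if module_assignment.get(g) == j]
        for gi in members:
            dev[gi, :] = profile + rng.normal(0.0, sigma_w, config.n_entities)

    # tissue-specific genes: flat baseline + one spike.  The baseline is
    # bounded to [1, 100] PPM: above the annotation floor so the planted
    # differential expression is defined, and a small enough mole fraction
    # that the spike does not distort its own column normalization.
    tissue_specific: dict[str, str] = {}
    planted_fc: dict[str, dict[str, float]] = {}
    base[ts_idx] = _truncated_normal(rng, 0.0, 2.0, mu, sigma, len(ts_idx))
    spike = np.log10(config.tissue_specific_factor)
    for gi in ts_idx:
        ent = tissue_entities[rng.integers(len(tissue_entities))]
        dev[gi, entities.index(ent)] += spike
        tissue_specific[genes[gi]] = ent
        planted_fc[genes[gi]] = {ent: config.tissue_specific_factor}

    # housekeeping genes: near-uniform across tissues/cells at the gene's own
    # baseline level (the housekeeping score is scale-free), absent in fluids
    hk_genes = sorted(genes[gi] for gi in hk_idx)
    for gi in hk_idx:
        dev[gi, :] = rng.normal(0.0, 0.15, config.n_entities)

    values = 10.0 ** (base[:, None] + dev)
    for gi in hk_idx:
        for e in fluid_entities:
            values[gi, entities.index(e)] = 0.0

    # normalize each entity column to mole-fraction PPM
    colsum = values.sum(axis=0)
    values = values / colsum * 1e6
    profile = pd.DataFrame(values, index=genes, columns=entities)

    log_ratio = rng.normal(*config.pr_ratio_log10_mu_sigma, config.n_genes)
    lo, hi = np.log10(config.pr_ratio_range[0]), np.log10(config.pr_ratio_range[1])
    log_ratio = np.clip(log_ratio, lo, hi)
    levels = config.pr_correlation_levels
    truth = SyntheticTruth(
        entity_profile=profile,
        entity_categories=categories,
        module_assignment=module_assignment,
        tissue_specific_genes=tissue_specific,
        housekeeping_genes=hk_genes,
        planted_fold_changes=planted_fc,
        planted_pr_ratio={g: float(10.0 ** log_ratio[i]) for i, g in enumerate(genes)},
        planted_pr_correlation={g: float(levels[i % len(levels)]) for i, g in enumerate(genes)},
        rna_entities=[e for e in entities if categories[e] == CATEGORY_TISSUE][: config.n_rna_entities],
    )
    return profile, truth


def _alias_structures(config: SyntheticConfig, rng, genes: list[str]):
    """Per-gene protein identifiers + alias map (incl. symbol self-mapping).

    Each gene has one UniProt-like private protein, possibly a second
    Ensembl-like private protein, and a fraction of gene pairs additionally
    share one protein (mapped to both symbols, value equally divided on
    aggregation).
    """
    alias: dict[str, tuple[str, ...]] = {}
    privates: dict[str, list[tuple[str, float]]] = {}
    counter = 0
    for g in genes:
        counter += 1
        p1 = f"SP{counter:05d}"
        alias[p1] = (g,)
        if rng.random() < 0.3:
            counter += 1
            p2 = f"ENSPX{counter:09d}"
            alias[p2] = (g,)
            w = float(rng.uniform(0.5, 0.9))
            privates[g] = [(p1, w), (p2, 1.0 - w)]
        else:
            privates[g] = [(p1, 1.0)]
        alias[g] = (g,)
    n_pairs = int(round(config.shared_protein_fraction * config.n_genes / 2))
    pair_idx = rng.permutation(config.n_genes)[: 2 * n_pairs]
    shared: list[tuple[str, str, str]] = []
    for k in range(n_pairs):
        g1, g2 = genes[pair_idx[2 * k]], genes[pair_idx[2 * k + 1]]
        pid = f"SPSH{k + 1:04d}"
        alias[pid] = tuple(sorted((g1, g2)))
        shared.append((pid, g1, g2))
    return alias, privates, shared


def _source_coverage(config: SyntheticConfig, rng, n_genes: int) -> list[np.ndarray]:
    """Boolean coverage mask per source honoring the all-way overlap fraction."""
    cover = np.zeros((config.n_sources, n_genes), dtype=bool)
    if config.n_sources == 1:
        cover[0, :] = True
        return [cover[0]]
    n_core = int(round(config.sources_overlap_fraction * n_genes))
    perm = rng.permutation(n_genes)
    core = perm[:n_core]
    cover[:, core] = True
    for gi in perm[n_core:]:
        k = int(rng.integers(1, config.n_sources))
        chosen = rng.choice(config.n_sources, size=k, replace=False)
        cover[chosen, gi] = True
    return [cover[s] for s in range(config.n_sources)]


def generate_proteome_sources(
    config: SyntheticConfig,
) -> tuple[list[SourceTable], pd.DataFrame, dict[str, tuple[str, ...]], SyntheticTruth]:
    """Generate per-source protein-level tables, sample metadata, alias map and truth.

    Returns
    -------
    sources : list of SourceTable
    meta : DataFrame with columns sample_id, source_name, entity, category,
        duplicate_group (one row per sample)
    alias_map : identifier -> tuple of gene symbols
    truth : SyntheticTruth
    """
    rng = np.random.default_rng(config.seed)
    profile, truth = _planted_profile(config, rng)
    genes = list(profile.index)
    entities = list(profile.columns)
    gvals = profile.to_numpy()

    alias, privates, shared = _alias_structures(config, rng, genes)
    coverage = _source_coverage(config, rng, len(genes))

    n_ibaq = (config.n_sources + 1) // 2
    source_names = [
        f"simIBAQ{s + 1}" if s < n_ibaq else f"simPPM{s - n_ibaq + 1}" for s in range(config.n_sources)
    ]
    units = ["iBAQ" if s < n_ibaq else "PPM" for s in range(config.n_sources)]
    ibaq_scales = 10.0 ** rng.uniform(2.0, 4.0, config.n_sources)

    # cell-line entities: profiles unrelated to the normal planted structure
    mu, sigma = config.lognormal_mu_sigma
    cl_entities = [f"cellline_{i + 1:02d}" for i in range(config.n_cell_line_entities)]
    cl_vals = 10.0 ** rng.normal(mu, sigma, (len(genes), len(cl_entities)))

    gene_idx = {g: i for i, g in enumerate(genes)}
    shared_by_gene: dict[int, list[tuple[str, int]]] = {}
    for pid, g1, g2 in shared:
        shared_by_gene.setdefault(gene_idx[g1], []).append((pid, gene_idx[g2]))
        shared_by_gene.setdefault(gene_idx[g2], []).append((pid, gene_idx[g1]))

    tables: list[SourceTable] = []
    meta_rows: list[dict] = []
    for s, src in enumerate(source_names):
        mask = coverage[s]
        sample_specs: list[tuple[str, str, str, str, np.ndarray]] = []
        for e_i, ent in enumerate(entities):
            group = f"{src}.{ent}"
            for c in range(max(config.n_duplicate_curations, 1)):
                sid = f"{src}.{ent}.c{c}"
                sample_specs.append((sid, ent, truth.entity_categories[ent], group, gvals[:, e_i]))
        if s == 0:
            for e_i, ent in enumerate(cl_entities):
                sid = f"{src}.{ent}.c0"
                sample_specs.append((sid, ent, CATEGORY_CELL_LINE, f"{src}.{ent}", cl_vals[:, e_i]))

        rec_pid: list[str] = []
        rec_sid: list[str] = []
        rec_val: list[float] = []
        for sid, ent, cat, group, col in sample_specs:
            meta_rows.append(
                {
                    "sample_id": sid,
                    "source_name": src,
                    "entity": ent,
                    "category": cat,
                    "duplicate_group": group,
                }
            )
            noise = 10.0 ** rng.normal(0.0, config.sample_noise_sigma, len(genes))
            v = np.where(mask, col * noise, 0.0)
            if config.zero_dropout_rate > 0:
                keep = rng.random(len(genes)) >= config.zero_dropout_rate
                v = np.where(keep, v, 0.0)
            total = v.sum()
            if total <= 0:
                continue
            if units[s] == "PPM":
                v = v / total * 1e6
            else:
                v = v * ibaq_scales[s]
            present = np.nonzero(v > 0)[0]
            present_set = set(present.tolist())
            shared_contrib = np.zeros(len(genes))
            shared_rows: dict[str, float] = {}
            for gi in present:
                for pid, gj in shared_by_gene.get(gi, ()):
                    if gj in present_set and gi < gj:
                        c = 0.1 * min(v[gi], v[gj])
                        shared_contrib[gi] += c
                        shared_contrib[gj] += c
                        shared_rows[pid] = 2.0 * c
            for gi in present:
                rem = v[gi] - shared_contrib[gi]
                for pid, w in privates[genes[gi]]:
                    val = rem * w
                    if val > 0:
                        rec_pid.append(pid)
                        rec_sid.append(sid)
                        rec_val.append(val)
            for pid, val in shared_rows.items():
                rec_pid.append(pid)
                rec_sid.append(sid)
                rec_val.append(val)
        data = pd.DataFrame({"protein_id": rec_pid, "sample_id": rec_sid, "value": rec_val})
        tables.append(SourceTable(name=src, unit=units[s], data=data))

    meta = pd.DataFrame(meta_rows, columns=["sample_id", "source_name", "entity", "category", "duplicate_group"])
    return tables, meta, alias, truth


def generate_rna_table(
    config: SyntheticConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a gene x sample RPKM table with planted P/R structure.

    RNA log10 vectors are constructed per gene so that (i) the geometric
    mean across the RNA panel of protein-copies / RNA-copies equals the
    planted ratio exactly in expectation, and (ii) the correlation between
    the log protein and log RNA tissue vectors targets the planted level
    (exactly 1 when the planted level is 1).  Per-individual noise is
    mean-one multiplicative log-normal so arithmetic averaging across
    individuals is unbiased.

    Returns (rna long table: gene, sample_id, rpkm; rna_meta: sample_id, entity).
    """
    if truth is None:
        raise ValueError("SyntheticTruth is required to generate the RNA table")
    rng = np.random.default_rng(config.seed + 1_000_003)
    panel = truth.rna_entities
    if not panel:
        raise ValueError("truth has no RNA entities")
    prot = truth.entity_profile[panel].to_numpy() * 1e4  # protein copies/cell
    genes = list(truth.entity_profile.index)
    n_t = len(panel)

    log_rna = np.zeros((len(genes), n_t))
    for i, g in enumerate(genes):
        p = np.log10(np.maximum(prot[i], 1e-12))
        rho = truth.planted_pr_correlation[g]
        log_ratio = np.log10(truth.planted_pr_ratio[g])
        sd = p.std()
        if sd == 0 or n_t < 3:
            log_rna[i] = p - log_ratio
            continue
        zp = (p - p.mean()) / sd
        if rho >= 1.0:
            zr = zp
        else:
            e = rng.normal(0.0, 1.0, n_t)
            zr = rho * zp + np.sqrt(1.0 - rho**2) * e
            zr = zr - zr.mean()
        log_rna[i] = zr * sd + p.mean() - log_ratio

    s_ln = config.rna_noise_sigma * np.log(10.0)
    rows_gene: list[str] = []
    rows_sid: list[str] = []
    rows_val: list[float] = []
    for t, ent in enumerate(panel):
        for k in range(config.n_rna_individuals):
            sid = f"rna.{ent}.ind{k}"
            if s_ln > 0:
                noise = np.exp(rng.normal(-0.5 * s_ln**2, s_ln, len(genes)))
            else:
                noise = np.ones(len(genes))
            vals = 10.0 ** log_rna[:, t] * noise
            rows_gene.extend(genes)
            rows_sid.extend([sid] * len(genes))
            rows_val.extend(vals.tolist())
    rna = pd.DataFrame({"gene": rows_gene, "sample_id": rows_sid, "rpkm": rows_val})
    rna_meta = pd.DataFrame(
        [
            {"sample_id": f"rna.{ent}.ind{k}", "entity": ent}
            for ent in panel
            for k in range(config.n_rna_individuals)
        ]
    )
    return rna, rna_meta


def make_paired_fold_change_tables(
    n_genes: int, n_tissues: int, disagreement_sigma: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two fold-change tables over the same genes/tissues with controlled disagreement.

    Table A is the reference; table B multiplies every fold change by
    10**N(0, disagreement_sigma).  Used by the replicate-handling
    comparison harness.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GS{i + 1:04d}" for i in range(n_genes)]
    tissues = [f"tissue_{t + 1:02d}" for t in range(n_tissues)]
    a = 10.0 ** rng.normal(0.0, 0.5, (n_genes, n_tissues))
    b = a * 10.0 ** rng.normal(0.0, disagreement_sigma, (n_genes, n_tissues))
    return (
        pd.DataFrame(a, index=genes, columns=tissues),
        pd.DataFrame(b, index=genes, columns=tissues),
    )


# ---------------------------------------------------------------------------
# TSV/JSON writers matching the ingest module's dialect


def write_inputs(
    outdir: str | Path,
    sources: list[SourceTable],
    meta: pd.DataFrame,
    alias_map: dict[str, tuple[str, ...]],
    truth: SyntheticTruth,
    rna: pd.DataFrame | None = None,
    rna_meta: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write all generated inputs as TSV (+ truth JSON); returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for st in sources:
        p = outdir / f"source_{st.name}.tsv"
        df = st.data.copy()
        df["unit"] = st.unit
        df.to_csv(p, sep="\t", index=False)
        paths[f"source:{st.name}"] = str(p)
    p = outdir / "sample_meta.tsv"
    meta.to_csv(p, sep="\t", index=False)
    paths["sample_meta"] = str(p)
    p = outdir / "aliases.tsv"
    rows = [(ident, sym) for ident, syms in sorted(alias_map.items()) for sym in syms]
    pd.DataFrame(rows, columns=["identifier", "symbol"]).to_csv(p, sep="\t", index=False)
    paths["aliases"] = str(p)
    p = outdir / "truth.json"
    p.write_text(truth.to_json())
    paths["truth"] = str(p)
    if rna is not None:
        p = outdir / "rna.tsv"
        rna.to_csv(p, sep="\t", index=False)
        paths["rna"] = str(p)
    if rna_meta is not None:
        p = outdir / "rna_meta.tsv"
        rna_meta.to_csv(p, sep="\t", index=False)
        paths["rna_meta"] = str(p)
    return paths
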