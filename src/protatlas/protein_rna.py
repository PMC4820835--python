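"""Protein-vs-RNA copy-number signatures and the replicate-handling harness.

Protein PPM and RNA RPKM are put on a common cellular copy-number scale
(1 PPM -> 1e4 protein copies, assuming ~1e10 protein molecules per cell;
1 RPKM -> 1 RNA copy).  Per gene, across a shared tissue panel, the
signature combines the geometric-mean protein/RNA copy ratio, the
protein-RNA Pearson correlation after per-tissue normalization, and the
count of tissues with protein data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CopyNumberScales:
    protein_factor: float = 1e4  # copies per PPM
    rna_factor: float = 1.0  # copies per RPKM

    def __post_init__(self) -> None:
        if self.protein_factor <= 0 or self.rna_factor <= 0:
            raise ValueError("copy-number factors must be positive")


def average_rna(
    rna: pd.DataFrame,
    rna_meta: pd.DataFrame,
    merge_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Average RPKM across individuals per entity (arithmetic mean).

    ``rna`` is long (gene, sample_id, rpkm); ``rna_meta`` maps samples to
    entities.  ``merge_map`` optionally merges close entities (e.g.
    coronary artery + aorta): the merged value is the mean of the entity
    means.  Entities with no samples are dropped with a warning.
    """
    m = rna_meta.set_index("sample_id")["entity"]
    df = rna.copy()
    df["entity"] = df["sample_id"].map(m)
    orphan = df["entity"].isna()
    if orphan.any():
        warnings.warn(f"{int(orphan.sum())} RNA rows with unmapped samples dropped", stacklevel=2)
        df = df[~orphan]
    wide = df.groupby(["gene", "entity"])["rpkm"].mean().unstack(fill_value=0.0)
    empty = set(rna_meta["entity"]) - set(wide.columns)
    if empty:
        warnings.warn(f"entities with no RNA samples dropped: {sorted(empty)}", stacklevel=2)
    if merge_map:
        merged_cols = {}
        groups: dict[str, list[str]] = {}
        for src, dst in merge_map.items():
            groups.setdefault(dst, []).append(src)
        keep = [c for c in wide.columns if c not in merge_map]
        for dst, srcs in groups.items():
            present = [s for s in srcs if s in wide.columns]
            if present:
                merged_cols[dst] = wide[present].mean(axis=1)
        wide = pd.concat([wide[keep]] + [v.rename(k) for k, v in merged_cols.items()], axis=1)
    return wide.sort_index(axis=1)


def to_copy_numbers(
    matrix: pd.DataFrame, scales: CopyNumberScales, kind: str
) -> pd.DataFrame:
    """Convert PPM or RPKM matrices to cellular copy numbers."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("negative abundance values")
    if kind == "protein":
        return matrix * scales.protein_factor
    if kind == "rna":
        return matrix * scales.rna_factor
    raise ValueError(f"unknown kind: {kind!r} (expected 'protein' or 'rna')")


def pr_ratio(
    protein_copies: pd.DataFrame,
    rna_copies: pd.DataFrame,
    shared_tissues: list[str] | None = None,
) -> tuple[pd.Series, list[str]]:
    """Per-gene geometric-mean protein/RNA copy ratio across shared tissues.

    Tissues where either scale is zero are ignored; genes with no usable
    tissue at all are excluded and reported.  Returns (ratios, excluded).
    """
    tissues = shared_tissues or [t for t in protein_copies.columns if t in set(rna_copies.columns)]
    genes = protein_copies.index.intersection(rna_copies.index)
    p = protein_copies.loc[genes, tissues].to_numpy(dtype=float)
    r = rna_copies.loc[genes, tissues].to_numpy(dtype=float)
    usable = (p > 0) & (r > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, p, 1.0) / np.where(usable, r, 1.0)), 0.0)
    count = usable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        gm = np.exp(logs.sum(axis=1) / np.maximum(count, 1))
    ratios = pd.Series(np.where(count > 0, gm, np.nan), index=genes, name="pr_ratio")
    excluded = sorted(ratios.index[ratios.isna()])
    return ratios.dropna(), excluded


def _tissue_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue across-gene normalization: log10, z-score, right shift.

    Zeros are kept out of the log by the matrix's smallest-positive/2
    floor convention; the right shift (adding the global minimum) leaves
    Pearson correlations unchanged and only enforces positivity.
    """
    values = matrix.to_numpy(dtype=float)
    pos = values[values > 0]
    floor = (pos.min() / 2.0) if pos.size else 1.0
    logs = np.log10(np.maximum(values, floor))
    mean = logs.mean(axis=0, keepdims=True)
    sd = logs.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (logs - mean) / sd
    z = z - z.min()
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def _gene_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Alternative per-gene across-tissue z-scoring (switchable reading)."""
    values = matrix.to_numpy(dtype=float)
    pos = values[values > 0]
    floor = (pos.min() / 2.0) if pos.size else 1.0
    logs = np.log10(np.maximum(values, floor))
    mean = logs.mean(axis=1, keepdims=True)
    sd = logs.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = (logs - mean) / sd
    return pd.DataFrame(z - z.min(), index=matrix.index, columns=matrix.columns)


def pr_correlation(
    protein: pd.DataFrame,
    rna: pd.DataFrame,
    shared_tissues: list[str] | None = None,
    mode: str = "per_tissue",
    min_tissues: int = 3,
) -> tuple[pd.Series, list[str]]:
    """Per-gene Pearson r between normalized protein and RNA tissue vectors.

    Each scale's gene-by-tissue block is normalized per tissue across
    genes (log10, z-score, right shift) by default; ``mode='per_gene'``
    z-scores per gene instead.  Genes constant on either scale, or with
    fewer than ``min_tissues`` tissues, get a missing value and are
    reported.  Returns (correlations, reported genes).
    """
    tissues = shared_tissues or [t for t in protein.columns if t in set(rna.columns)]
    if len(tissues) < min_tissues:
        raise ValueError(f"need >= {min_tissues} shared tissues, got {len(tissues)}")
    genes = protein.index.intersection(rna.index)
    norm = _tissue_normalize if mode == "per_tissue" else _gene_normalize
    if mode not in {"per_tissue", "per_gene"}:
        raise ValueError(f"unknown mode: {mode}")
    pn = norm(protein.loc[genes, tissues]).to_numpy(dtype=float)
    rn = norm(rna.loc[genes, tissues]).to_numpy(dtype=float)
    pc = pn - pn.mean(axis=1, keepdims=True)
    rc = rn - rn.mean(axis=1, keepdims=True)
    # genes (near-)constant on either scale have no defined correlation
    ok = (pn.std(axis=1) > 1e-9) & (rn.std(axis=1) > 1e-9)
    denom = np.sqrt((pc**2).sum(axis=1) * (rc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(ok & (denom > 0), (pc * rc).sum(axis=1) / denom, np.nan)
    out = pd.Series(r, index=genes, name="pr_correlation")
    reported = sorted(out.index[out.isna()])
    return out.dropna(), reported


def pr_correlation_null(
    protein: pd.DataFrame,
    rna: pd.DataFrame,
    seed: int,
    shared_tissues: list[str] | None = None,
    mode: str = "per_tissue",
) -> pd.Series:
    """Random control: protein tissue vectors permuted per gene."""
    rng = np.random.default_rng(seed)
    tissues = shared_tissues or [t for t in protein.columns if t in set(rna.columns)]
    perm = protein[tissues].to_numpy(dtype=float).copy()
    for i in range(perm.shape[0]):
        rng.shuffle(perm[i])
    permuted = pd.DataFrame(perm, index=protein.index, columns=tissues)
    r, _ = pr_correlation(permuted, rna, shared_tissues=tissues, mode=mode)
    return r


def pr_signature(
    ratios: pd.Series, correlations: pd.Series, protein_copies: pd.DataFrame
) -> pd.DataFrame:
    """Joined per-gene (correlation, ratio, tissues-with-protein) table.

    Genes missing either statistic are omitted (the intersection of the
    two gene sets defines the signature's row set).
    """
    genes = ratios.index.intersection(correlations.index)
    n_tissues = (protein_copies.loc[genes] > 0).sum(axis=1)
    return pd.DataFrame(
        {
            "pr_correlation": correlations.loc[genes],
            "pr_ratio": ratios.loc[genes],
            "n_tissues_with_protein": n_tissues.astype(int),
        }
    )


def replicate_handling_comparison(
    fc_table_a: pd.DataFrame, fc_table_b: pd.DataFrame, de_cutoff: float = 4.0
) -> dict:
    """Agreement metrics between two fold-change tables over identical panels.

    Table A is treated as ground truth (the replicate-aware run).  Reports
    the per-gene Pearson correlation of fold-change vectors (and its mean)
    plus the false-positive and false-negative rates of B's >= cutoff
    differential-expression calls against A's.
    """
    if set(fc_table_a.index) != set(fc_table_b.index) or set(fc_table_a.columns) != set(
        fc_table_b.columns
    ):
        only_a = sorted(set(fc_table_a.index) - set(fc_table_b.index))[:5]
        only_b = sorted(set(fc_table_b.index) - set(fc_table_a.index))[:5]
        raise ValueError(f"mismatched gene/tissue sets (A-only genes {only_a}, B-only {only_b})")
    b = fc_table_b.loc[fc_table_a.index, fc_table_a.columns]
    av = fc_table_a.to_numpy(dtype=float)
    bv = b.to_numpy(dtype=float)
    ac = av - av.mean(axis=1, keepdims=True)
    bc = bv - bv.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ac * bc).sum(axis=1) / denom, np.nan)
    calls_a = av >= de_cutoff
    calls_b = bv >= de_cutoff
    negatives = (~calls_a).sum()
    positives = calls_a.sum()
    fpr = float((calls_b & ~calls_a).sum() / negatives) if negatives else np.nan
    fnr = float((~calls_b & calls_a).sum() / positives) if positives else np.nan
    per_gene = pd.Series(r, index=fc_table_a.index, name="fc_correlation")
    return {
        "per_gene_correlation": per_gene,
        "mean_correlation": float(np.nanmean(r)),
        "fpr": fpr,
        "fnr": fnr,
        "de_cutoff": de_cutoff,
    }
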