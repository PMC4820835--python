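"""Normalization to PPM, sample filtering, duplicate pre-averaging, and
cross-source averaging into the gene x anatomical-entity matrix.

PPM here is a mole fraction: protein i's share per million protein
molecules in the sample, so every converted sample column sums to 1e6.
Averaging is always the geometric mean of non-zero PPM values; a gene
absent from every contributor gets 0 (absence is informative downstream).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class EntityMatrix:
    """Gene x anatomical-entity averaged PPM matrix with provenance.

    ``entity_meta`` maps entity -> category ("normal tissue", "in-vivo
    cell", "body fluid", "cell line", "disease"); ``lineage`` maps entity ->
    contributing sample ids.  Analysis operations default to the
    normal-category subset via :meth:`normal`.
    """

    matrix: pd.DataFrame
    entity_meta: dict[str, str] = field(default_factory=dict)
    lineage: dict[str, list[str]] = field(default_factory=dict)

    NORMAL_CATEGORIES = ("normal tissue", "in-vivo cell", "body fluid")

    def normal(self) -> pd.DataFrame:
        cols = [c for c in self.matrix.columns if self.entity_meta.get(c) in self.NORMAL_CATEGORIES]
        return self.matrix[cols]

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.matrix.to_csv(prefix.with_suffix(".tsv"), sep="\t")
        sidecar = {"entity_meta": self.entity_meta, "lineage": self.lineage}
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def read(cls, prefix: str | Path) -> "EntityMatrix":
        prefix = Path(prefix)
        matrix = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0)
        matrix.index.name = "gene"
        matrix.columns.name = "entity"
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        return cls(matrix=matrix, entity_meta=sidecar["entity_meta"], lineage=sidecar["lineage"])


def ibaq_to_ppm(column: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Convert one sample's iBAQ intensities to PPM: v_i / sum_j v_j * 1e6."""
    values = np.asarray(column, dtype=float)
    if (values < 0).any():
        raise ValueError("negative iBAQ intensities")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero sample column cannot be converted to PPM")
    out = values / total * 1e6
    if isinstance(column, pd.Series):
        return pd.Series(out, index=column.index, name=column.name)
    return out


def to_ppm(wide: pd.DataFrame, unit: str) -> pd.DataFrame:
    """Convert a gene x sample table to PPM; PPM input passes through unchanged."""
    if unit == "PPM":
        return wide
    if unit != "iBAQ":
        raise ValueError(f"unknown abundance unit: {unit}")
    return wide.apply(ibaq_to_ppm, axis=0)


def filter_samples(
    wide: pd.DataFrame, min_genes: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples with < min_genes mapped genes and collapse exact duplicates.

    A "mapped gene" is a gene with positive abundance.  Exact duplication is
    byte-equality of the gene -> value map; of each duplicate set the first
    sample in column order is retained.  Returns (retained, exclusion report).
    """
    report_rows = []
    gene_counts = (wide > 0).sum(axis=0)
    low = gene_counts[gene_counts < min_genes].index
    for sid in low:
        report_rows.append(
            {"sample_id": sid, "reason": f"<{min_genes} mapped genes", "detail": int(gene_counts[sid])}
        )
    kept = wide.drop(columns=low)

    seen: dict[bytes, str] = {}
    dup_cols = []
    for sid in kept.columns:
        key = kept[sid].to_numpy().tobytes()
        if key in seen:
            dup_cols.append(sid)
            report_rows.append({"sample_id": sid, "reason": "exact duplicate", "detail": seen[key]})
        else:
            seen[key] = sid
    kept = kept.drop(columns=dup_cols)
    if kept.shape[1] == 0:
        warnings.warn("no samples retained after filtering", stacklevel=2)
    report = pd.DataFrame(report_rows, columns=["sample_id", "reason", "detail"])
    return kept, report


def gm_nonzero(values: np.ndarray, axis: int = 1) -> np.ndarray:
    """Geometric mean of the positive entries along ``axis``; all-zero -> 0."""
    values = np.asarray(values, dtype=float)
    mask = values > 0
    with np.errstate(divide="ignore"):
        logs = np.where(mask, np.log(np.where(mask, values, 1.0)), 0.0)
    count = mask.sum(axis=axis)
    total = logs.sum(axis=axis)
    with np.errstate(invalid="ignore"):
        gm = np.exp(total / np.maximum(count, 1))
    return np.where(count > 0, gm, 0.0)


def preaverage_duplicates(
    wide: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pre-average duplicate curations of the same experiment.

    Samples sharing a ``duplicate_group`` are collapsed to one column, the
    per-gene geometric mean of non-zero PPM values across curations (a gene
    absent everywhere stays 0).  Returns (group table, group metadata with
    one row per group carrying the group's entity/category/source).
    """
    m = meta.set_index("sample_id")
    groups: dict[str, list[str]] = {}
    for sid in wide.columns:
        if sid not in m.index:
            raise KeyError(f"sample {sid} missing from metadata")
        groups.setdefault(str(m.at[sid, "duplicate_group"]), []).append(sid)
    cols = {}
    meta_rows = []
    for gname in sorted(groups):
        sids = groups[gname]
        cols[gname] = gm_nonzero(wide[sids].to_numpy(), axis=1)
        first = m.loc[sids[0]]
        meta_rows.append(
            {
                "sample_id": gname,
                "source_name": first["source_name"],
                "entity": first["entity"],
                "category": first["category"],
                "n_curations": len(sids),
            }
        )
    out = pd.DataFrame(cols, index=wide.index)
    out.columns.name = "sample_id"
    return out, pd.DataFrame(meta_rows)


def average_entities(
    wide: pd.DataFrame,
    meta: pd.DataFrame,
    max_gene_count: int = 12_000,
) -> EntityMatrix:
    """Average samples into the gene x entity matrix (geometric mean of non-zeros).

    Contributing datasets whose mapped-gene count exceeds ``max_gene_count``
    are excluded from averaging (outlier proteomes with inflated coverage);
    they remain in the input table, only the averaging skips them.  Entities
    left with zero contributors are dropped with a warning.
    """
    m = meta.set_index("sample_id")
    gene_counts = (wide > 0).sum(axis=0)
    usable = [sid for sid in wide.columns if gene_counts[sid] <= max_gene_count]
    skipped = [sid for sid in wide.columns if sid not in set(usable)]
    if skipped:
        warnings.warn(
            f"{len(skipped)} datasets with >{max_gene_count} mapped genes excluded from averaging",
            stacklevel=2,
        )
    by_entity: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    for sid in usable:
        ent = str(m.at[sid, "entity"])
        by_entity.setdefault(ent, []).append(sid)
        categories[ent] = str(m.at[sid, "category"])
    for sid in skipped:
        ent = str(m.at[sid, "entity"])
        if ent not in by_entity:
            warnings.warn(f"entity {ent} has no contributing samples after exclusion", stacklevel=2)
    cols = {}
    lineage = {}
    for ent in sorted(by_entity):
        sids = sorted(by_entity[ent])
        cols[ent] = gm_nonzero(wide[sids].to_numpy(), axis=1)
        lineage[ent] = sids
    matrix = pd.DataFrame(cols, index=wide.index)
    matrix.columns.name = "entity"
    return EntityMatrix(matrix=matrix, entity_meta=categories, lineage=lineage)


def integrate_sources(
    aggregated: dict[str, pd.DataFrame],
    units: dict[str, str],
    meta: pd.DataFrame,
    min_genes: int = 10,
    max_gene_count: int = 12_000,
) -> tuple[EntityMatrix, pd.DataFrame]:
    """Full integration: PPM conversion, filtering, duplicate pre-averaging,
    cross-source entity averaging.  Returns (EntityMatrix, exclusion report)."""
    converted = []
    for name, wide in aggregated.items():
        converted.append(to_ppm(wide, units[name]))
    merged = pd.concat(converted, axis=1).fillna(0.0)
    merged = merged.sort_index(axis=0)
    filtered, report = filter_samples(merged, min_genes=min_genes)
    meta_known = meta[meta["sample_id"].isin(filtered.columns)]
    grouped, group_meta = preaverage_duplicates(filtered, meta_known)
    ematrix = average_entities(grouped, group_meta, max_gene_count=max_gene_count)
    return ematrix, report
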