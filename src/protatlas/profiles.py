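"""Per-gene expression descriptors over the integrated PPM matrix.

Covers the log-shift transform into positive space, expression breadth,
mean-normalized fold changes with an abundance floor, differential-
expression annotation at a fold-change cutoff, the binary-pattern census,
the cutoff-selection sweep, and the housekeeping score against an in
silico ideal profile (uniform 10,000 PPM across tissues and cells, 0 in
fluids).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integrate import EntityMatrix


@dataclass
class LogShiftParams:
    dataset_min: float  # smallest positive PPM in the matrix
    shift: float  # log10(dataset_min / 2); subtracted from log10 values


@dataclass
class DEAnnotation:
    """Differential-expression calls: (gene, entity, fold_change >= cutoff)."""

    pairs: pd.DataFrame  # columns gene, entity, fold_change
    cutoff: float
    abundance_floor: float

    def patterns(self, entities: list[str]) -> pd.Series:
        """Per-gene '0'/'1' bit string over ``entities`` (1 = differentially expressed)."""
        called = {(g, e) for g, e in zip(self.pairs["gene"], self.pairs["entity"])}
        genes = sorted(set(self.pairs["gene"]))
        return pd.Series(
            {g: "".join("1" if (g, e) in called else "0" for e in entities) for g in genes},
            name="pattern",
        )


def log_shift(matrix: pd.DataFrame) -> tuple[pd.DataFrame, LogShiftParams]:
    """log10-transform and right-shift positives into positive space.

    The shift is log10 of the dataset-wide positive minimum divided by 2,
    so the smallest positive value maps to log10(2) > 0.  Zeros map to 0,
    below every transformed positive value.
    """
    values = matrix.to_numpy(dtype=float)
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive values")
    dataset_min = float(pos.min())
    shift = float(np.log10(dataset_min / 2.0))
    with np.errstate(divide="ignore"):
        out = np.where(values > 0, np.log10(np.where(values > 0, values, 1.0)) - shift, 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), LogShiftParams(
        dataset_min=dataset_min, shift=shift
    )


def expression_breadth(matrix: pd.DataFrame, gene: str | None = None):
    """Number of entities with non-zero abundance (per gene, or one gene)."""
    if gene is not None:
        if gene not in matrix.index:
            raise KeyError(f"unknown gene: {gene}")
        return int((matrix.loc[gene] > 0).sum())
    return (matrix > 0).sum(axis=1).rename("breadth")


def fold_changes(
    matrix: pd.DataFrame,
    abundance_floor: float = 0.1,
    mean_over_nonzero: bool = False,
) -> pd.DataFrame:
    """Fold change of each gene in each entity over the gene's mean abundance.

    FC(g, t) = PPM(g, t) / mean_t' PPM(g, t'); the mean is arithmetic over
    all entities (including zeros) by default.  Entries whose observed
    abundance is below ``abundance_floor`` (PPM) are NaN — fold changes
    derived from such low abundances are ignored.  Operates on the raw PPM
    scale, not log space.
    """
    values = matrix.to_numpy(dtype=float)
    if mean_over_nonzero:
        nz = (values > 0).sum(axis=1)
        denom = np.where(nz > 0, values.sum(axis=1) / np.maximum(nz, 1), 0.0)
    else:
        denom = values.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = values / denom[:, None]
    fc = np.where(denom[:, None] > 0, fc, np.nan)
    fc = np.where(values >= abundance_floor, fc, np.nan)
    return pd.DataFrame(fc, index=matrix.index, columns=matrix.columns)


def call_differential_expression(
    fc_table: pd.DataFrame, cutoff: float = 6.0, abundance_floor: float = 0.1
) -> DEAnnotation:
    """Annotate (gene, entity) pairs with fold change >= cutoff (inclusive)."""
    stacked = fc_table.stack()
    hits = stacked[stacked >= cutoff]
    pairs = hits.rename("fold_change").reset_index()
    pairs.columns = ["gene", "entity", "fold_change"]
    pairs = pairs.sort_values(["gene", "entity"]).reset_index(drop=True)
    return DEAnnotation(pairs=pairs, cutoff=cutoff, abundance_floor=abundance_floor)


def de_summaries(annotation: DEAnnotation, genes: list[str], entities: list[str]):
    """(genes per entity, entities per gene) count summaries."""
    per_entity = annotation.pairs.groupby("entity")["gene"].nunique()
    per_entity = per_entity.reindex(entities, fill_value=0)
    per_gene = annotation.pairs.groupby("gene")["entity"].nunique()
    per_gene = per_gene.reindex(genes, fill_value=0)
    return per_entity.rename("n_genes"), per_gene.rename("n_entities")


def threshold_sweep(fc_table: pd.DataFrame, cutoffs: list[float]) -> pd.DataFrame:
    """Diagnostics for fold-change cutoff selection.

    For each cutoff: total annotations, mean annotated genes per entity,
    and the number of genes left without any annotation.  The cutoff is
    chosen to balance inflating per-tissue gene lists against leaving too
    many genes unannotated.
    """
    if not list(cutoffs):
        raise ValueError("empty cutoff list")
    rows = []
    values = fc_table.to_numpy()
    n_entities = fc_table.shape[1]
    for c in cutoffs:
        mask = values >= c
        n_annot = int(np.nansum(mask))
        genes_with = int((mask.sum(axis=1) > 0).sum())
        rows.append(
            {
                "cutoff": c,
                "n_annotations": n_annot,
                "mean_genes_per_entity": n_annot / n_entities,
                "genes_without_annotation": fc_table.shape[0] - genes_with,
            }
        )
    return pd.DataFrame(rows)


def pattern_census(annotation: DEAnnotation, genes: list[str], entities: list[str]) -> dict:
    """Census of distinct binary across-entity expression patterns.

    Returns distinct pattern count (including the all-zero pattern when
    present), the non-zero pattern count, per-pattern gene groups, and the
    pattern-frequency-by-set-bit-count summary.
    """
    called = annotation.pairs.groupby("gene")["entity"].apply(set).to_dict()
    ent_index = {e: i for i, e in enumerate(entities)}
    patterns: dict[str, list[str]] = {}
    for g in genes:
        bits = ["0"] * len(entities)
        for e in called.get(g, ()):  # genes without calls get the zero pattern
            bits[ent_index[e]] = "1"
        patterns.setdefault("".join(bits), []).append(g)
    zero = "0" * len(entities)
    by_bits: dict[int, int] = {}
    for p in patterns:
        by_bits[p.count("1")] = by_bits.get(p.count("1"), 0) + 1
    return {
        "n_distinct_patterns": len(patterns),
        "n_nonzero_patterns": len(patterns) - (1 if zero in patterns else 0),
        "groups": {p: sorted(gs) for p, gs in patterns.items()},
        "patterns_by_tissue_count": dict(sorted(by_bits.items())),
    }


def ideal_housekeeping_profile(
    entity_meta: dict[str, str], entities: list[str], level_ppm: float = 10_000.0
) -> pd.Series:
    """In silico ideal housekeeping vector: level_ppm in tissues/cells, 0 in fluids."""
    vals = [0.0 if entity_meta.get(e) == "body fluid" else level_ppm for e in entities]
    return pd.Series(vals, index=entities, name="ideal_housekeeping")


def housekeeping_score(
    matrix: pd.DataFrame,
    entity_meta: dict[str, str],
    gene: str | None = None,
    level_ppm: float = 10_000.0,
    log_space: bool = True,
) -> pd.Series | float:
    """Pearson similarity of gene vectors to the ideal housekeeping profile.

    Both the gene vectors and the ideal profile go through the matrix's
    log-shift transform by default (``log_space=False`` correlates raw
    PPM).  Genes constant after transform have an undefined score (NaN).
    """
    entities = list(matrix.columns)
    ideal = ideal_housekeeping_profile(entity_meta, entities, level_ppm)
    if log_space:
        joint = pd.concat([matrix, ideal.to_frame().T])
        transformed, _ = log_shift(joint)
        x = transformed.iloc[:-1]
        ideal_v = transformed.iloc[-1].to_numpy()
    else:
        x = matrix
        ideal_v = ideal.to_numpy()
    xv = x.to_numpy(dtype=float)
    xc = xv - xv.mean(axis=1, keepdims=True)
    ic = ideal_v - ideal_v.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (ic**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (xc @ ic) / denom, np.nan)
    out = pd.Series(scores, index=x.index, name="housekeeping_score")
    if gene is not None:
        if gene not in out.index:
            raise KeyError(f"unknown gene: {gene}")
        return float(out[gene])
    return out
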