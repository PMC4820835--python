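"""Pairwise expression similarity, permutation null, and the partner graph.

Expression similarity between genes is the Pearson correlation of their
log-shifted entity vectors (zeros kept at 0 — absence is informative).
Gene pairs with r strictly above the cutoff (default 0.7, the mean of two
cutoff-optimization readings of 0.6 and 0.8) are "expression partners";
an edge is flagged "elite" when the pair is also partnered on the RNA
scale.  A per-gene permutation null and binned fraction-ratio enrichment
curves support the metric's validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PartnerGraph:
    """Undirected expression-partner edges (geneA < geneB, r > cutoff)."""

    edges: pd.DataFrame  # columns gene_a, gene_b, r, elite
    cutoff: float
    partner_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, r=row.r, elite=bool(row.elite))
        return g


def _usable_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = [g for g, s in zip(matrix.index, sd) if s == 0]
    return matrix.loc[sd > 0], degenerate


def pairwise_correlations(
    matrix: pd.DataFrame, genes: list[str] | None = None
) -> tuple[pd.Series, list[str]]:
    """Pearson r for every unordered gene pair of log-shift vectors.

    Returns (condensed series indexed by (gene_a, gene_b) with a < b,
    excluded zero-variance genes).  Raises if fewer than two usable genes.
    """
    sub = matrix.loc[genes] if genes is not None else matrix
    usable, excluded = _usable_rows(sub)
    if usable.shape[0] < 2:
        raise ValueError("need at least two genes with non-zero variance")
    r = np.corrcoef(usable.to_numpy(dtype=float))
    names = list(usable.index)
    iu = np.triu_indices(len(names), k=1)
    index = pd.MultiIndex.from_arrays(
        [np.asarray(names)[iu[0]], np.asarray(names)[iu[1]]], names=["gene_a", "gene_b"]
    )
    return pd.Series(r[iu], index=index, name="r"), excluded


def correlation_block(matrix: pd.DataFrame, block_size: int = 2000) -> pd.DataFrame:
    """Full gene x gene correlation matrix computed in row blocks.

    Identical to the dense path; the blocking only bounds peak memory for
    large gene sets.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    centered = values - mean
    norms = np.sqrt((centered**2).sum(axis=1))
    out = np.empty((len(values), len(values)))
    for start in range(0, len(values), block_size):
        stop = min(start + block_size, len(values))
        num = centered[start:stop] @ centered.T
        with np.errstate(invalid="ignore", divide="ignore"):
            out[start:stop] = num / np.outer(norms[start:stop], norms)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.index)


def permutation_null(
    matrix: pd.DataFrame, seed: int, n_pairs: int | None = None
) -> pd.Series | np.ndarray:
    """Null pairwise correlations after permuting every gene's entity vector.

    Each gene's vector is independently permuted (same multiset of values
    per gene).  With ``n_pairs`` set, that many random pairs are sampled
    from the permuted matrix instead of computing all pairs.
    """
    rng = np.random.default_rng(seed)
    values = matrix.to_numpy(dtype=float).copy()
    for i in range(values.shape[0]):
        rng.shuffle(values[i])
    permuted = pd.DataFrame(values, index=matrix.index, columns=matrix.columns)
    if n_pairs is None:
        null, _ = pairwise_correlations(permuted)
        return null
    usable, _ = _usable_rows(permuted)
    v = usable.to_numpy(dtype=float)
    v = v - v.mean(axis=1, keepdims=True)
    norms = np.sqrt((v**2).sum(axis=1))
    n = len(v)
    ia = rng.integers(0, n, n_pairs)
    ib = rng.integers(0, n - 1, n_pairs)
    ib = np.where(ib >= ia, ib + 1, ib)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v[ia] * v[ib]).sum(axis=1) / (norms[ia] * norms[ib])
    return r[np.isfinite(r)]


def distribution_enrichment(
    real: np.ndarray,
    reference: np.ndarray,
    bin_width: float = 0.02,
    min_fraction: float = 8e-5,
) -> tuple[pd.DataFrame, float]:
    """Binned fraction-ratio curve of two correlation samples + rank-sum p.

    Both samples are binned over [-1, 1] with the same bins and converted
    to fractions; the per-bin ratio real/reference is reported with bins of
    extremely low fraction (< min_fraction on either side) masked.  The
    p-value is a one-sided Wilcoxon rank-sum test for real > reference.
    """
    real = np.asarray(real, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if real.size == 0 or reference.size == 0:
        raise ValueError("both correlation samples must be non-empty")
    edges = np.arange(-1.0, 1.0 + bin_width / 2, bin_width)
    if len(edges) < 3:
        raise ValueError("degenerate single-bin histogram")
    f_real = np.histogram(real, bins=edges)[0] / real.size
    f_ref = np.histogram(reference, bins=edges)[0] / reference.size
    masked = (f_real < min_fraction) | (f_ref < min_fraction)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(masked, np.nan, f_real / f_ref)
    table = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "fraction_real": f_real,
            "fraction_reference": f_ref,
            "ratio": ratio,
            "masked": masked,
        }
    )
    p = stats.mannwhitneyu(real, reference, alternative="greater").pvalue
    return table, float(p)


def build_partner_graph(
    correlations: pd.Series,
    cutoff: float = 0.7,
    rna_matrix: pd.DataFrame | None = None,
    rna_cutoff: float | None = None,
) -> PartnerGraph:
    """Edges for pairs with r strictly above the cutoff, with elite flags.

    ``rna_matrix`` holds RNA entity vectors (same log-shift convention as
    the protein side); an edge is elite when the same pair's RNA-side
    correlation also exceeds the (RNA) cutoff.
    """
    hits = correlations[correlations > cutoff]
    edges = hits.rename("r").reset_index()
    edges["elite"] = False
    if rna_matrix is not None and len(edges):
        rc = rna_cutoff if rna_cutoff is not None else cutoff
        rna_genes = set(rna_matrix.index)
        rows = rna_matrix.to_numpy(dtype=float)
        centered = rows - rows.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        idx = {g: i for i, g in enumerate(rna_matrix.index)}
        elite = []
        for a, b in zip(edges["gene_a"], edges["gene_b"]):
            if a in rna_genes and b in rna_genes:
                ia, ib = idx[a], idx[b]
                denom = norms[ia] * norms[ib]
                r = float((centered[ia] * centered[ib]).sum() / denom) if denom > 0 else np.nan
                elite.append(bool(np.isfinite(r) and r > rc))
            else:
                elite.append(False)
        edges["elite"] = elite
    counts = (
        pd.concat([edges["gene_a"], edges["gene_b"]]).value_counts().sort_index()
        if len(edges)
        else pd.Series(dtype=int)
    )
    return PartnerGraph(edges=edges, cutoff=cutoff, partner_counts=counts.rename("n_partners"))


def and_metric(matrix: pd.DataFrame, gene_a: str, gene_b: str) -> int:
    """Number of entities where both genes have non-zero abundance."""
    for g in (gene_a, gene_b):
        if g not in matrix.index:
            raise KeyError(f"unknown gene: {g}")
    return int(((matrix.loc[gene_a] > 0) & (matrix.loc[gene_b] > 0)).sum())


def cutoff_diagnostics(correlations: pd.Series, cutoff_grid: list[float]) -> pd.DataFrame:
    """Per-cutoff gene coverage and partner-count statistics.

    Used to pick a partnering cutoff reconciling promiscuous partnering
    (high mean degree) with scarcity of genes that have any partner (low
    coverage); also reports knee-point candidates via maximum curvature.
    """
    if not list(cutoff_grid):
        raise ValueError("empty cutoff grid")
    genes = sorted(set(correlations.index.get_level_values(0)) | set(correlations.index.get_level_values(1)))
    rows = []
    for c in cutoff_grid:
        hits = correlations[correlations > c]
        n_edges = len(hits)
        if n_edges:
            deg = pd.concat(
                [hits.reset_index()["gene_a"], hits.reset_index()["gene_b"]]
            ).value_counts()
            coverage = len(deg) / len(genes)
            mean_deg = 2 * n_edges / len(genes)
            max_deg = int(deg.max())
        else:
            coverage, mean_deg, max_deg = 0.0, 0.0, 0
        rows.append(
            {
                "cutoff": c,
                "n_edges": n_edges,
                "gene_coverage": coverage,
                "mean_partner_count": mean_deg,
                "max_partner_count": max_deg,
            }
        )
    return pd.DataFrame(rows)


def knee_points(diagnostics: pd.DataFrame) -> dict[str, float]:
    """Max-curvature cutoff candidates from the coverage and mean-degree curves."""
    out = {}
    for col in ("gene_coverage", "mean_partner_count"):
        y = diagnostics[col].to_numpy(dtype=float)
        x = diagnostics["cutoff"].to_numpy(dtype=float)
        if len(y) < 3:
            out[col] = float(x[len(x) // 2])
            continue
        curvature = np.abs(np.gradient(np.gradient(y, x), x))
        out[col] = float(x[int(np.argmax(curvature))])
    return out


def pair_set_enrichment(
    correlations: pd.Series,
    pair_set: set[tuple[str, str]],
    background: np.ndarray | None = None,
    bin_width: float = 0.02,
    min_fraction: float = 8e-5,
) -> tuple[pd.DataFrame, float]:
    """Fraction-ratio curve of a functional pair set against background pairs.

    ``pair_set`` holds unordered gene pairs (paralogs, shared-disease,
    PPI, shared-pathway...); pairs not present in the correlation index
    are dropped, and an empty intersection is an error.
    """
    normalized = {frozenset(p) for p in pair_set}
    idx = correlations.index
    mask = [frozenset(p) in normalized for p in idx]
    in_set = correlations[np.asarray(mask)]
    if in_set.empty:
        raise ValueError("pair set has empty intersection with the correlation index")
    bg = background if background is not None else correlations.to_numpy()
    return distribution_enrichment(
        in_set.to_numpy(), np.asarray(bg), bin_width=bin_width, min_fraction=min_fraction
    )


def read_pair_set(path) -> set[tuple[str, str]]:
    """Read a two-column TSV of gene pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return {tuple(sorted((a, b))) for a, b in zip(df[cols[0]], df[cols[1]])}
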