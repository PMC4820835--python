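"""Reading source tables, identifier symbolization, and gene-level aggregation.

Identifiers (UniProt-like, Ensembl-like, or plain symbols) are mapped to
gene symbols through an alias map.  Gene-level values are obtained by
summing a gene's proteins within a sample; a protein mapped to several
genes contributes its value equally divided among them, so total abundance
per sample is conserved.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SourceTable

SOURCE_COLUMNS = ("protein_id", "sample_id", "value")


def read_source_table(path: str | Path, source_name: str | None = None) -> SourceTable:
    """Read a source TSV (protein_id, sample_id, value, unit)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sample_id": str})
    missing = set(SOURCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    units = df["unit"].unique() if "unit" in df.columns else np.array(["PPM"])
    if len(units) != 1:
        raise ValueError(f"{path}: mixed units {sorted(units)}")
    name = source_name or path.stem.removeprefix("source_")
    return SourceTable(name=name, unit=str(units[0]), data=df[list(SOURCE_COLUMNS)].copy())


def read_alias_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column (identifier, symbol) TSV into identifier -> symbols."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"identifier", "symbol"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns identifier, symbol")
    out: dict[str, tuple[str, ...]] = {}
    for ident, grp in df.groupby("identifier"):
        syms = tuple(sorted(set(grp["symbol"].str.strip())))
        out[str(ident).strip()] = syms
    return out


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "source_name", "entity", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if "duplicate_group" not in df.columns:
        df["duplicate_group"] = df["sample_id"]
    return df


def symbolize(
    table: SourceTable, aliases: dict[str, tuple[str, ...]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map protein/gene identifiers to gene symbols.

    Returns (symbolized rows, reject report).  Symbolized rows keep the full
    symbol tuple per identifier; splitting of multi-gene proteins happens at
    aggregation so that mass conservation is checkable.  Unmappable
    identifiers are collected in the reject report, never silently dropped.
    """
    if not aliases:
        raise ValueError("alias map is empty")
    df = table.data
    if (df["value"] < 0).any():
        raise ValueError(f"{table.name}: negative abundance values")
    ids = df["protein_id"].str.strip()
    symbols = ids.map(aliases)
    unmapped = symbols.isna()
    rejects = (
        df.loc[unmapped, ["protein_id", "sample_id", "value"]]
        .assign(reason="unmapped identifier")
        .reset_index(drop=True)
    )
    if len(rejects):
        warnings.warn(
            f"{table.name}: {len(rejects)} rows with unmappable identifiers rejected",
            stacklevel=2,
        )
    out = df.loc[~unmapped].copy()
    out["symbols"] = symbols[~unmapped]
    return out.reset_index(drop=True), rejects


def aggregate_to_genes(symbolized: pd.DataFrame) -> pd.DataFrame:
    """Aggregate symbolized protein rows to a gene x sample wide table.

    Per gene and sample the value is the sum over the gene's proteins,
    where a protein mapped to k genes contributes value / k to each.
    Duplicate (protein, sample) rows are summed with a warning.
    """
    if (symbolized["value"] < 0).any():
        raise ValueError("negative abundance values")
    dup = symbolized.duplicated(subset=["protein_id", "sample_id"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (protein, sample) rows summed during aggregation",
            stacklevel=2,
        )
    n_genes = symbolized["symbols"].str.len()
    exploded = symbolized.assign(share=symbolized["value"] / n_genes).explode("symbols")
    wide = (
        exploded.groupby(["symbols", "sample_id"], sort=True)["share"]
        .sum()
        .unstack(fill_value=0.0)
    )
    wide.index.name = "gene"
    wide.columns.name = "sample_id"
    return wide


def aggregate_sources(
    tables: list[SourceTable], aliases: dict[str, tuple[str, ...]]
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Symbolize and aggregate every source; returns ({source: wide table}, rejects)."""
    aggregated: dict[str, pd.DataFrame] = {}
    reject_frames = []
    for t in tables:
        sym, rejects = symbolize(t, aliases)
        if len(rejects):
            reject_frames.append(rejects.assign(source_name=t.name))
        aggregated[t.name] = aggregate_to_genes(sym)
    all_rejects = (
        pd.concat(reject_frames, ignore_index=True)
        if reject_frames
        else pd.DataFrame(columns=["protein_id", "sample_id", "value", "reason", "source_name"])
    )
    return aggregated, all_rejects
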