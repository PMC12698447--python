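"""Clonotype-table summaries: subsampling, V-J pairing grids, locus pairing,
CDR3 spectratypes and diversity indices.

A clonotype table is a pandas DataFrame with columns ``v_name``, ``j_name``,
``cdr3_nt``, ``cdr3_aa``, ``count`` (reads or UMIs) and optionally
``d_name``; extra columns are carried through untouched.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("v_name", "j_name", "cdr3_nt", "cdr3_aa", "count")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clonotype table lacks columns: {missing}")
    if len(table) == 0:
        raise ValueError("empty clonotype table")
    if (table["count"] < 1).any():
        raise ValueError("clonotype counts must be >= 1")


def subsample(table: pd.DataFrame, n_reads: int, seed: int = 0) -> pd.DataFrame:
    """Draw ``n_reads`` reads without replacement (multivariate hypergeometric
    across clonotypes), re-aggregate, and return the reduced table.

    Deterministic for a fixed seed; the returned counts sum exactly to
    ``n_reads``. Raises when fewer reads are available than requested.
    """
    _check_table(table)
    counts = table["count"].to_numpy(dtype=np.int64)
    total = int(counts.sum())
    if total < n_reads:
        raise ValueError(f"cannot subsample {n_reads} reads from {total}")
    if total == n_reads:
        return table.reset_index(drop=True).copy()
    rng = np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(counts, n_reads)
    out = table.reset_index(drop=True).copy()
    out["count"] = new_counts
    out = out[out["count"] > 0].reset_index(drop=True)
    return out


def _weights(table: pd.DataFrame, weight: str) -> pd.Series:
    if weight == "reads":
        return table["count"].astype(float)
    if weight == "clonotypes":
        return pd.Series(1.0, index=table.index)
    raise ValueError("weight must be 'reads' or 'clonotypes'")


def vj_pairing_matrix(table: pd.DataFrame, weight: str = "clonotypes") -> pd.DataFrame:
    """Normalized V x J pairing grid over observed pairs (entries sum to 1)."""
    _check_table(table)
    w = _weights(table, weight)
    grid = pd.crosstab(table["v_name"], table["j_name"], values=w,
                       aggfunc="sum", dropna=False).fillna(0.0)
    return grid / grid.to_numpy().sum()


def locus_pairing_fractions(table: pd.DataFrame, locus_of: dict,
                            weight: str = "clonotypes") -> dict:
    """Fractions of clonotypes pairing within each locus, plus the cross-locus
    fraction. Values sum to 1. Unmapped gene names are an error."""
    _check_table(table)
    unmapped = sorted({g for g in pd.concat([table["v_name"], table["j_name"]])
                       if g not in locus_of})
    if unmapped:
        raise KeyError(f"genes not mapped to a locus: {unmapped}")
    w = _weights(table, weight).to_numpy()
    v_loc = table["v_name"].map(locus_of).to_numpy()
    j_loc = table["j_name"].map(locus_of).to_numpy()
    total = w.sum()
    out: dict[str, float] = {}
    within = v_loc == j_loc
    for locus in sorted(set(v_loc) | set(j_loc)):
        out[f"within_{locus}"] = float(w[within & (v_loc == locus)].sum() / total)
    out["cross_locus"] = float(w[~within].sum() / total)
    return out


def spectratype(table: pd.DataFrame, weight: str = "reads") -> tuple[pd.Series, float]:
    """CDR3 amino-acid length histogram (normalized) and its weighted mean.

    Default weighting is by clonotype abundance (each clone contributes its
    read/UMI count); ``weight='clonotypes'`` counts each clone once.
    """
    _check_table(table)
    w = _weights(table, weight)
    lengths = table["cdr3_aa"].str.len()
    hist = w.groupby(lengths).sum()
    hist = hist / hist.sum()
    hist.index.name = "cdr3_aa_length"
    mean = float((hist.index.to_numpy() * hist.to_numpy()).sum())
    return hist, mean


def diversity(table: pd.DataFrame) -> dict:
    """Clonotype richness, Shannon entropy (nats) and Gini-Simpson index of
    the read-fraction distribution."""
    _check_table(table)
    counts = table["count"].to_numpy(dtype=float)
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    return {
        "richness": int(len(table)),
        "shannon": shannon,
        "gini_simpson": float(1.0 - (p ** 2).sum()),
    }


def read_clonotypes(path: str) -> pd.DataFrame:
    # keep_default_na=False so empty junction-insert strings survive as ""
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    _check_table(table)
    return table


def write_clonotypes(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
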