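"""FPKM chain-expression summaries and windowed-coverage diagnostics.

The coverage check addresses a specific assembly question: if an apparently
duplicated locus were in fact two haplotypes of one locus (a retained
haplotig), whole-genome read depth inside it would drop to about half of the
flanking level. ``haplotig_test`` compares median 10-kb window depth inside
the locus against the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def fpkm(count: float, gene_length: int, library_size: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if gene_length <= 0 or library_size <= 0:
        raise ValueError("gene_length and library_size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / (gene_length / 1000.0) / (library_size / 1_000_000.0)


def fpkm_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add an ``fpkm`` column to a table with ``count``, ``gene_length``,
    ``library_size`` columns (one row per sample x gene)."""
    req = {"count", "gene_length", "library_size"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    out = records.copy()
    out["fpkm"] = [fpkm(c, l, s) for c, l, s in
                   zip(out["count"], out["gene_length"], out["library_size"])]
    return out


def chain_expression(records: pd.DataFrame, chain_map: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample per-chain FPKM (sum over the chain's C genes) and per-stage
    means.

    ``records`` columns: sample, stage, gene, count, gene_length,
    library_size (optionally tissue). ``chain_map`` maps each C-gene id to
    exactly one chain; a gene mapped twice is an error.
    """
    genes = list(chain_map)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene in chain map")
    unmapped = sorted(set(records["gene"]) - set(genes))
    if unmapped:
        raise KeyError(f"genes without a chain assignment: {unmapped}")
    tab = fpkm_table(records)
    tab["chain"] = tab["gene"].map(chain_map)
    per_sample = (tab.groupby(["sample", "stage", "chain"], as_index=False)["fpkm"]
                  .sum())
    per_stage = (per_sample.groupby(["stage", "chain"], as_index=False)["fpkm"]
                 .mean().rename(columns={"fpkm": "mean_fpkm"}))
    return per_sample, per_stage


@dataclass(frozen=True)
class WindowCoverage:
    start: int
    end: int
    mean_depth: float
    partial: bool = False


def window_coverage(depth: pd.DataFrame, window: int = 10_000) -> list[WindowCoverage]:
    """Mean depth in fixed-width windows from a sorted BED-like depth table
    (columns chrom, start, end, depth). The trailing partial window carries
    ``partial=True``."""
    if not {"start", "end", "depth"}.issubset(depth.columns):
        raise ValueError("depth table needs start/end/depth columns")
    starts = depth["start"].to_numpy()
    ends = depth["end"].to_numpy()
    if np.any(np.diff(starts) < 0):
        raise ValueError("depth input must be sorted by start")
    if len(starts) == 0:
        return []
    d = depth["depth"].to_numpy(dtype=float)
    region_end = int(ends.max())
    out = []
    for wstart in range(int(starts.min()) // window * window, region_end, window):
        wend = min(wstart + window, region_end)
        ov = np.minimum(ends, wend) - np.maximum(starts, wstart)
        ov = np.clip(ov, 0, None).astype(float)
        covered = ov.sum()
        if covered == 0:
            continue
        out.append(WindowCoverage(start=wstart, end=wend,
                                  mean_depth=float((d * ov).sum() / covered),
                                  partial=wend - wstart < window))
    return out


def haplotig_test(windows: list[WindowCoverage], locus_interval: tuple[int, int],
                  flank: int = 1_000_000,
                  haplotig_band: tuple[float, float] = (0.35, 0.65),
                  duplication_band: tuple[float, float] = (0.8, 1.25)) -> tuple[float, str]:
    """Locus-to-flank median depth ratio and a verdict.

    "suspect_haplotig" when the ratio falls in the band around 0.5 (the locus
    holds only one of two haplotypes' reads), "consistent_with_duplication"
    around 1.0, otherwise "inconclusive". The ratio is scale-invariant.
    """
    a, b = locus_interval
    locus = [w.mean_depth for w in windows if w.start >= a and w.end <= b]
    flank_ws = [w.mean_depth for w in windows
                if (a - flank <= w.start and w.end <= a) or
                   (b <= w.start and w.end <= b + flank)]
    if not locus or not flank_ws:
        raise ValueError("locus or flank not covered by any window")
    ratio = float(np.median(locus) / np.median(flank_ws))
    if haplotig_band[0] <= ratio <= haplotig_band[1]:
        verdict = "suspect_haplotig"
    elif duplication_band[0] <= ratio <= duplication_band[1]:
        verdict = "consistent_with_duplication"
    else:
        verdict = "inconclusive"
    return ratio, verdict
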