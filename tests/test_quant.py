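import math

import numpy as np
import pandas as pd
import pytest

from tcrlocus import (chain_expression, fpkm, fpkm_table, haplotig_test,
                      simulate_depth, window_coverage)
from tcrlocus.quant import WindowCoverage


# ---------------------------------------------------------------------------
# FPKM


def test_fpkm_closed_forms():
    assert fpkm(100, 1000, 1_000_000) == pytest.approx(100.0, rel=1e-12)
    assert fpkm(0, 500, 2_000_000) == 0.0
    # scale relations: doubling length halves, doubling library halves
    base = fpkm(37, 1234, 5_000_000)
    assert fpkm(37, 2468, 5_000_000) == pytest.approx(base / 2, rel=1e-12)
    assert fpkm(37, 1234, 10_000_000) == pytest.approx(base / 2, rel=1e-12)
    assert fpkm(74, 1234, 5_000_000) == pytest.approx(base * 2, rel=1e-12)


def test_fpkm_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fpkm(10, 0, 1000)
    with pytest.raises(ValueError):
        fpkm(10, 100, 0)
    with pytest.raises(ValueError):
        fpkm(-1, 100, 1000)


def test_fpkm_table_matches_scalar():
    tab = pd.DataFrame({"count": [10, 20], "gene_length": [500, 1500],
                        "library_size": [1_000_000, 2_000_000]})
    out = fpkm_table(tab)
    for row in out.itertuples():
        assert row.fpkm == fpkm(row.count, row.gene_length, row.library_size)
    with pytest.raises(ValueError):
        fpkm_table(tab.drop(columns=["gene_length"]))


def test_chain_expression_sums_and_stage_means():
    records = pd.DataFrame({
        "sample": ["s1", "s1", "s1", "s2", "s2", "s2"],
        "stage": ["larva", "larva", "larva", "larva", "larva", "larva"],
        "gene": ["TRBC1", "TRBC2", "TRAC", "TRBC1", "TRBC2", "TRAC"],
        "count": [10, 20, 30, 40, 50, 60],
        "gene_length": [1000] * 6,
        "library_size": [1_000_000] * 6,
    })
    chain_map = {"TRBC1": "TRB", "TRBC2": "TRB", "TRAC": "TRA"}
    per_sample, per_stage = chain_expression(records, chain_map)
    s1_trb = per_sample.query("sample == 's1' and chain == 'TRB'")["fpkm"].iloc[0]
    assert s1_trb == pytest.approx(30.0, rel=1e-12)
    trb_mean = per_stage.query("chain == 'TRB'")["mean_fpkm"].iloc[0]
    assert trb_mean == pytest.approx((30.0 + 90.0) / 2, rel=1e-12)


def test_chain_expression_unmapped_gene_errors():
    records = pd.DataFrame({
        "sample": ["s1"], "stage": ["adult"], "gene": ["TRDC"],
        "count": [5], "gene_length": [900], "library_size": [1_000_000]})
    with pytest.raises(KeyError):
        chain_expression(records, {"TRAC": "TRA"})


# ---------------------------------------------------------------------------
# window coverage


def test_window_coverage_overlap_weighted_mean():
    depth = pd.DataFrame({
        "chrom": ["c"] * 2,
        "start": [0, 15_000],
        "end": [15_000, 25_000],
        "depth": [10.0, 30.0],
    })
    ws = window_coverage(depth, window=10_000)
    assert len(ws) == 3
    assert ws[0].mean_depth == pytest.approx(10.0)
    # second window: 5 kb at 10x + 5 kb at 30x
    assert ws[1].mean_depth == pytest.approx(20.0)
    assert ws[2].mean_depth == pytest.approx(30.0)
    assert ws[2].partial and ws[2].end == 25_000
    assert not ws[0].partial


def test_window_coverage_requires_sorted_input():
    depth = pd.DataFrame({"chrom": ["c", "c"], "start": [100, 0],
                          "end": [200, 100], "depth": [1.0, 2.0]})
    with pytest.raises(ValueError, match="sorted"):
        window_coverage(depth)


def test_window_coverage_empty():
    depth = pd.DataFrame({"chrom": [], "start": [], "end": [], "depth": []})
    assert window_coverage(depth) == []


# ---------------------------------------------------------------------------
# haplotig test


def _flat_windows(locus_ratio):
    ws = []
    for i in range(100):
        ws.append(WindowCoverage(i * 10_000, (i + 1) * 10_000, 30.0))
    for i in range(100, 150):
        ws.append(WindowCoverage(i * 10_000, (i + 1) * 10_000,
                                 30.0 * locus_ratio))
    for i in range(150, 250):
        ws.append(WindowCoverage(i * 10_000, (i + 1) * 10_000, 30.0))
    return ws, (1_000_000, 1_500_000)


def test_haplotig_bands_give_expected_verdicts():
    for ratio, verdict in ((0.5, "suspect_haplotig"),
                           (1.0, "consistent_with_duplication"),
                           (0.72, "inconclusive")):
        ws, interval = _flat_windows(ratio)
        got_ratio, got = haplotig_test(ws, interval)
        assert got == verdict
        assert got_ratio == pytest.approx(ratio, rel=1e-12)


def test_haplotig_ratio_is_scale_invariant():
    ws, interval = _flat_windows(0.5)
    scaled = [WindowCoverage(w.start, w.end, w.mean_depth * 7.3) for w in ws]
    r1, _ = haplotig_test(ws, interval)
    r2, _ = haplotig_test(scaled, interval)
    assert r1 == pytest.approx(r2, rel=1e-12)


def test_haplotig_requires_coverage():
    ws, _ = _flat_windows(0.5)
    with pytest.raises(ValueError):
        haplotig_test(ws, (10_000_000, 10_100_000))


def test_haplotig_on_simulated_depth_both_scenarios():
    interval = (1_000_000, 1_500_000)
    dep = simulate_depth(2_500_000, 30.0, interval, seed=11)
    ws = window_coverage(dep)
    ratio, verdict = haplotig_test(ws, interval)
    assert verdict == "suspect_haplotig"
    dep2 = simulate_depth(2_500_000, 30.0, None, seed=12)
    ratio2, verdict2 = haplotig_test(window_coverage(dep2), interval)
    assert verdict2 == "consistent_with_duplication"
    assert ratio2 == pytest.approx(1.0, abs=0.1)
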