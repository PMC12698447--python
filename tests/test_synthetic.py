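import numpy as np
import pandas as pd
import pytest

from tcrlocus import (DefectSpec, LocusConfig, default_usage, generate_locus,
                      merge_truths, scan_rss, simulate_clonotypes)
from tcrlocus.seqs import revcomp, translate
from tcrlocus.synthetic import (clonotype_length_pmf, simulate_depth, _scrub)


def test_generation_is_deterministic():
    a = generate_locus(LocusConfig(seed=42))
    b = generate_locus(LocusConfig(seed=42))
    assert a.genome == b.genome
    assert [s.key() for s in a.segments] == [s.key() for s in b.segments]


def test_different_seeds_differ():
    a = generate_locus(LocusConfig(seed=1))
    b = generate_locus(LocusConfig(seed=2))
    assert a.genome != b.genome


def test_scrub_removes_start_codons_both_strands():
    rng = np.random.default_rng(0)
    raw = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
    s = _scrub(raw, rng)
    assert "ATG" not in s
    assert "ATG" not in revcomp(s)
    assert len(s) == len(raw)


def test_planted_rss_hits_are_recovered_by_scan(small_truth):
    t = small_truth
    hits23 = {(h.heptamer_start, h.strand) for h in scan_rss(t.genome, 23)}
    for v in t.segments_of("V"):
        assert (v.rss.heptamer_start, v.rss.strand) in hits23
    hits12 = {(h.heptamer_start, h.strand) for h in scan_rss(t.genome, 12)}
    for j in t.segments_of("J"):
        assert (j.rss.heptamer_start, j.rss.strand) in hits12


def test_v_exon_carries_conserved_features(small_truth):
    for v in small_truth.segments_of("V"):
        pep = translate(v.sequence(small_truth.genome))
        assert "*" not in pep
        assert pep.find("C") == 21
        assert pep[40] == "W"
        assert "C" in pep[-5:]


def test_j_carries_motif_and_donor(small_truth):
    t = small_truth
    for j in t.segments_of("J"):
        seq = j.sequence(t.genome)
        pep = translate(seq)
        assert "*" not in pep
        head = (j.conserved_positions["phe_g"] - j.start) // 3
        assert pep[head] == "F"
        assert pep[head + 1] == "G"
        assert pep[head + 3] == "G"
        assert t.genome[j.end:j.end + 2] == "GT"


def test_c_references_splice_back_onto_genome(small_truth):
    t = small_truth
    for c, ref in zip(t.segments_of("C"), t.c_references()):
        cdna = "".join(t.genome[a:b] for a, b in sorted(c.exons))
        assert ref == cdna


def test_defect_plan_sets_functionality():
    cfg = LocusConfig(seed=5, defect_plan=(
        DefectSpec("V", 0, "internal_stop"),
        DefectSpec("V", 1, "broken_rss"),
        DefectSpec("J", 0, "broken_splice"),
        DefectSpec("J", 1, "missing_motif"),
    ))
    t = generate_locus(cfg)
    funcs = sorted((s.kind, s.functionality) for s in t.segments
                   if s.kind in ("V", "J") and s.functionality != "F")
    assert funcs == [("J", "ORF"), ("J", "ORF"), ("V", "ORF"), ("V", "P")]


def test_reverse_orientation_is_exact_reflection():
    fwd = generate_locus(LocusConfig(seed=9))
    rev = generate_locus(LocusConfig(seed=9, scaffold_orientation="REV"))
    assert rev.genome == revcomp(fwd.genome)
    L = len(fwd.genome)
    reflected = sorted((s.kind, L - s.end, L - s.start,
                        {"+": "-", "-": "+"}[s.strand]) for s in fwd.segments)
    assert reflected == sorted((s.kind, s.start, s.end, s.strand)
                               for s in rev.segments)


def test_family_plan_identities_hold():
    from tcrlocus import pairwise_identity

    cfg = LocusConfig(seed=11, v_clusters=(("FWD", 5),),
                      family_plan=((3, 85.0, 60.0), (2, 90.0, 60.0)))
    t = generate_locus(cfg)
    by_fam = {}
    for v in t.segments_of("V"):
        by_fam.setdefault(v.family, []).append(v.sequence(t.genome))
    for fam, (size, within, between) in zip((1, 2), cfg.family_plan):
        assert len(by_fam[fam]) == size
    for a in by_fam[1]:
        for b in by_fam[2]:
            assert pairwise_identity(a, b) <= 65.0
    # members derive from their family founder at the planned identity (the
    # founder's locus position is shuffled); single linkage co-clusters each
    # family through the founder even when member-member identity is lower
    for fam, (_, within, _) in zip((1, 2), cfg.family_plan):
        seqs = by_fam[fam]
        assert any(all(pairwise_identity(f, s) >= within - 2.0
                       for s in seqs if s is not f) for f in seqs)


def test_clonotype_counts_conserved_and_reproducible(small_truth):
    usage = default_usage(small_truth)
    assert usage["prob"].sum() == pytest.approx(1.0)
    a = simulate_clonotypes(small_truth, usage, 2000, seed=3)
    b = simulate_clonotypes(small_truth, usage, 2000, seed=3)
    pd.testing.assert_frame_equal(a, b)
    assert a["count"].sum() == 2000
    key = ["v_name", "j_name", "cdr3_nt", "trim_v", "trim_j", "insert_nt"]
    assert (a.groupby(key).size() == 1).all()


def test_clonotype_cdr3_aa_is_translation(small_truth):
    tab = simulate_clonotypes(small_truth, None, 500, seed=1)
    for row in tab.itertuples():
        assert row.cdr3_aa == translate(row.cdr3_nt)
        assert len(row.cdr3_nt) % 3 == 0


def test_length_pmf_matches_empirical_spectratype(small_truth):
    usage = default_usage(small_truth)
    pmf = clonotype_length_pmf(small_truth, usage)
    assert sum(pmf.values()) == pytest.approx(1.0)
    tab = simulate_clonotypes(small_truth, usage, 30000, seed=8)
    n = tab["count"].sum()
    obs = tab.groupby(tab["cdr3_aa"].str.len())["count"].sum() / n
    for length, p in pmf.items():
        se = max((p * (1 - p) / n) ** 0.5, 1e-9)
        assert abs(obs.get(length, 0.0) - p) < 5 * se + 1e-12


def test_merged_truth_supports_cross_locus_pairs():
    a = generate_locus(LocusConfig(seed=1, locus_label="TRA1"))
    b = generate_locus(LocusConfig(seed=2, locus_label="TRG1",
                                   v_clusters=(("FWD", 3),)))
    m = merge_truths(a, b, seed=3)
    usage = m.clonotype_model
    cross = usage[[r.v_name[:4] != r.j_name[:4] for r in usage.itertuples()]]
    assert len(cross) > 0
    tab = simulate_clonotypes(m, usage, 1000, seed=4)
    assert tab["count"].sum() == 1000


def test_merge_requires_distinct_labels():
    a = generate_locus(LocusConfig(seed=1))
    with pytest.raises(ValueError):
        merge_truths(a, a)


def test_depth_track_halves_inside_interval():
    dep = simulate_depth(500_000, 40.0, (200_000, 300_000), seed=6)
    mid = dep[(dep["start"] >= 200_000) & (dep["end"] <= 300_000)]["depth"].mean()
    out = dep[(dep["end"] <= 200_000) | (dep["start"] >= 300_000)]["depth"].mean()
    assert mid == pytest.approx(20.0, rel=0.05)
    assert out == pytest.approx(40.0, rel=0.05)


def test_depth_track_empty_genome():
    assert len(simulate_depth(0, 30.0, None, seed=0)) == 0


def test_invalid_configs_raise():
    with pytest.raises(ValueError):
        LocusConfig(n_c=0).validate()
    with pytest.raises(ValueError):
        LocusConfig(scaffold_orientation="X").validate()
    with pytest.raises(ValueError):
        LocusConfig(family_plan=((3, 80.0, 90.0),),
                    v_clusters=(("FWD", 3),)).validate()
    with pytest.raises(ValueError):
        LocusConfig(defect_plan=(DefectSpec("V", 0, "nope"),)).validate()
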