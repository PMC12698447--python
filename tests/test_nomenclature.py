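import numpy as np
import pytest

from tcrlocus import (LocusConfig, annotate_locus, assign_names, cdr3_anchors,
                      cdr3_sequence, cluster_families, determine_orientation,
                      generate_locus, pairwise_identity)
from tcrlocus.model import GeneSegment, LocusAnnotation
from tcrlocus.seqs import revcomp, translate


# ---------------------------------------------------------------------------
# pairwise identity


def test_identity_identical_sequences():
    assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0


def test_identity_hand_counted():
    a = "ACGTACGTAC"
    b = "ACGTACGTAA"  # 9 of 10 positions match, no gaps needed
    assert pairwise_identity(a, b) == pytest.approx(90.0)


def test_identity_symmetry():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=75))
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


def test_identity_ignores_terminal_overhang():
    # overhang bases chosen so they cannot re-align against the core
    core = "ACGTACGTACGTACGTACGT"
    assert pairwise_identity(core, "TT" + core + "CC") == pytest.approx(100.0)


def test_identity_empty_sequence_errors():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


# ---------------------------------------------------------------------------
# family clustering


def _segs_with_seqs(seqs):
    segs, genome, pos = [], [], 0
    for s in seqs:
        segs.append(GeneSegment(kind="V", start=pos, end=pos + len(s), strand="+"))
        genome.append(s)
        pos += len(s)
    return segs, "".join(genome)


def _mutated(rng, seq, n):
    s = list(seq)
    for p in rng.choice(len(s), size=n, replace=False):
        s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
    return "".join(s)


def test_single_linkage_chains_through_intermediate():
    rng = np.random.default_rng(1)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    pos = rng.choice(300, size=105, replace=False)
    s = list(a)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for p in pos[:60]:
        s[p] = flip[s[p]]
    b = "".join(s)                       # a-b: 240/300 = 80%
    for p in pos[60:]:
        s[p] = flip[s[p]]
    c = "".join(s)                       # b-c: 255/300 = 85%; a-c: 195/300 = 65%
    assert pairwise_identity(a, b) == pytest.approx(80.0)
    assert pairwise_identity(b, c) == pytest.approx(85.0)
    # the aligner may squeeze out slightly more than the ungapped 65%, but
    # a and c must stay clearly below the 75% family threshold
    assert pairwise_identity(a, c) < 70.0
    segs, genome = _segs_with_seqs([a, b, c])
    fams = cluster_families(segs, genome)
    assert len(set(fams)) == 1  # chained into one family via b


def test_exact_threshold_is_inclusive():
    rng = np.random.default_rng(2)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    b = _mutated(rng, a, 75)  # exactly 225/300 = 75.0%
    assert pairwise_identity(a, b) == pytest.approx(75.0)
    segs, genome = _segs_with_seqs([a, b])
    fams = cluster_families(segs, genome)
    assert fams[0] == fams[1]


def test_below_threshold_separates():
    rng = np.random.default_rng(4)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    b = _mutated(rng, a, 120)  # 60%
    segs, genome = _segs_with_seqs([a, b])
    fams = cluster_families(segs, genome)
    assert fams[0] != fams[1]


def test_families_numbered_from_five_prime():
    rng = np.random.default_rng(5)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    b = _mutated(rng, a, 120)
    segs, genome = _segs_with_seqs([a, b])
    cluster_families(segs, genome)
    assert segs[0].family == 1 and segs[1].family == 2
    # in a REV locus the rightmost segment is 5'-most
    segs2, genome2 = _segs_with_seqs([a, b])
    for s in segs2:
        s.strand = "-"
    cluster_families(segs2, genome2, orientation="REV")
    assert segs2[1].family == 1 and segs2[0].family == 2


# ---------------------------------------------------------------------------
# orientation and naming


def test_orientation_follows_c_strand():
    plus_c = GeneSegment(kind="C", start=0, end=10, strand="+")
    minus_c = GeneSegment(kind="C", start=20, end=30, strand="-")
    assert determine_orientation([plus_c]) == "FWD"
    assert determine_orientation([minus_c]) == "REV"


def test_naming_single_c_unit(small_truth, small_result):
    names = [s.name for s in small_result.locus.in_locus_order()
             if s.kind == "J"]
    assert names == ["TRA1J1", "TRA1J2", "TRA1J3"]
    v_names = [s.name for s in small_result.locus.in_locus_order()
               if s.kind == "V"]
    assert v_names == [f"TRA1V1-{i}" for i in range(1, 6)]
    c_names = [s.name for s in small_result.locus.segments if s.kind == "C"]
    assert c_names == ["TRA1C"]


def test_naming_multi_c_units():
    t = generate_locus(LocusConfig(seed=21, locus_label="TRB",
                                   v_clusters=(("FWD", 2),), n_j=4, n_d=2,
                                   n_c=2))
    res = annotate_locus(t.genome, t.c_references(), locus_label="TRB",
                         scaffold=t.scaffold)
    j_names = sorted(s.name for s in res.locus.segments if s.kind == "J")
    assert j_names == ["TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-2"]
    c_names = sorted(s.name for s in res.locus.segments if s.kind == "C")
    assert c_names == ["TRBC1", "TRBC2"]
    d_names = sorted(s.name for s in res.locus.segments if s.kind == "D")
    assert d_names == ["TRBD1-1", "TRBD2-1"]


def test_assign_names_is_idempotent(small_result):
    locus = small_result.locus
    before = [s.name for s in locus.segments]
    assign_names(locus)
    assert [s.name for s in locus.segments] == before


def test_assign_names_requires_v_family():
    seg = GeneSegment(kind="V", start=0, end=30, strand="+")
    locus = LocusAnnotation(scaffold="s", locus_label="TRA", orientation="FWD",
                            segments=[seg])
    with pytest.raises(ValueError):
        assign_names(locus)


# ---------------------------------------------------------------------------
# CDR3


def test_cdr3_toy_example():
    # V: ...(C104 = TGT) then heptamer side; J: head TTT GGA CAA GGG ...
    v_exon = "GCA" * 20 + "TGT" + "GCA"
    j_gene = "AAA" + "TTT" + "GGA" + "CAA" + "GGG" + "CCC"
    genome = "AA" + v_exon + "TTTT" + j_gene + "GG"
    v = GeneSegment(kind="V", start=2, end=2 + len(v_exon), strand="+",
                    conserved_positions={"cys104": 2 + 60})
    j = GeneSegment(kind="J", start=2 + len(v_exon) + 4,
                    end=2 + len(v_exon) + 4 + len(j_gene), strand="+",
                    conserved_positions={"phe_g": 2 + len(v_exon) + 4 + 3})
    cdr3 = cdr3_sequence(genome, v, j, 0, 0, "")
    # anchors included: Cys codon .. Phe codon
    assert cdr3 == "TGT" + "GCA" + "AAA" + "TTT"
    assert translate(cdr3) == "CAKF"
    anchors = cdr3_anchors(v, j)
    assert anchors.v_anchor == 62
    # j_anchor is the last nucleotide of the Phe codon; FR4 starts just after
    assert anchors.j_anchor == j.conserved_positions["phe_g"] + 2
    assert anchors.fr4_start == anchors.j_anchor + 1


def test_cdr3_round_trip_on_simulated_clonotypes(small_truth):
    from tcrlocus import default_usage, simulate_clonotypes

    by_name = {s.name: s for s in small_truth.segments}
    tab = simulate_clonotypes(small_truth, default_usage(small_truth), 1500,
                              seed=2)
    for row in tab.itertuples():
        rec = cdr3_sequence(small_truth.genome, by_name[row.v_name],
                            by_name[row.j_name], row.trim_v, row.trim_j,
                            row.insert_nt)
        assert rec == row.cdr3_nt


def test_cdr3_rejects_trim_into_anchor(small_truth):
    vs = small_truth.segments_of("V")
    js = small_truth.segments_of("J")
    with pytest.raises(ValueError):
        cdr3_sequence(small_truth.genome, vs[0], js[0], 100, 0, "")


def test_cdr3_missing_anchor_errors():
    v = GeneSegment(kind="V", start=0, end=30, strand="+")
    j = GeneSegment(kind="J", start=40, end=70, strand="+",
                    conserved_positions={"phe_g": 43})
    with pytest.raises(ValueError):
        cdr3_anchors(v, j)
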