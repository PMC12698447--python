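"""V-family clustering, IMGT-style gene naming, and CDR3/FR4 anchoring.

Families group V genes at >=75% pairwise nucleotide identity (inclusive,
single linkage); family numbers ascend from the locus 5' end, as do gene
ranks within a family and J numbers. Locus orientation (FWD/REV) follows the
transcription orientation of the constant gene(s), so in a REV locus the
5'->3' order corresponds to descending scaffold coordinate.

The CDR3 convention used throughout: the region starts at the first
nucleotide of the conserved Cys (C104) codon of the V and ends at the last
nucleotide of the conserved Phe/Trp codon of the J [FW]GxG motif — both
anchor residues are included — and FR4 starts at the next transcript
position.
"""

from __future__ import annotations

from typing import Optional, Sequence

from Bio import Align

from .model import AnchorPair, GeneSegment, LocusAnnotation

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = -1.0
_aligner.open_gap_score = -2.0
_aligner.extend_gap_score = -0.5


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of a global alignment, excluding terminal-gap columns
    from the denominator (MatGat-like global mode). Symmetric."""
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if a == b:
        return 100.0
    # alignment tie-breaking depends on argument order; canonicalize so the
    # score is symmetric as documented
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aln = _aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    lead = max(len(s1) - len(s1.lstrip("-")), len(s2) - len(s2.lstrip("-")))
    trail = max(len(s1) - len(s1.rstrip("-")), len(s2) - len(s2.rstrip("-")))
    core1 = s1[lead:len(s1) - trail]
    core2 = s2[lead:len(s2) - trail]
    if not core1:
        return 0.0
    matches = sum(x == y and x != "-" for x, y in zip(core1, core2))
    return 100.0 * matches / len(core1)


def _locus_position(seg: GeneSegment, orientation: str) -> float:
    """Sort key for 5'->3' order in locus (transcription) orientation."""
    return float(seg.start) if orientation == "FWD" else float(-seg.end)


def cluster_families(v_segments: Sequence[GeneSegment], genome: Optional[str] = None,
                     threshold: float = 75.0, orientation: str = "FWD",
                     sequences: Optional[Sequence[str]] = None) -> list[int]:
    """Single-linkage clustering of V genes at >=``threshold``% identity.

    Returns family ids aligned with the input order and sets ``seg.family``.
    Family numbers ascend with each family's 5'-most member in locus
    orientation; the result is invariant to input order.
    """
    if not v_segments:
        raise ValueError("need at least one V segment")
    if sequences is None:
        if genome is None:
            raise ValueError("provide genome or sequences")
        sequences = [s.sequence(genome) for s in v_segments]
    n = len(v_segments)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(sequences[i], sequences[j]) >= threshold:
                parent[find(i)] = find(j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    ordered = sorted(comps.values(),
                     key=lambda idxs: min(_locus_position(v_segments[i], orientation)
                                          for i in idxs))
    fam_of = {}
    for fam_id, idxs in enumerate(ordered, start=1):
        for i in idxs:
            fam_of[i] = fam_id
    out = [fam_of[i] for i in range(n)]
    for seg, fam in zip(v_segments, out):
        seg.family = fam
    return out


def determine_orientation(segments: Sequence[GeneSegment]) -> str:
    """Locus orientation from C-gene transcription strand (IMGT convention)."""
    c = [s for s in segments if s.kind == "C"]
    if not c:
        raise ValueError("orientation requires at least one C gene")
    minus = sum(1 for s in c if s.strand == "-")
    return "REV" if minus * 2 > len(c) else "FWD"


def assign_names(locus: LocusAnnotation) -> LocusAnnotation:
    """Assign IMGT-style names in locus orientation.

    V: ``<locus>V<family>-<rank>`` (family rank from the 5' end);
    J: ``<locus>J<k>`` for single-C loci, ``<locus>J<cluster>-<rank>`` per
    C-J(-D) unit otherwise; C: ``<locus>C`` or ``<locus>C<k>``;
    D: ``<locus>D<k>`` / ``<locus>D<cluster>-<rank>``; L-PART1: ``<locus>L<k>``.
    Re-running on a named locus is idempotent.
    """
    if locus.orientation not in ("FWD", "REV"):
        locus.orientation = determine_orientation(locus.segments)
    label = locus.locus_label
    ordered = locus.in_locus_order()

    vs = [s for s in ordered if s.kind == "V"]
    for s in vs:
        if s.family is None:
            raise ValueError(f"V segment at {s.start} has no family assigned")
    rank: dict[int, int] = {}
    for s in vs:
        rank[s.family] = rank.get(s.family, 0) + 1
        s.name = f"{label}V{s.family}-{rank[s.family]}"

    cs = [s for s in ordered if s.kind == "C"]
    multi = len(cs) > 1
    for k, s in enumerate(cs, start=1):
        s.name = f"{label}C{k}" if multi else f"{label}C"

    # assign each J/D to the first C gene at or after it in locus order
    c_positions = [(_locus_position(s, locus.orientation), i + 1) for i, s in enumerate(cs)]

    def unit_of(seg: GeneSegment) -> int:
        p = _locus_position(seg, locus.orientation)
        for cp, idx in c_positions:
            if cp >= p:
                return idx
        return len(cs) if cs else 1

    j_count: dict[int, int] = {}
    j_total = 0
    for s in (x for x in ordered if x.kind == "J"):
        u = unit_of(s)
        j_count[u] = j_count.get(u, 0) + 1
        j_total += 1
        s.name = f"{label}J{u}-{j_count[u]}" if multi else f"{label}J{j_total}"

    d_count: dict[int, int] = {}
    d_total = 0
    d_segs = [x for x in ordered if x.kind == "D"]
    for s in d_segs:
        u = unit_of(s)
        d_count[u] = d_count.get(u, 0) + 1
        d_total += 1
        s.name = f"{label}D{u}-{d_count[u]}" if multi else f"{label}D{d_total}"

    for k, s in enumerate((x for x in ordered if x.kind == "L-PART1"), start=1):
        s.name = f"{label}L{k}"
    return locus


def cdr3_anchors(v: GeneSegment, j: GeneSegment) -> AnchorPair:
    """CDR3 anchor coordinates (plus-strand genome positions, transcript
    semantics): first nt of the V C104 codon, last nt of the J conserved
    Phe/Trp codon, and the FR4 start.

    Raises ValueError when a conserved position is missing — such segments
    must be flagged for review, not silently skipped.
    """
    if "cys104" not in v.conserved_positions:
        raise ValueError(f"V segment {v.name or v.start} lacks a C104 anchor")
    phe_src = j if "phe_g" in j.conserved_positions else v
    if "phe_g" not in phe_src.conserved_positions:
        raise ValueError(f"J segment {j.name or j.start} lacks a conserved-F anchor")
    cys = v.conserved_positions["cys104"]
    phe = phe_src.conserved_positions["phe_g"]
    if v.strand == "+":
        v_anchor = cys
    else:
        v_anchor = cys + 2
    if phe_src.strand == "+":
        j_anchor = phe + 2
        fr4 = j_anchor + 1
    else:
        j_anchor = phe
        fr4 = j_anchor - 1
    return AnchorPair(v_anchor=v_anchor, j_anchor=j_anchor, fr4_start=fr4)


def cdr3_sequence(genome: str, v: GeneSegment, j: GeneSegment,
                  trim_v: int = 0, trim_j: int = 0, insert: str = "") -> str:
    """Rearranged CDR3 nucleotide sequence implied by the anchors: V tail from
    the C104 codon, minus ``trim_v`` 3'-trimmed bases, the untemplated insert,
    and the J head through the conserved-F codon minus ``trim_j`` 5' bases.

    A pre-joined V region (fused germline V-J, carrying both anchors) yields
    its fixed germline CDR3; trims and insert must be zero for it.
    """
    cdr3_anchors(v, j)  # validates anchors
    v_seq = v.sequence(genome)
    cys_off = (v.conserved_positions["cys104"] - v.start if v.strand == "+"
               else v.end - (v.conserved_positions["cys104"] + 3))
    if "phe_g" in v.conserved_positions and (j is v or j.key() == v.key()):
        if trim_v or trim_j or insert:
            raise ValueError("a pre-joined V-J admits no trimming or insertion")
        phe_off = (v.conserved_positions["phe_g"] - v.start if v.strand == "+"
                   else v.end - (v.conserved_positions["phe_g"] + 3))
        return v_seq[cys_off:phe_off + 3]
    j_seq = j.sequence(genome)
    phe_off = (j.conserved_positions["phe_g"] - j.start if j.strand == "+"
               else j.end - (j.conserved_positions["phe_g"] + 3))
    v_tail = v_seq[cys_off:]
    j_head = j_seq[:phe_off + 3]
    if trim_v > len(v_tail) - 3 or trim_j > len(j_head) - 3:
        raise ValueError("trimming would remove an anchor codon")
    return v_tail[:len(v_tail) - trim_v] + insert + j_head[trim_j:]
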