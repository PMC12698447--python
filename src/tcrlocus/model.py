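"""Domain types for TCR locus annotation.

Coordinates are 0-based half-open on the plus strand of the scaffold.
``strand`` is "+" or "-". Segment ``kind`` is one of V, D, J, C, L-PART1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

SEGMENT_KINDS = ("V", "D", "J", "C", "L-PART1")
FUNCTIONALITY = ("F", "ORF", "P", "unassigned")


@dataclass(frozen=True)
class RSSHit:
    """One recombination signal sequence match in plus-strand coordinates.

    ``heptamer_start`` / ``nonamer_start`` are plus-strand starts of the
    respective 7-mer / 9-mer intervals. For a "+" hit the heptamer is the
    leftmost element (nonamer_start == heptamer_start + 7 + spacer_len); for a
    "-" hit the layout is mirrored (heptamer_start == nonamer_start + 9 +
    spacer_len) and the coding segment lies to the right of the heptamer.
    """

    heptamer_start: int
    spacer_len: int
    nonamer_start: int
    strand: str
    mismatches_heptamer: int
    mismatches_nonamer: int

    @property
    def score(self) -> int:
        return self.mismatches_heptamer + self.mismatches_nonamer

    @property
    def start(self) -> int:
        return min(self.heptamer_start, self.nonamer_start)

    @property
    def end(self) -> int:
        return max(self.heptamer_start + 7, self.nonamer_start + 9)

    @property
    def coding_boundary(self) -> int:
        """Plus-strand coordinate where the flanked coding segment abuts.

        For "+" hits the segment ends at ``heptamer_start``; for "-" hits it
        begins at ``heptamer_start + 7``.
        """
        return self.heptamer_start if self.strand == "+" else self.heptamer_start + 7


@dataclass
class GeneSegment:
    """One annotated V/D/J/C/L-PART1 element."""

    kind: str
    start: int
    end: int
    strand: str
    locus_label: str = ""
    functionality: str = "unassigned"
    family: Optional[int] = None
    name: Optional[str] = None
    # conserved_positions: plus-strand starts of anchor codons
    # (keys: first_cys, trp, cys104 for V; phe_g for J).
    conserved_positions: dict = field(default_factory=dict)
    rss: Optional[RSSHit] = None
    rss_3p: Optional[RSSHit] = None  # D genes carry two RSSs
    splice_donor: Optional[bool] = None
    splice_acceptor: Optional[bool] = None
    evidence: Optional["EvidenceRecord"] = None
    exons: list = field(default_factory=list)  # C genes: [(start, end), ...]
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.start < self.end:
            raise ValueError(f"empty segment interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def sequence(self, genome: str) -> str:
        """Segment sequence in transcription (5'->3') orientation."""
        from .seqs import revcomp

        s = genome[self.start:self.end]
        return s if self.strand == "+" else revcomp(s)

    def key(self) -> tuple:
        return (self.kind, self.start, self.end, self.strand)

    def copy(self, **changes) -> "GeneSegment":
        seg = replace(self) if not changes else replace(self)
        for k, v in changes.items():
            setattr(seg, k, v)
        return seg


@dataclass(frozen=True)
class EvidenceRecord:
    """The three curation evidence booleans for one candidate segment."""

    global_similarity: bool
    functional_rss: bool
    read_or_leader_support: bool

    def n_true(self) -> int:
        return int(self.global_similarity) + int(self.functional_rss) + int(
            self.read_or_leader_support
        )


@dataclass
class LocusAnnotation:
    """Ordered collection of GeneSegments on one scaffold."""

    scaffold: str
    locus_label: str
    orientation: str  # FWD | REV
    segments: list = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        if not self.segments:
            return (0, 0)
        return (min(s.start for s in self.segments), max(s.end for s in self.segments))

    def sorted_segments(self) -> list:
        return sorted(self.segments, key=lambda s: (s.start, s.end, s.kind))

    def in_locus_order(self) -> list:
        """Segments ordered 5'->3' in transcription (locus) orientation."""
        if self.orientation == "REV":
            return sorted(self.segments, key=lambda s: (-s.end, -s.start, s.kind))
        return self.sorted_segments()


def shift_rss(h: Optional[RSSHit], off: int) -> Optional[RSSHit]:
    if h is None:
        return None
    return RSSHit(heptamer_start=h.heptamer_start + off, spacer_len=h.spacer_len,
                  nonamer_start=h.nonamer_start + off, strand=h.strand,
                  mismatches_heptamer=h.mismatches_heptamer,
                  mismatches_nonamer=h.mismatches_nonamer)


def reflect_rss(h: Optional[RSSHit], length: int) -> Optional[RSSHit]:
    """Map an RSS hit through reverse complementation of its sequence."""
    if h is None:
        return None
    return RSSHit(heptamer_start=length - (h.heptamer_start + 7),
                  spacer_len=h.spacer_len,
                  nonamer_start=length - (h.nonamer_start + 9),
                  strand="-" if h.strand == "+" else "+",
                  mismatches_heptamer=h.mismatches_heptamer,
                  mismatches_nonamer=h.mismatches_nonamer)


def shift_segment(s: GeneSegment, off: int) -> GeneSegment:
    s = s.copy()
    s.start += off
    s.end += off
    s.conserved_positions = {k: v + off for k, v in s.conserved_positions.items()}
    s.rss = shift_rss(s.rss, off)
    s.rss_3p = shift_rss(s.rss_3p, off)
    s.exons = [(a + off, b + off) for a, b in s.exons]
    return s


def reflect_segment(s: GeneSegment, length: int) -> GeneSegment:
    """Map a segment through reverse complementation of its sequence.

    Conserved positions denote codon starts (3-nt intervals) and are reflected
    as intervals.
    """
    s = s.copy()
    s.start, s.end = length - s.end, length - s.start
    s.strand = "-" if s.strand == "+" else "+"
    s.conserved_positions = {k: length - (v + 3)
                             for k, v in s.conserved_positions.items()}
    s.rss = reflect_rss(s.rss, length)
    s.rss_3p = reflect_rss(s.rss_3p, length)
    s.exons = sorted((length - b, length - a) for a, b in s.exons)
    return s


@dataclass(frozen=True)
class Clonotype:
    """One rearrangement record."""

    v_name: str
    j_name: str
    cdr3_nt: str
    cdr3_aa: str
    count: int
    d_name: Optional[str] = None


@dataclass(frozen=True)
class AnchorPair:
    """CDR3 delimitation anchors for one V/J pair, in transcript orientation.

    ``v_anchor``: first nucleotide of the conserved Cys (C104) codon;
    ``j_anchor``: last nucleotide of the conserved Phe/Trp codon of the J
    [FW]GxG motif; ``fr4_start`` is the next transcript position. The CDR3 as
    delimited here includes both anchor residues.
    """

    v_anchor: int
    j_anchor: int
    fr4_start: int
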