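"""Synthetic TCR locus, clonotype and depth-track generation with planted truth.

The generator emulates the structural features the annotation pipeline
assumes: translocon loci (V-cassette clusters, then per constant-gene unit
optional D genes, J genes and a multi-exon C gene), forward and inverted V
clusters, canonical-spacer RSSs, leader (L-PART1) exons with hydrophobic
cores, planted pseudogene/ORF defects, an optional germline pre-joined V-J
cassette, clonotype tables drawn from a configurable V-J usage model, and
per-window read-depth tracks with an optional half-coverage interval.

Every generated element is recorded in a ``SyntheticTruth`` with exact
coordinates so that downstream recovery can be scored against a planted
oracle. Construction deliberately keeps exon boundaries unambiguous (see
docs/methods.md): splices are phase-0, generated introns and intergenic
spacers carry no start codons on either strand, the last bases of each intron
contain no internal AG, and the first 26 V-exon codons avoid xAG codons, so
the boundary search of the annotator has a unique solution on defect-free
loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (GeneSegment, LocusAnnotation, RSSHit, reflect_segment,
                    shift_segment)
from .rss import HEPTAMER, NONAMER, rss_sequence
from .seqs import revcomp, translate, CODON_TABLE, STOP_CODONS

BASES = "ACGT"

SAFE_CODONS = tuple(c for c in CODON_TABLE if c not in STOP_CODONS)
CYS_CODONS = ("TGT", "TGC")
NAG_CODONS = ("AAG", "CAG", "GAG")  # codons ending in AG (TAG is a stop)
VAL_CODONS = ("GTT", "GTC", "GTA", "GTG")
# Leader codons: hydrophobic, Val-free (no internal GT donor), Met-free,
# and closed under concatenation with respect to the ATG trinucleotide.
LEADER_CODONS = ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG",
                 "GCT", "GCC", "GCA", "GCG", "ATT", "ATC", "TTT", "TTC")

V_EXON_CODON_RANGE = (90, 116)      # 270-348 nt
FIRST_CYS_CODON = 21
TRP_CODON = 40
J_HEAD_CODON_RANGE = (9, 19)        # J length 45-75 nt with motif + 2 tail codons
LEADER_EXTRA_CODONS = 10            # L-PART1 = ATG + 10 codons = 33 nt
DEFECT_KINDS = ("internal_stop", "broken_rss", "broken_splice", "missing_motif")


@dataclass(frozen=True)
class DefectSpec:
    """One planted defect: ``segment_kind`` in {V, J}, index within that kind
    (in construction order), ``defect`` one of DEFECT_KINDS."""

    segment_kind: str
    index: int
    defect: str


@dataclass
class LocusConfig:
    """Parameters of one synthetic locus."""

    locus_label: str = "TRA1"
    v_clusters: Sequence[tuple[str, int]] = (("FWD", 5),)  # orientation rel. to locus
    n_j: int = 3
    n_d: int = 0
    n_c: int = 1
    family_plan: Optional[Sequence[tuple[int, float, float]]] = None
    defect_plan: Sequence[DefectSpec] = ()
    prejoined_vj: bool = False
    intergenic_length_range: tuple[int, int] = (1500, 3000)
    scaffold_orientation: str = "FWD"  # REV => whole locus minus-strand on scaffold
    seed: int = 0

    @property
    def n_v(self) -> int:
        return sum(n for _, n in self.v_clusters)

    def validate(self) -> None:
        if self.n_j < 0 or self.n_d < 0 or self.n_c < 1 or self.n_v < 0:
            raise ValueError("counts must be non-negative (and n_c >= 1)")
        if self.scaffold_orientation not in ("FWD", "REV"):
            raise ValueError("scaffold_orientation must be FWD or REV")
        for ori, n in self.v_clusters:
            if ori not in ("FWD", "REV"):
                raise ValueError("cluster orientation must be FWD or REV")
        if self.family_plan is not None:
            if sum(s for s, _, _ in self.family_plan) != self.n_v:
                raise ValueError("family_plan sizes must sum to total V count")
            for _, within, between in self.family_plan:
                if not (0 <= between < within <= 100):
                    raise ValueError("need 0 <= between < within <= 100")
        lo, hi = self.intergenic_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad intergenic_length_range")
        for d in self.defect_plan:
            if d.defect not in DEFECT_KINDS or d.segment_kind not in ("V", "J"):
                raise ValueError(f"bad defect spec {d}")


@dataclass
class SyntheticTruth:
    """Planted ground truth paired with the generated genome."""

    genome: str
    scaffold: str
    locus_label: str
    orientation: str
    segments: list = field(default_factory=list)
    clonotype_model: Optional[pd.DataFrame] = None
    notes: list = field(default_factory=list)

    def annotation(self) -> LocusAnnotation:
        return LocusAnnotation(scaffold=self.scaffold, locus_label=self.locus_label,
                               orientation=self.orientation,
                               segments=list(self.segments))

    def segments_of(self, kind: str) -> list:
        return [s for s in self.segments if s.kind == kind]

    def c_references(self) -> list[str]:
        """Spliced (cDNA) sequences of the planted C genes, 5'->3'."""
        refs = []
        for c in self.segments_of("C"):
            exons = sorted(c.exons)
            parts = [self.genome[a:b] for a, b in exons]
            cdna = "".join(parts)
            refs.append(cdna if c.strand == "+" else revcomp(cdna))
        return refs


# ---------------------------------------------------------------------------
# random-sequence helpers


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _scrub(seq: str, rng: np.random.Generator, motifs=("ATG", "CAT")) -> str:
    """Remove start codons (both strands) by local substitution.

    Single left-to-right pass with a two-position backtrack: ATG -> ACG and
    CAT -> CGT; neither replacement can create a new occurrence further left
    than i - 2.
    """
    s = list(seq)
    sub = {"T": "C", "A": "G"}
    i = 0
    while i + 2 < len(s):
        tri = s[i] + s[i + 1] + s[i + 2]
        if tri in motifs:
            s[i + 1] = sub[s[i + 1]]
            i = max(0, i - 2)
        else:
            i += 1
    return "".join(s)


def _rss_spacer(rng: np.random.Generator, n: int) -> str:
    """Random RSS spacer free of pseudo-heptamer prefixes: no CAC (plus
    reading) or GTG (minus reading) substring, so a spacer can never seed a
    chance RSS hit that borrows the planted nonamer."""
    while True:
        s = _rand_seq(rng, n)
        if "CAC" not in s and "GTG" not in s:
            return s


def _intergenic(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return _scrub(_rand_seq(rng, n), rng)


def _intron(rng: np.random.Generator, with_donor: bool, with_acceptor: bool,
            length: Optional[int] = None) -> str:
    """Intron body; no ATG/CAT anywhere, no AG within the last 15 nt before
    the acceptor (keeps the upstream exon-boundary search unique)."""
    n = length if length is not None else int(rng.integers(80, 151))
    body = _scrub(_rand_seq(rng, max(n - 15, 10)), rng)
    tail = ""
    while True:
        tail = "".join(("C", "T", "G")[i] for i in rng.integers(0, 3, size=13))
        if "AG" not in tail and "ATG" not in tail and "CAT" not in tail:
            break
    s = body + tail
    if with_donor:
        s = "GT" + s
    if with_acceptor:
        s = s + "AG"
    return s


def _pick(rng: np.random.Generator, options: Sequence[str]) -> str:
    return options[int(rng.integers(0, len(options)))]


def _codon_ok(codon: str, idx: int, n_codons: int, k_last: int = 5) -> bool:
    """Positional constraints for V-exon codons (see module docstring).

    Trp is excluded outside the planted position so that the conserved-Trp
    feature is diagnostic; Cys placement keeps the first-Cys and C104 anchors
    unique; xAG codons are excluded from the first 26 codons so the splice
    acceptor is the only in-frame AG near the exon start."""
    if codon in STOP_CODONS or codon == "TGG":
        return False
    if idx < 26 and codon in NAG_CODONS:
        return False
    if idx < FIRST_CYS_CODON and codon in CYS_CODONS:
        return False
    if idx >= n_codons - k_last and idx != n_codons - 2 and codon in CYS_CODONS:
        return False
    return True


def _v_exon_codons(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = []
    for i in range(n_codons):
        if i == FIRST_CYS_CODON or i == n_codons - 2:
            codons.append("TGT")
        elif i == TRP_CODON:
            codons.append("TGG")
        else:
            while True:
                c = _pick(rng, SAFE_CODONS)
                if _codon_ok(c, i, n_codons):
                    codons.append(c)
                    break
    return codons


def _mutate_codons(rng: np.random.Generator, codons: list[str], n_mut: int,
                   fixed: set[int], n_codons: int,
                   check=_codon_ok) -> list[str]:
    """Apply exactly ``n_mut`` single-nucleotide substitutions at distinct
    positions inside non-fixed codons, preserving positional constraints."""
    out = list(codons)
    free = [i for i in range(len(out)) if i not in fixed]
    used: set[tuple[int, int]] = set()
    done = 0
    attempts = 0
    while done < n_mut:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place requested mutations")
        ci = free[int(rng.integers(0, len(free)))]
        p = int(rng.integers(0, 3))
        if (ci, p) in used:
            continue
        old = out[ci]
        b = _pick(rng, [x for x in BASES if x != old[p]])
        new = old[:p] + b + old[p + 1:]
        if check(new, ci, n_codons):
            out[ci] = new
            used.add((ci, p))
            done += 1
    return out


# J codon alphabet: no stops (frame test), no Val (no internal GT donor), no
# Phe/Trp (the planted [FW]GxG motif is the only one).
_J_EXCLUDED = frozenset(VAL_CODONS) | {"TTT", "TTC", "TGG"}
_J_CODONS = tuple(c for c in SAFE_CODONS if c not in _J_EXCLUDED)


def _j_codon_ok(codon: str, idx: int, n_codons: int) -> bool:
    return codon in _J_CODONS


def _j_gene_codons(rng: np.random.Generator, head: int) -> list[str]:
    """J coding codons: ``head`` codons, F-G-x-G motif, two tail codons."""
    codons = [_pick(rng, _J_CODONS) for _ in range(head)]
    codons += ["TTT", "GGA", _pick(rng, _J_CODONS), "GGG"]
    codons += [_pick(rng, _J_CODONS) for _ in range(2)]
    return codons


# ---------------------------------------------------------------------------
# locus assembly


class _Builder:
    """Accumulates sequence chunks and truth segments in plus coordinates."""

    def __init__(self) -> None:
        self.chunks: list[str] = []
        self.pos = 0
        self.segments: list[GeneSegment] = []

    def add(self, seq: str) -> int:
        start = self.pos
        self.chunks.append(seq)
        self.pos += len(seq)
        return start

    def add_block(self, seq: str, segments: list[GeneSegment], invert: bool) -> None:
        """Append a cassette block; ``invert`` reverse-complements it and
        reflects the local segment coordinates/strands."""
        if invert:
            L = len(seq)
            seq = revcomp(seq)
            segments = [reflect_segment(s, L) for s in segments]
        offset = self.pos
        self.add(seq)
        for s in segments:
            self.segments.append(shift_segment(s, offset))

    def sequence(self) -> str:
        return "".join(self.chunks)


def _consensus_rss_hit(heptamer_start: int, spacer: int, strand: str) -> RSSHit:
    if strand == "+":
        nona = heptamer_start + 7 + spacer
    else:
        nona = heptamer_start - spacer - 9
    return RSSHit(heptamer_start=heptamer_start, spacer_len=spacer,
                  nonamer_start=nona, strand=strand,
                  mismatches_heptamer=0, mismatches_nonamer=0)


def _functionality_for(defect: Optional[str]) -> str:
    if defect is None:
        return "F"
    return "P" if defect == "internal_stop" else "ORF"


def _build_v_cassette(rng: np.random.Generator, codons: list[str],
                      defect: Optional[str], locus_label: str,
                      prejoined_tail: Optional[list[str]] = None,
                      with_leader: bool = True) -> tuple[str, list[GeneSegment]]:
    """One L-PART1 + intron + V-exon (+RSS23 or prejoined J tail), local coords."""
    n = len(codons)
    codons = list(codons)
    notes = []
    if defect == "internal_stop":
        codons[30] = "TAA"
        notes.append("planted_internal_stop")
    elif defect == "missing_motif":
        codons[TRP_CODON] = "AGG"
        notes.append("planted_missing_motif")

    segs: list[GeneSegment] = []
    parts: list[str] = []
    pos = 0

    if with_leader:
        leader = "ATG" + "".join(_pick(rng, LEADER_CODONS)
                                 for _ in range(LEADER_EXTRA_CODONS))
        l_start = pos
        parts.append(leader)
        pos += len(leader)
        segs.append(GeneSegment(kind="L-PART1", start=l_start, end=pos, strand="+",
                                locus_label=locus_label, functionality="F",
                                splice_donor=True))
        intron = _intron(rng, with_donor=True, with_acceptor=True)
    else:
        intron = _intron(rng, with_donor=False, with_acceptor=True,
                         length=int(rng.integers(60, 121)))
    if defect == "broken_splice":
        intron = intron[:-2] + "AA"
        notes.append("planted_broken_splice")
    parts.append(intron)
    pos += len(intron)

    exon_codons = codons if prejoined_tail is None else codons + prejoined_tail
    exon = "".join(exon_codons)
    v_start = pos
    parts.append(exon)
    pos += len(exon)
    conserved = {
        "first_cys": v_start + 3 * FIRST_CYS_CODON,
        "trp": v_start + 3 * TRP_CODON,
        "cys104": v_start + 3 * (n - 2),
    }

    rss_hit = None
    if prejoined_tail is None:
        rss = rss_sequence(_rss_spacer(rng, 23), "+")
        if defect == "broken_rss":
            rss = "CTC" + rss[3:]
            notes.append("planted_broken_rss")
            rss_hit = None
        else:
            rss_hit = _consensus_rss_hit(pos, 23, "+")
        parts.append(rss)
        pos += len(rss)
    else:
        # pre-joined V-J: fused exon already ends with [FW]GxG + tail; add donor
        motif_codon = len(codons) + _PREJOIN_LINKER
        conserved["phe_g"] = v_start + 3 * motif_codon
        parts.append("GT" + _scrub(_rand_seq(rng, 20), rng))
        notes.append("prejoined")

    seg = GeneSegment(kind="V", start=v_start, end=v_start + len(exon), strand="+",
                      locus_label=locus_label,
                      functionality=_functionality_for(defect),
                      conserved_positions=conserved, rss=rss_hit,
                      splice_acceptor=defect != "broken_splice",
                      notes=";".join(notes))
    segs.append(seg)
    return "".join(parts), segs


_PREJOIN_LINKER = 2  # codons between the V part's final codon and the fused motif


def _prejoined_tail(rng: np.random.Generator) -> list[str]:
    safe = [c for c in _J_CODONS if c not in CYS_CODONS]
    linker = [_pick(rng, safe) for _ in range(_PREJOIN_LINKER)]
    x = _pick(rng, safe)
    return linker + ["TTT", "GGA", x, "GGG"] + [_pick(rng, safe)]


def _build_j(rng: np.random.Generator, codons: list[str], defect: Optional[str],
             locus_label: str) -> tuple[str, list[GeneSegment]]:
    codons = list(codons)
    head = len(codons) - 6
    notes = []
    if defect == "internal_stop":
        codons[2] = "TAA"
        notes.append("planted_internal_stop")
    elif defect == "missing_motif":
        codons[head:head + 4] = ["TTT", "AAA", "CGA", "GTC"]  # FKRV
        notes.append("planted_missing_motif")

    rss = rss_sequence(_rss_spacer(rng, 12), "-")
    if defect == "broken_rss":
        # break the heptamer core (last 7 plus-strand bases = revcomp heptamer)
        rss = rss[:-7] + revcomp("CTC" + HEPTAMER[3:])
        notes.append("planted_broken_rss")
        rss_hit = None
    else:
        rss_hit = _consensus_rss_hit(12 + 9, 12, "-")
    coding = "".join(codons)
    donor = "AT" if defect == "broken_splice" else "GT"
    if defect == "broken_splice":
        notes.append("planted_broken_splice")
    j_start = len(rss)
    seq = rss + coding + donor + _scrub(_rand_seq(rng, 10), rng)
    seg = GeneSegment(kind="J", start=j_start, end=j_start + len(coding), strand="+",
                      locus_label=locus_label,
                      functionality=_functionality_for(defect),
                      conserved_positions={"phe_g": j_start + 3 * head},
                      rss=rss_hit, splice_donor=defect != "broken_splice",
                      notes=";".join(notes))
    return seq, [seg]


def _build_d(rng: np.random.Generator, locus_label: str) -> tuple[str, list[GeneSegment]]:
    d_len = int(rng.integers(9, 13))
    d_seq = _rand_seq(rng, d_len)
    left = rss_sequence(_rss_spacer(rng, 12), "-")
    right = rss_sequence(_rss_spacer(rng, 23), "+")
    start = len(left)
    seq = left + d_seq + right
    seg = GeneSegment(kind="D", start=start, end=start + d_len, strand="+",
                      locus_label=locus_label, functionality="F",
                      rss=_consensus_rss_hit(12 + 9, 12, "-"),
                      rss_3p=_consensus_rss_hit(start + d_len, 23, "+"))
    return seq, [seg]


def _build_c(rng: np.random.Generator, locus_label: str,
             exon_lengths=(300, 150, 120)) -> tuple[str, list[GeneSegment]]:
    parts = []
    exons = []
    pos = 0
    for i, L in enumerate(exon_lengths):
        ex = _rand_seq(rng, L)
        exons.append((pos, pos + L))
        parts.append(ex)
        pos += L
        if i < len(exon_lengths) - 1:
            intr = _intron(rng, with_donor=True, with_acceptor=True,
                           length=int(rng.integers(80, 161)))
            parts.append(intr)
            pos += len(intr)
    seg = GeneSegment(kind="C", start=0, end=pos, strand="+",
                      locus_label=locus_label, functionality="F", exons=exons)
    return "".join(parts), [seg]


def generate_locus(config: LocusConfig) -> SyntheticTruth:
    """Generate one synthetic locus and its planted truth annotation."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    label = config.locus_label

    # family founders and member codon lists
    plan = config.family_plan
    if plan is None and config.n_v > 0:
        plan = [(config.n_v, 88.0, 60.0)]
    members: list[tuple[int, list[str]]] = []  # (family_id, codons)
    founders: list[list[str]] = []
    if plan:
        from .nomenclature import pairwise_identity

        for fam_id, (size, within, between) in enumerate(plan, start=1):
            for _ in range(30):
                n_codons = int(rng.integers(*V_EXON_CODON_RANGE))
                cand = _v_exon_codons(rng, n_codons)
                seq = "".join(cand)
                if all(pairwise_identity(seq, "".join(f)) <= between
                       for f in founders):
                    break
            else:
                raise RuntimeError("could not generate a sufficiently divergent founder")
            founders.append(cand)
            members.append((fam_id, cand))
            L = 3 * n_codons
            n_mut = round((1 - within / 100.0) * L)
            fixed = {FIRST_CYS_CODON, TRP_CODON, n_codons - 2}
            for _ in range(size - 1):
                members.append((fam_id, _mutate_codons(rng, cand, n_mut, fixed, n_codons)))
    order = rng.permutation(len(members)) if members else []
    members = [members[i] for i in order]

    v_defects = {d.index: d.defect for d in config.defect_plan if d.segment_kind == "V"}
    j_defects = {d.index: d.defect for d in config.defect_plan if d.segment_kind == "J"}

    b = _Builder()
    gap = lambda: b.add(_intergenic(rng, *config.intergenic_length_range))
    gap()

    v_idx = 0
    for ci, (ori, count) in enumerate(config.v_clusters):
        invert = ori == "REV"
        for _ in range(count):
            fam, codons = members[v_idx]
            block, segs = _build_v_cassette(rng, codons, v_defects.get(v_idx), label)
            for s in segs:
                if s.kind == "V":
                    s.family = fam
            b.add_block(block, segs, invert)
            v_idx += 1
            gap()
        if config.prejoined_vj and ci == 0 and count > 0:
            # fused V-J cassette, derived from the family-1 founder so it
            # clusters with its family; carries its own leader exon
            fam_id, founder = 1, founders[0]
            tail = _prejoined_tail(rng)
            block, segs = _build_v_cassette(rng, founder, None, label,
                                            prejoined_tail=tail)
            for s in segs:
                if s.kind == "V":
                    s.family = fam_id
            b.add_block(block, segs, invert)
            gap()

    # J genes from a per-locus template so they share global similarity
    j_segments_order = []
    if config.n_j > 0:
        head = int(rng.integers(*J_HEAD_CODON_RANGE))
        j_template = _j_gene_codons(rng, head)
        motif_idx = set(range(head, head + 4))
        n_mut_j = round(0.15 * 3 * len(j_template))

        def jcheck(codon, idx, n):
            return _j_codon_ok(codon, idx, n)

    per_unit = [config.n_j // config.n_c] * config.n_c
    for i in range(config.n_j % config.n_c):
        per_unit[i] += 1
    d_per_unit = [0] * config.n_c
    if config.n_d:
        for i in range(config.n_d):
            d_per_unit[i % config.n_c] += 1

    j_idx = 0
    for unit in range(config.n_c):
        for _ in range(d_per_unit[unit]):
            block, segs = _build_d(rng, label)
            b.add_block(block, segs, invert=False)
            gap()
        for _ in range(per_unit[unit]):
            codons = _mutate_codons(rng, j_template, n_mut_j, motif_idx,
                                    len(j_template), check=jcheck)
            block, segs = _build_j(rng, codons, j_defects.get(j_idx), label)
            b.add_block(block, segs, invert=False)
            j_idx += 1
            gap()
        block, segs = _build_c(rng, label)
        b.add_block(block, segs, invert=False)
        gap()

    genome = b.sequence()
    segments = b.segments

    orientation = "FWD"
    if config.scaffold_orientation == "REV":
        L = len(genome)
        genome = revcomp(genome)
        segments = [reflect_segment(s, L) for s in segments]
        orientation = "REV"

    truth = SyntheticTruth(genome=genome, scaffold=f"{label}_scaffold",
                           locus_label=label, orientation=orientation,
                           segments=sorted(segments, key=lambda s: s.start),
                           notes=[f"{d.segment_kind}{d.index}:{d.defect}"
                                  for d in config.defect_plan])
    _name_truth(truth)
    truth.clonotype_model = default_usage(truth)
    return truth


def merge_truths(a: SyntheticTruth, b: SyntheticTruth, spacer_nt: int = 2000,
                 seed: int = 0) -> SyntheticTruth:
    """Concatenate two loci (with a scrubbed spacer) into one truth, e.g. to
    model a repertoire drawing from two loci. Locus labels must differ so
    segment names stay unique."""
    if a.locus_label == b.locus_label:
        raise ValueError("merged loci need distinct locus labels")
    rng = np.random.default_rng(seed)
    spacer = _scrub(_rand_seq(rng, spacer_nt), rng)
    offset = len(a.genome) + len(spacer)
    segments = [s.copy() for s in a.segments] + \
        [shift_segment(s, offset) for s in b.segments]
    merged = SyntheticTruth(genome=a.genome + spacer + b.genome,
                            scaffold=f"{a.scaffold}+{b.scaffold}",
                            locus_label=f"{a.locus_label}+{b.locus_label}",
                            orientation=a.orientation,
                            segments=sorted(segments, key=lambda s: s.start),
                            notes=list(a.notes) + list(b.notes))
    merged.clonotype_model = default_usage(merged)
    return merged


def _name_truth(truth: SyntheticTruth) -> None:
    from .nomenclature import assign_names

    ann = truth.annotation()
    assign_names(ann)


def default_usage(truth: SyntheticTruth) -> pd.DataFrame:
    """Uniform usage over functional V x J pairs; a pre-joined V appears only
    as its single fixed combination."""
    vs = [s for s in truth.segments_of("V") if s.functionality == "F"
          and "prejoined" not in s.notes]
    js = [s for s in truth.segments_of("J") if s.functionality == "F"]
    pre = [s for s in truth.segments_of("V") if "prejoined" in s.notes]
    rows = []
    n_pairs = len(vs) * len(js) + len(pre)
    if n_pairs == 0:
        return pd.DataFrame(columns=["v_name", "j_name", "prob", "prejoined"])
    p = 1.0 / n_pairs
    for v in vs:
        for j in js:
            rows.append((v.name, j.name, p, False))
    for s in pre:
        rows.append((s.name, s.name, p, True))
    return pd.DataFrame(rows, columns=["v_name", "j_name", "prob", "prejoined"])


# ---------------------------------------------------------------------------
# clonotype simulation


def _junction_pieces(truth: SyntheticTruth, v_name: str, j_name: str):
    by_name = {s.name: s for s in truth.segments}
    v = by_name[v_name]
    if "prejoined" in v.notes:
        return v, v, _prejoined_cdr3(truth, v), None, None
    j = by_name[j_name]
    v_seq = v.sequence(truth.genome)
    j_seq = j.sequence(truth.genome)
    cys_off = _anchor_offset(v, "cys104", truth)
    phe_off = _anchor_offset(j, "phe_g", truth)
    v_tail = v_seq[cys_off:]
    j_head = j_seq[:phe_off + 3]
    return v, j, None, v_tail, j_head


def _anchor_offset(seg: GeneSegment, key: str, truth: SyntheticTruth) -> int:
    pos = seg.conserved_positions[key]
    if seg.strand == "+":
        return pos - seg.start
    return seg.end - (pos + 3)


def _prejoined_cdr3(truth: SyntheticTruth, v: GeneSegment) -> str:
    s = v.sequence(truth.genome)
    cys = _anchor_offset(v, "cys104", truth)
    phe = _anchor_offset(v, "phe_g", truth)
    return s[cys:phe + 3]


def simulate_clonotypes(truth: SyntheticTruth, usage: Optional[pd.DataFrame],
                        n_reads: int, trim_max: int = 3, n_insert_max: int = 6,
                        seed: int = 0) -> pd.DataFrame:
    """Draw ``n_reads`` independent rearrangement reads from the V-J usage
    model and aggregate them into a clonotype table.

    Junctions: uniform exonuclease trimming on [0, trim_max] on each side
    (never into the anchor codons), uniform insert length on [0, n_insert_max]
    padded up to the next in-frame length, insert bases uniform over ACGT.
    Read counts sum exactly to ``n_reads``.
    """
    if usage is None:
        usage = truth.clonotype_model
    if usage is None or len(usage) == 0:
        raise ValueError("empty usage table")
    probs = usage["prob"].to_numpy(dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-9):
        raise ValueError("usage probabilities must sum to 1")
    rng = np.random.default_rng(seed)

    pieces = [_junction_pieces(truth, r.v_name, r.j_name)
              for r in usage.itertuples()]
    pair_idx = rng.choice(len(usage), size=n_reads, p=probs)
    tv_raw = rng.integers(0, trim_max + 1, size=n_reads)
    tj_raw = rng.integers(0, trim_max + 1, size=n_reads)
    k_raw = rng.integers(0, n_insert_max + 1, size=n_reads)
    records: dict[tuple, int] = {}
    meta: dict[tuple, tuple] = {}
    for i in range(n_reads):
        pi = int(pair_idx[i])
        v, j, fixed_cdr3, v_tail, j_head = pieces[pi]
        if fixed_cdr3 is not None:
            key = (v.name, v.name, 0, 0, "")
            cdr3 = fixed_cdr3
        else:
            tv = min(int(tv_raw[i]), len(v_tail) - 3)
            tj = min(int(tj_raw[i]), len(j_head) - 3)
            k = int(k_raw[i])
            fixed_len = (len(v_tail) - tv) + (len(j_head) - tj)
            k += (3 - (fixed_len + k) % 3) % 3
            ins = _rand_seq(rng, k)
            key = (v.name, j.name, tv, tj, ins)
            cdr3 = v_tail[:len(v_tail) - tv] + ins + j_head[tj:]
        records[key] = records.get(key, 0) + 1
        meta[key] = (cdr3,)
    rows = []
    for key, count in sorted(records.items()):
        v_name, j_name, tv, tj, ins = key
        cdr3 = meta[key][0]
        rows.append((v_name, j_name, None, cdr3, translate(cdr3), count, tv, tj, ins))
    return pd.DataFrame(rows, columns=["v_name", "j_name", "d_name", "cdr3_nt",
                                       "cdr3_aa", "count", "trim_v", "trim_j",
                                       "insert_nt"])


def clonotype_length_pmf(truth: SyntheticTruth, usage: Optional[pd.DataFrame] = None,
                         trim_max: int = 3, n_insert_max: int = 6) -> dict[int, float]:
    """Exact CDR3 amino-acid length distribution implied by the junction model
    (enumeration over the uniform trim/insert grid); the oracle for
    spectratype-recovery tests."""
    if usage is None:
        usage = truth.clonotype_model
    pmf: dict[int, float] = {}
    n_t = trim_max + 1
    n_k = n_insert_max + 1
    for r in usage.itertuples():
        v, j, fixed_cdr3, v_tail, j_head = _junction_pieces(truth, r.v_name, r.j_name)
        if fixed_cdr3 is not None:
            L = len(fixed_cdr3) // 3
            pmf[L] = pmf.get(L, 0.0) + r.prob
            continue
        w = r.prob / (n_t * n_t * n_k)
        for tv in range(n_t):
            tv_eff = min(tv, len(v_tail) - 3)
            for tj in range(n_t):
                tj_eff = min(tj, len(j_head) - 3)
                fixed_len = (len(v_tail) - tv_eff) + (len(j_head) - tj_eff)
                for k in range(n_k):
                    kk = k + (3 - (fixed_len + k) % 3) % 3
                    L = (fixed_len + kk) // 3
                    pmf[L] = pmf.get(L, 0.0) + w
    return pmf


# ---------------------------------------------------------------------------
# depth simulation


def simulate_depth(genome_length: int, mean_depth: float,
                   half_interval: Optional[tuple[int, int]] = None,
                   seed: int = 0, window: int = 100,
                   chrom: str = "sim") -> pd.DataFrame:
    """Per-window Poisson read depth, halved inside ``half_interval``."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    rng = np.random.default_rng(seed)
    starts = np.arange(0, genome_length, window, dtype=int)
    if starts.size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "depth"])
    ends = np.minimum(starts + window, genome_length)
    means = np.full(starts.size, float(mean_depth))
    if half_interval is not None:
        a, b = half_interval
        inside = (starts >= a) & (ends <= b)
        means[inside] = mean_depth / 2.0
    depth = rng.poisson(means)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                         "depth": depth})
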