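"""Evidence-based candidate filtering and IMGT functionality classification.

Candidates are retained when at least two of three evidence criteria hold:
(1) global similarity to other segments of the locus, (2) a functional RSS,
(3) read or leader support. Functionality follows IMGT-ONTOLOGY: P
(pseudogene) when the reading frame is broken (stop codon or
frameshift-inducing length), ORF when the frame is intact but the RSS,
a splice site or a conserved motif is defective, F otherwise. Coding defects
dominate: a segment with both a stop and a broken RSS is P.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .model import EvidenceRecord, GeneSegment
from .rss import DEFAULT_FUNCTIONAL_SCORE, DEFAULT_MAX_SCORE, score_rss
from .seqs import revcomp, translate
from .segments import _MOTIF_RE, AnnotParams


def apply_evidence_filter(candidates: Sequence[GeneSegment],
                          evidence: dict) -> tuple[list[GeneSegment], list[GeneSegment]]:
    """Partition candidates into (retained, discarded): retained iff >=2 of the
    3 evidence booleans are true. ``evidence`` maps ``segment.key()`` to an
    EvidenceRecord; a candidate without a record is an error."""
    retained, discarded = [], []
    for seg in candidates:
        rec = evidence.get(seg.key())
        if rec is None:
            raise KeyError(f"no evidence record for candidate {seg.key()}")
        seg.evidence = rec
        (retained if rec.n_true() >= 2 else discarded).append(seg)
    return retained, discarded


def _rss_functional(seg: GeneSegment, sequence: str,
                    max_score: int = DEFAULT_MAX_SCORE) -> bool:
    """Re-examine the canonical-spacer RSS at the segment's flank."""
    spacers = {"V": (23,), "J": (12,), "D": (12, 23)}.get(seg.kind)
    if spacers is None:
        return True

    def window_ok(start: int, end: int, spacer: int, orient: str) -> bool:
        if start < 0 or end > len(sequence):
            return False
        w = sequence[start:end]
        if orient == "-":
            w = revcomp(w)
        try:
            return score_rss(w, spacer, max_score=max_score) is not None
        except ValueError:
            return False

    n = 7 + 9
    if seg.kind == "V":
        sp = 23
        if seg.strand == "+":
            return window_ok(seg.end, seg.end + n + sp, sp, "+")
        return window_ok(seg.start - n - sp, seg.start, sp, "-")
    if seg.kind == "J":
        sp = 12
        if seg.strand == "+":
            return window_ok(seg.start - n - sp, seg.start, sp, "-")
        return window_ok(seg.end, seg.end + n + sp, sp, "+")
    # D: both flanks
    if seg.strand == "+":
        return (window_ok(seg.start - n - 12, seg.start, 12, "-")
                and window_ok(seg.end, seg.end + n + 23, 23, "+"))
    return (window_ok(seg.end, seg.end + n + 12, 12, "+")
            and window_ok(seg.start - n - 23, seg.start, 23, "-"))


def _splice_ok(seg: GeneSegment, sequence: str) -> bool:
    if seg.kind == "V":  # acceptor AG immediately 5' of the exon
        if seg.strand == "+":
            return sequence[seg.start - 2:seg.start] == "AG"
        return revcomp(sequence[seg.end:seg.end + 2]) == "AG"
    if seg.kind == "J":  # donor GT immediately 3' of the region
        if seg.strand == "+":
            return sequence[seg.end:seg.end + 2] == "GT"
        return revcomp(sequence[seg.start - 2:seg.start]) == "GT"
    return True


def _motif_ok(seg: GeneSegment, coding: str,
              params: AnnotParams) -> bool:
    pep = translate(coding)
    if seg.kind == "V":
        lo, hi = params.first_cys_window
        first_c = pep.find("C")
        if not (lo <= first_c <= hi):
            return False
        if "W" not in pep[first_c + 1:]:
            return False
        return "C" in pep[len(pep) - params.cys104_last_k:]
    if seg.kind == "J":
        return any(m.start(1) % 3 == 0 for m in _MOTIF_RE.finditer(coding))
    return True


def classify_functionality(seg: GeneSegment, sequence: str,
                           params: Optional[AnnotParams] = None,
                           max_rss_score: int = DEFAULT_FUNCTIONAL_SCORE) -> str:
    """IMGT functionality class of a V or J segment on ``sequence``.

    P: stop codon in frame or a frameshift-inducing length; ORF: intact frame
    but non-functional RSS, broken splice site or missing conserved motif;
    F: all features intact. Sets ``seg.functionality`` and returns it.
    """
    params = params or AnnotParams()
    if seg.start < 0 or seg.end > len(sequence):
        raise ValueError("segment out of sequence bounds")
    coding = seg.sequence(sequence)
    if seg.kind in ("V", "J"):
        if len(coding) % 3 != 0 or "*" in translate(coding):
            seg.functionality = "P"
            return "P"
    if seg.kind == "V" and "prejoined" in seg.notes:
        # a germline-fused V-J has no recombination RSS; its exon must carry
        # the V features up to the fused motif, the motif itself, a 5'
        # acceptor and a 3' donor
        ok = (_splice_ok(seg, sequence) and _splice_ok_j_like(seg, sequence)
              and _prejoined_motifs_ok(seg, coding, params))
        seg.functionality = "F" if ok else "ORF"
        return seg.functionality
    rss_ok = _rss_functional(seg, sequence, max_rss_score)
    if rss_ok and _splice_ok(seg, sequence) and _motif_ok(seg, coding, params):
        seg.functionality = "F"
    else:
        seg.functionality = "ORF"
    return seg.functionality


def _prejoined_motif_offset(seg: GeneSegment, coding: str) -> Optional[int]:
    """Offset of the fused [FW]GxG motif within the transcript-oriented coding
    sequence, from the recorded anchor when present, else the last in-frame
    motif occurrence."""
    cp = seg.conserved_positions
    if "phe_g" in cp:
        if seg.strand == "+":
            return cp["phe_g"] - seg.start
        return seg.end - (cp["phe_g"] + 3)
    offs = [m.start(1) for m in _MOTIF_RE.finditer(coding) if m.start(1) % 3 == 0]
    return offs[-1] if offs else None


def _prejoined_motifs_ok(seg: GeneSegment, coding: str, params: AnnotParams) -> bool:
    off = _prejoined_motif_offset(seg, coding)
    if off is None or off % 3 != 0 or not (0 < off <= len(coding) - 12):
        return False
    if coding[off:off + 3] not in ("TTT", "TTC", "TGG") or \
            coding[off + 3:off + 5] != "GG" or coding[off + 9:off + 11] != "GG":
        return False
    v_pep = translate(coding[:off])
    lo, hi = params.first_cys_window
    first_c = v_pep.find("C")
    if not (lo <= first_c <= hi) or "W" not in v_pep[first_c + 1:]:
        return False
    # C104 sits in the codons just before the fused motif (linker included)
    return "C" in v_pep[-(params.cys104_last_k + 1):]


def detect_prejoined_vj(v_candidates: Sequence[GeneSegment], sequence: str,
                        params: Optional[AnnotParams] = None) -> list[bool]:
    """Flag V candidates whose 3' end continues in frame into a [FW]GxG motif
    and GT donor with no intervening RSS (germline pre-joined V-J)."""
    params = params or AnnotParams()
    flags = []
    for seg in v_candidates:
        coding = seg.sequence(sequence)
        # an ordinary V has a 23-spacer RSS right at its 3' end
        if _rss_functional(seg, sequence):
            flags.append(False)
            continue
        donor = _splice_ok_j_like(seg, sequence)
        motif = any(m.start(1) % 3 == 0 for m in _MOTIF_RE.finditer(coding))
        flag = bool(donor and motif)
        flags.append(flag)
        if flag and "prejoined" not in seg.notes:
            seg.notes = (seg.notes + ";" if seg.notes else "") + "prejoined"
    return flags


def _splice_ok_j_like(seg: GeneSegment, sequence: str) -> bool:
    if seg.strand == "+":
        return sequence[seg.end:seg.end + 2] == "GT"
    return revcomp(sequence[seg.start - 2:seg.start]) == "GT"


def leader_evidence(seg: GeneSegment, leaders: Sequence[GeneSegment]) -> bool:
    """Read-or-leader support operationalized as: a leader exon was found for
    this V (possibly shared with a neighbouring cassette)."""
    return len(leaders) > 0
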