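"""End-to-end locus annotation: scan RSSs, discover candidates, filter on
evidence, classify functionality, cluster families, assign names.

The evidence filter retains a candidate when at least two of three criteria
hold: global similarity to other candidates of the same kind in the locus, a
functional RSS, and read-or-leader support (a discovered leader exon for V
genes; externally supplied read evidence otherwise). This two-of-three rule
is what removes the scanner's false anchors, so precision does not depend on
the RSS score threshold alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .curation import apply_evidence_filter, classify_functionality, detect_prejoined_vj
from .model import EvidenceRecord, GeneSegment, LocusAnnotation
from .nomenclature import assign_names, cluster_families, determine_orientation, \
    pairwise_identity
from .rss import DEFAULT_FUNCTIONAL_SCORE, DEFAULT_MAX_SCORE, scan_rss
from .segments import (AnnotParams, find_d_segments, find_j_segments,
                       find_leaders, find_prejoined_v_segments, find_v_segments,
                       locate_c_genes)


@dataclass
class AnnotationResult:
    locus: LocusAnnotation
    discarded: list = field(default_factory=list)
    unplaced_references: list = field(default_factory=list)
    evidence: dict = field(default_factory=dict)


def _overlap(a: GeneSegment, b: GeneSegment) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _deoverlap_v(cands: list[GeneSegment]) -> tuple[list[GeneSegment], list[GeneSegment]]:
    """When two V candidates overlap >50% of the shorter, keep the one with
    the better (lower) RSS score; prefer a candidate with intact features."""
    kept: list[GeneSegment] = []
    dropped: list[GeneSegment] = []

    def quality(s: GeneSegment):
        return (0 if s.functionality != "P" else 1,
                s.rss.score if s.rss is not None else 99,
                -(s.end - s.start))

    for cand in sorted(cands, key=quality):
        clash = next((k for k in kept
                      if _overlap(cand, k) * 2 > min(cand.end - cand.start,
                                                     k.end - k.start)), None)
        if clash is None:
            kept.append(cand)
        else:
            cand.notes = (cand.notes + ";" if cand.notes else "") + \
                f"overlaps_{clash.start}_{clash.end}"
            dropped.append(cand)
    return sorted(kept, key=lambda s: s.start), dropped


def _similarity_evidence(segs: Sequence[GeneSegment], sequence: str,
                         threshold: float) -> dict:
    """Global-similarity boolean per segment: clusters with at least one other
    same-kind candidate at >= threshold% identity."""
    out = {s.key(): False for s in segs}
    seqs = [s.sequence(sequence) for s in segs]
    n = len(segs)
    for i in range(n):
        for j in range(i + 1, n):
            if out[segs[i].key()] and out[segs[j].key()]:
                continue
            if pairwise_identity(seqs[i], seqs[j]) >= threshold:
                out[segs[i].key()] = True
                out[segs[j].key()] = True
    return out


def annotate_locus(sequence: str, c_references: list[str],
                   locus_label: str = "TRA", scaffold: str = "scaffold",
                   params: Optional[AnnotParams] = None,
                   max_rss_score: int = DEFAULT_MAX_SCORE,
                   functional_rss_score: int = DEFAULT_FUNCTIONAL_SCORE,
                   family_threshold: float = 75.0,
                   similarity_threshold: float = 60.0,
                   read_support: Optional[dict] = None,
                   search_prejoined: bool = True) -> AnnotationResult:
    """Annotate one scaffold region.

    ``read_support`` optionally maps a candidate ``(kind, start, end, strand)``
    key to an externally determined read-evidence boolean (amplicon/IsoSeq
    mapping is not recomputed here); leader discovery stands in for it on V
    genes when absent.
    """
    params = params or AnnotParams()
    read_support = read_support or {}

    hits23 = scan_rss(sequence, 23, strands="both", max_score=max_rss_score)
    hits12 = scan_rss(sequence, 12, strands="both", max_score=max_rss_score)

    c_segs, unplaced = locate_c_genes(sequence, c_references, params)
    if not c_segs:
        raise ValueError("no constant-gene reference could be placed; "
                         "locus orientation is undefined")
    orientation = determine_orientation(c_segs)

    v_cands = find_v_segments(sequence, hits23, params)
    j_cands = find_j_segments(sequence, hits12, params)
    d_cands = find_d_segments(sequence, hits12, hits23, params)

    # a D's left 12-RSS has the same geometry as a J anchor, so a chance
    # J-shaped reading across a D body must defer to the D interpretation,
    # which rests on two close-to-consensus flanking RSSs
    j_cands = [j for j in j_cands
               if all(_overlap(j, d) == 0 for d in d_cands)]

    if search_prejoined:
        anchored = v_cands + c_segs
        for cand in find_prejoined_v_segments(sequence, params):
            if all(_overlap(cand, other) == 0 for other in anchored):
                # the fused exon contains J-derived sequence; a partial
                # J-shaped reading of the same span defers to the cassette
                j_cands = [j for j in j_cands if _overlap(cand, j) == 0]
                v_cands.append(cand)
        v_cands.sort(key=lambda s: s.start)

    v_cands, dropped = _deoverlap_v(v_cands)

    # leader discovery (evidence + L-PART1 annotation)
    leaders_of: dict = {}
    for v in v_cands:
        leaders_of[v.key()] = find_leaders(sequence, v, params)

    v_sim = _similarity_evidence(v_cands, sequence, similarity_threshold)
    j_sim = _similarity_evidence(j_cands, sequence, similarity_threshold)

    evidence = {}
    for v in v_cands:
        evidence[v.key()] = EvidenceRecord(
            global_similarity=v_sim[v.key()],
            functional_rss=v.rss is not None and v.rss.score <= functional_rss_score,
            read_or_leader_support=read_support.get(v.key(),
                                                    bool(leaders_of[v.key()])),
        )
    for j in j_cands:
        evidence[j.key()] = EvidenceRecord(
            global_similarity=j_sim[j.key()],
            functional_rss=j.rss is not None and j.rss.score <= functional_rss_score,
            read_or_leader_support=read_support.get(j.key(), False),
        )

    v_keep, v_drop = apply_evidence_filter(v_cands, evidence)
    j_keep, j_drop = apply_evidence_filter(j_cands, evidence)
    discarded = dropped + v_drop + j_drop

    for seg in v_keep + j_keep:
        classify_functionality(seg, sequence, params, functional_rss_score)
    detect_prejoined_vj(v_keep, sequence, params)

    # one leader per retained V (the nearest candidate), shared leaders dedup
    leader_segs: dict = {}
    for v in v_keep:
        found = leaders_of.get(v.key()) or []
        if found:
            lead = found[0]
            lead.functionality = "F"
            leader_segs[lead.key()] = lead

    if v_keep:
        cluster_families(v_keep, sequence, threshold=family_threshold,
                         orientation=orientation)

    segments = v_keep + j_keep + d_cands + c_segs + list(leader_segs.values())
    for s in segments:
        s.locus_label = locus_label
    locus = LocusAnnotation(scaffold=scaffold, locus_label=locus_label,
                            orientation=orientation,
                            segments=sorted(segments, key=lambda s: s.start))
    assign_names(locus)
    return AnnotationResult(locus=locus, discarded=discarded,
                            unplaced_references=unplaced, evidence=evidence)


def recovery_scores(truth_segments: Sequence[GeneSegment],
                    found: LocusAnnotation) -> dict:
    """Coordinate-exact recall/precision per segment kind against a planted
    truth (matching on kind, start, end, strand)."""
    out = {}
    for kind in ("V", "D", "J", "C", "L-PART1"):
        t = {s.key() for s in truth_segments if s.kind == kind}
        f = {s.key() for s in found.segments if s.kind == kind}
        if not t and not f:
            continue
        tp = len(t & f)
        out[kind] = {
            "recall": tp / len(t) if t else 1.0,
            "precision": tp / len(f) if f else 1.0,
            "truth": len(t),
            "found": len(f),
        }
    return out
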