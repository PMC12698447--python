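"""Candidate V/J/D/C/leader discovery from sequence plus RSS hits.

Discovery follows the conserved-feature logic of antigen-receptor gene
annotation: V exons are anchored on a downstream 23-spacer RSS and must show
an AG splice acceptor, an open reading frame, the first conserved Cys, a
conserved Trp and the CDR3-opening Cys (C104 homolog) near the exon end;
J genes are anchored on an upstream 12-spacer RSS and must show a [FW]GxG
motif and a GT splice donor; D genes are 9-12 bp stretches framed by a
12-spacer and a 23-spacer RSS; C genes are placed by spliced mapping of
reference constant-region cDNAs; leader (L-PART1) exons start at ATG, carry a
hydrophobic core and end at a GT donor.

All finders handle the minus strand by running the forward logic on the
reverse complement and reflecting coordinates, which makes annotation of a
sequence and of its reverse complement mirror images by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import GeneSegment, RSSHit, reflect_rss, reflect_segment
from .seqs import hydrophobic_core, revcomp, translate


@dataclass
class AnnotParams:
    """Tunable thresholds of the segment finders."""

    v_len_range: tuple[int, int] = (270, 348)   # V exon, nt (multiples of 3)
    v_end_offset_max: int = 3                   # max nt between V end and heptamer
    v_min_content: int = 3                      # of 4 hallmarks; pseudogene floor
    first_cys_window: tuple[int, int] = (18, 25)  # codon index of the first Cys
    cys104_last_k: int = 5                      # C104 within the last k codons
    j_len_range: tuple[int, int] = (45, 75)     # J coding region, nt
    d_len_range: tuple[int, int] = (9, 12)      # D coding region, nt
    d_rss_score: int = 2                        # both D RSSs must score <= this
    leader_len_range: tuple[int, int] = (18, 60)
    leader_window: int = 800                    # upstream search distance, bp
    leader_min_intron: int = 20
    prejoined_extra: int = 21                   # fused J tail added to V range, nt
    c_min_identity: float = 80.0                # %, C reference placement
    c_min_coverage: float = 0.8


# [FW]-G-x-G at the nucleotide level: F/W codon, Gly codon, any codon, Gly codon
_MOTIF_RE = re.compile(r"(?=((?:TTT|TTC|TGG)GG..{3}GG.))")


# ---------------------------------------------------------------------------
# V segments


def _v_content(pep: str, params: AnnotParams):
    """Return (score, anchors|None) for a candidate V-exon translation."""
    score = 0
    anchors = {}
    if "*" not in pep:
        score += 1
    lo, hi = params.first_cys_window
    first_c = pep.find("C")
    if lo <= first_c <= hi:
        score += 1
        anchors["first_cys"] = first_c
    k = params.cys104_last_k
    tail = pep[len(pep) - k:]
    c104 = tail.rfind("C")
    if c104 != -1:
        score += 1
        anchors["cys104"] = len(pep) - k + c104
    w = pep.find("W", first_c + 1 if first_c != -1 else 0)
    if w != -1:
        score += 1
        anchors["trp"] = w
    return score, anchors


def _find_v_forward(seq: str, hits: list[RSSHit], params: AnnotParams) -> list[GeneSegment]:
    """V exons upstream of plus-strand 23-RSS hits."""
    out = []
    min_len, max_len = params.v_len_range
    for h in hits:
        if h.strand != "+" or h.spacer_len < 20:
            continue
        best = None
        best_key = None  # (perfect, score, -offset, -length): shortest wins
        for offset in range(0, params.v_end_offset_max + 1):
            end = h.heptamer_start - offset
            # shortest-first: the most conservative exon call consistent with
            # all conserved features
            for L in range(min_len + (3 - min_len % 3) % 3, max_len + 1, 3):
                start = end - L
                if start < 2:
                    continue
                if seq[start - 2:start] != "AG":
                    continue
                pep = translate(seq[start:end])
                score, anchors = _v_content(pep, params)
                perfect = score == 4
                key = (perfect, score, -offset, -L)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (perfect, score, start, end, anchors)
                if perfect:
                    break
            if best is not None and best[0]:
                break
        if best is None or best[1] < params.v_min_content:
            # a credible V candidate (even a pseudogene) keeps most hallmarks
            continue
        perfect, score, start, end, anchors = best
        conserved = {k: start + 3 * v for k, v in anchors.items()}
        notes = []
        if not perfect:
            pep = translate(seq[start:end])
            if "*" in pep:
                notes.append("internal_stop")
            if "first_cys" not in anchors:
                notes.append("no_first_cys")
            if "trp" not in anchors:
                notes.append("no_trp")
            if "cys104" not in anchors:
                notes.append("no_cys104")
        out.append(GeneSegment(kind="V", start=start, end=end, strand="+",
                               functionality="unassigned" if perfect else "P",
                               conserved_positions=conserved, rss=h,
                               splice_acceptor=True, notes=";".join(notes)))
    return out


def find_v_segments(sequence: str, rss_hits_23: list[RSSHit],
                    params: AnnotParams | None = None) -> list[GeneSegment]:
    """Discover V-exon candidates anchored on 23-spacer RSS hits (both strands)."""
    params = params or AnnotParams()
    out = _find_v_forward(sequence, [h for h in rss_hits_23 if h.strand == "+"], params)
    minus = [h for h in rss_hits_23 if h.strand == "-"]
    if minus:
        L = len(sequence)
        rc = revcomp(sequence)
        rhits = [reflect_rss(h, L) for h in minus]
        found = _find_v_forward(rc, rhits, params)
        out += [reflect_segment(s, L) for s in found]
    return sorted(out, key=lambda s: s.start)


# ---------------------------------------------------------------------------
# J segments


def _find_j_forward(seq: str, hits: list[RSSHit], params: AnnotParams) -> list[GeneSegment]:
    """J regions downstream of minus-strand 12-spacer RSS hits (the heptamer
    abuts the J 5' end and reads away from it, i.e. appears as a minus hit)."""
    out = []
    min_len, max_len = params.j_len_range
    n = len(seq)
    for h in hits:
        if h.strand != "-" or h.spacer_len > 20:
            continue
        j_start = h.heptamer_start + 7
        call = None
        fallback = None
        for L in range(min_len + (3 - min_len % 3) % 3, max_len + 1, 3):
            j_end = j_start + L
            if j_end + 2 > n:
                break
            if seq[j_end:j_end + 2] != "GT":
                continue
            region = seq[j_start:j_end]
            pep = translate(region)
            if "*" in pep:
                continue
            m = None
            for mm in _MOTIF_RE.finditer(region):
                if mm.start(1) % 3 == 0:
                    m = mm.start(1)
            if m is not None:
                call = (j_start, j_end, j_start + m)
                break
            if fallback is None:
                fallback = (j_start, j_end)
        if call is not None:
            start, end, phe = call
            out.append(GeneSegment(kind="J", start=start, end=end, strand="+",
                                   functionality="unassigned",
                                   conserved_positions={"phe_g": phe},
                                   rss=h, splice_donor=True))
        elif fallback is not None:
            start, end = fallback
            out.append(GeneSegment(kind="J", start=start, end=end, strand="+",
                                   functionality="ORF", rss=h, splice_donor=True,
                                   notes="non_canonical_motif"))
    return out


def find_j_segments(sequence: str, rss_hits_12: list[RSSHit],
                    params: AnnotParams | None = None) -> list[GeneSegment]:
    """Discover J-region candidates anchored on 12-spacer RSS hits (both strands)."""
    params = params or AnnotParams()
    out = _find_j_forward(sequence, [h for h in rss_hits_12 if h.strand == "-"], params)
    plus = [h for h in rss_hits_12 if h.strand == "+"]
    if plus:
        L = len(sequence)
        rc = revcomp(sequence)
        rhits = [reflect_rss(h, L) for h in plus]
        found = _find_j_forward(rc, rhits, params)
        out += [reflect_segment(s, L) for s in found]
    return sorted(out, key=lambda s: s.start)


# ---------------------------------------------------------------------------
# D segments


def _find_d_forward(hits12: list[RSSHit], hits23: list[RSSHit],
                    params: AnnotParams) -> list[tuple[int, int, RSSHit, RSSHit]]:
    lo, hi = params.d_len_range
    out = []
    # a 9-12 bp D carries no curatable sequence content, so both flanking
    # RSSs must be high quality (close to consensus) on their own
    left = [h for h in hits12 if h.strand == "-" and h.score <= params.d_rss_score]
    right = [h for h in hits23 if h.strand == "+" and h.score <= params.d_rss_score]
    for h1 in left:
        d_start = h1.heptamer_start + 7
        for h2 in right:
            gap = h2.heptamer_start - d_start
            if lo <= gap <= hi:
                out.append((d_start, h2.heptamer_start, h1, h2))
    return out


def find_d_segments(sequence: str, rss_hits_12: list[RSSHit],
                    rss_hits_23: list[RSSHit],
                    params: AnnotParams | None = None) -> list[GeneSegment]:
    """D candidates: every 12/23 RSS pair framing a 9-12 bp stretch; all
    qualifying pairs are reported (downstream curation disambiguates)."""
    params = params or AnnotParams()
    segs = [GeneSegment(kind="D", start=a, end=b, strand="+",
                        functionality="unassigned", rss=h1, rss_3p=h2)
            for a, b, h1, h2 in _find_d_forward(rss_hits_12, rss_hits_23, params)]
    L = len(sequence)
    r12 = [reflect_rss(h, L) for h in rss_hits_12]
    r23 = [reflect_rss(h, L) for h in rss_hits_23]
    for a, b, h1, h2 in _find_d_forward(r12, r23, params):
        seg = GeneSegment(kind="D", start=a, end=b, strand="+",
                          functionality="unassigned", rss=h1, rss_3p=h2)
        segs.append(reflect_segment(seg, L))
    return sorted(segs, key=lambda s: (s.start, s.strand))


# ---------------------------------------------------------------------------
# leader (L-PART1) exons


def _find_leaders_forward(seq: str, v_start: int, params: AnnotParams) -> list[GeneSegment]:
    lo = max(0, v_start - params.leader_window)
    min_len, max_len = params.leader_len_range
    out = []
    region_end = v_start - 2  # exclude the acceptor AG
    for a in range(region_end - 1, lo - 1, -1):  # nearest ATG first
        if seq[a:a + 3] != "ATG":
            continue
        for L in range(min_len + (3 - min_len % 3) % 3, max_len + 1, 3):
            end = a + L
            if end + 2 + params.leader_min_intron > v_start:
                break
            if seq[end:end + 2] != "GT":
                continue
            pep = translate(seq[a:end])
            if "*" in pep or not hydrophobic_core(pep):
                break
            out.append(GeneSegment(kind="L-PART1", start=a, end=end, strand="+",
                                   functionality="unassigned", splice_donor=True))
            break  # smallest valid exon for this ATG
    return out


def find_leaders(sequence: str, v_segment: GeneSegment,
                 params: AnnotParams | None = None) -> list[GeneSegment]:
    """Leader-exon candidates upstream (in transcription sense) of a V segment,
    ordered by proximity; zero, one or several may be returned (leaders can be
    shared between neighbouring V genes)."""
    params = params or AnnotParams()
    if v_segment.strand == "+":
        return _find_leaders_forward(sequence, v_segment.start, params)
    L = len(sequence)
    rc = revcomp(sequence)
    found = _find_leaders_forward(rc, L - v_segment.end, params)
    return [reflect_segment(s, L) for s in found]


# ---------------------------------------------------------------------------
# C genes (spliced reference mapping)


def _splice_map(seq: str, ref: str, max_mismatch_frac: float = 0.2):
    """Greedy spliced placement of ``ref`` (a cDNA) onto ``seq``.

    Returns (exons, matches) or None. Introns must start GT and end AG and are
    validated by a 20-nt anchor match after the acceptor.
    """
    anchor = ref[:20]
    g0 = seq.find(anchor)
    if g0 == -1:
        return None
    budget = int(max_mismatch_frac * len(ref))
    exons = []
    matches = 0
    mismatches = 0
    i, g = 0, g0
    exon_start = g0
    n = len(seq)
    while i < len(ref):
        if g < n and seq[g] == ref[i]:
            matches += 1
            i += 1
            g += 1
            continue
        # try an intron: scan GT positions back from here (longest exon first)
        jumped = False
        for s in range(g, exon_start, -1):
            if seq[s:s + 2] != "GT":
                continue
            back = g - s  # matched bases that actually belong to the next exon
            ri = i - back
            probe = ref[ri:ri + 20]
            if len(probe) < 8:
                continue
            q = s + 2
            while True:
                q = seq.find("AG", q)
                if q == -1 or q > s + 5000:
                    break
                if seq[q + 2:q + 2 + len(probe)] == probe:
                    exons.append((exon_start, s))
                    matches -= back
                    exon_start = q + 2
                    i, g = ri, q + 2
                    jumped = True
                    break
                q += 1
            if jumped:
                break
        if jumped:
            continue
        if mismatches < budget and g < n:
            mismatches += 1
            i += 1
            g += 1
            continue
        return None
    exons.append((exon_start, g))
    return exons, matches


def locate_c_genes(sequence: str, c_references: list[str],
                   params: AnnotParams | None = None) -> tuple[list[GeneSegment], list[int]]:
    """Place constant-region reference cDNAs on the genome.

    Returns (segments, unplaced_reference_indices). Exon sub-features are
    stored on each segment in genome coordinate order; EX1..EXn labelling
    follows transcription order (reversed on the minus strand).
    """
    params = params or AnnotParams()
    if not c_references:
        raise ValueError("at least one C reference is required")
    segs, unplaced = [], []
    L = len(sequence)
    for idx, ref in enumerate(c_references):
        ref = ref.upper()
        placed = None
        res = _splice_map(sequence, ref)
        if res is not None:
            exons, matches = res
            placed = (exons, matches, "+")
        else:
            rc = revcomp(sequence)
            res = _splice_map(rc, ref)
            if res is not None:
                exons, matches = res
                exons = sorted((L - b, L - a) for a, b in exons)
                placed = (exons, matches, "-")
        if placed is None:
            unplaced.append(idx)
            continue
        exons, matches, strand = placed
        identity = 100.0 * matches / len(ref)
        coverage = sum(b - a for a, b in exons) / len(ref)
        if identity < params.c_min_identity or coverage < params.c_min_coverage:
            unplaced.append(idx)
            continue
        segs.append(GeneSegment(kind="C", start=exons[0][0], end=exons[-1][1],
                                strand=strand, functionality="F", exons=exons,
                                notes=f"identity={identity:.1f}"))
    return sorted(segs, key=lambda s: s.start), unplaced


# ---------------------------------------------------------------------------
# pre-joined V-J (RSS-less fused cassette)


def _find_prejoined_forward(seq: str, params: AnnotParams,
                            max_tail_codons: int = 3) -> list[GeneSegment]:
    out = []
    min_len = params.v_len_range[0] + params.prejoined_extra
    max_len = params.v_len_range[1] + params.prejoined_extra
    for mm in _MOTIF_RE.finditer(seq):
        p = mm.start(1)
        for t in range(0, max_tail_codons + 1):
            dpos = p + 12 + 3 * t
            if seq[dpos:dpos + 2] != "GT":
                continue
            end = dpos
            found = None
            for L in range(min_len + (3 - min_len % 3) % 3, max_len + 1, 3):
                start = end - L
                if start < 2 or (p - start) % 3 != 0:
                    continue
                if seq[start - 2:start] != "AG":
                    continue
                pep = translate(seq[start:end])
                score, anchors = _v_content(pep[: (p - start) // 3], params)
                if score < 4 or "*" in pep:
                    continue
                # C104 within the codons just before the fused motif
                motif_codon = (p - start) // 3
                window = pep[max(0, motif_codon - 6):motif_codon]
                c = window.rfind("C")
                if c == -1:
                    continue
                cys104 = max(0, motif_codon - 6) + c
                found = (start, end, cys104)
                break
            if found is not None:
                start, end, cys104 = found
                conserved = {"cys104": start + 3 * cys104, "phe_g": p,
                             "first_cys": start + 3 * translate(seq[start:end]).find("C")}
                out.append(GeneSegment(kind="V", start=start, end=end, strand="+",
                                       functionality="unassigned",
                                       conserved_positions=conserved,
                                       splice_acceptor=True, splice_donor=True,
                                       notes="prejoined"))
            break  # only the nearest donor candidate per motif
    return out


def find_prejoined_v_segments(sequence: str,
                              params: AnnotParams | None = None) -> list[GeneSegment]:
    """Scan for germline pre-joined V regions: a V-like ORF that continues in
    frame into a [FW]GxG motif and GT donor with no intervening RSS."""
    params = params or AnnotParams()
    out = _find_prejoined_forward(sequence, params)
    L = len(sequence)
    found = _find_prejoined_forward(revcomp(sequence), params)
    out += [reflect_segment(s, L) for s in found]
    # drop duplicates (same span found from both scans is impossible, but motifs
    # can overlap); keep unique keys
    uniq = {}
    for s in out:
        uniq.setdefault(s.key(), s)
    return sorted(uniq.values(), key=lambda s: s.start)
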