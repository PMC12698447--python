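"""Recombination signal sequence (RSS) detection.

An RSS is a conserved heptamer (consensus CACAGTG) and nonamer (consensus
ACAAAAACC) separated by a spacer of ~12 bp or ~23 bp; recombination pairs one
12-spacer RSS with one 23-spacer RSS (the 12/23 rule). Scoring is transparent
mismatch counting against the consensus with an obligatory CAC heptamer
prefix (the functionally critical heptamer core); a window is rejected when
the prefix is absent or the combined mismatch score exceeds ``max_score``.
"""

from __future__ import annotations

import numpy as np

from .model import RSSHit
from .seqs import revcomp

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
DEFAULT_MAX_SCORE = 4
# stricter threshold used when RSS quality serves as curation evidence or in
# functionality classification (discovery stays permissive at DEFAULT_MAX_SCORE)
DEFAULT_FUNCTIONAL_SCORE = 2


def score_rss(window: str, spacer_class: int, spacer_tolerance: int = 0,
              max_score: int = DEFAULT_MAX_SCORE):
    """Score one candidate window (heptamer + spacer + nonamer).

    Returns ``(score, spacer_len)`` or ``None`` when rejected (CAC prefix
    absent or score > max_score). Raises ValueError for a window whose length
    matches no admissible spacer.
    """
    window = window.upper()
    admissible = [spacer_class + d for d in range(-spacer_tolerance, spacer_tolerance + 1)]
    spacer = len(window) - 7 - 9
    if spacer not in admissible:
        raise ValueError(
            f"window length {len(window)} admits spacer {spacer}, "
            f"expected one of {admissible}"
        )
    if window[:3] != "CAC":
        return None
    hept = window[:7]
    nona = window[7 + spacer:]
    mm_h = sum(a != b for a, b in zip(hept, HEPTAMER))
    mm_n = sum(a != b for a, b in zip(nona, NONAMER))
    if mm_h + mm_n > max_score:
        return None
    return mm_h + mm_n, spacer


def _mismatch_profile(arr: np.ndarray, motif: str) -> np.ndarray:
    """Mismatch count of ``motif`` at every start position of ``arr``."""
    n = arr.size
    m = len(motif)
    if n < m:
        return np.zeros(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    mot = np.frombuffer(motif.encode(), dtype=np.uint8)
    for j in range(m):
        out += arr[j:n - m + 1 + j] != mot[j]
    return out


def _scan_plus(sequence: str, spacer_class: int, max_score: int,
               spacer_tolerance: int) -> list[tuple[int, int, int, int]]:
    """Plus-orientation hits as (heptamer_start, spacer, mm_h, mm_n)."""
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mm_h = _mismatch_profile(arr, HEPTAMER)
    mm_n = _mismatch_profile(arr, NONAMER)
    # obligatory CAC prefix
    cac = _mismatch_profile(arr, "CAC") == 0
    hits = []
    for spacer in range(spacer_class - spacer_tolerance, spacer_class + spacer_tolerance + 1):
        offset = 7 + spacer
        n_pos = len(arr) - offset - 9 + 1
        if n_pos <= 0:
            continue
        h = mm_h[:n_pos]
        n = mm_n[offset:offset + n_pos]
        ok = (h + n <= max_score) & cac[:n_pos]
        for p in np.flatnonzero(ok):
            hits.append((int(p), spacer, int(h[p]), int(n[p])))
    return hits


def scan_rss(sequence: str, spacer_class: int, strands: str = "both",
             max_score: int = DEFAULT_MAX_SCORE, spacer_tolerance: int = 0) -> list[RSSHit]:
    """Scan for RSS motifs of one spacer class.

    Minus-strand hits are found by scanning the reverse complement and are
    reported in plus-strand coordinates with ``strand="-"``. Results are
    sorted by coordinate. Overlapping hits are all reported.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if spacer_class not in (12, 23):
        raise ValueError("spacer_class must be 12 or 23")
    hits: list[RSSHit] = []
    L = len(sequence)
    if strands in ("+", "both"):
        for p, spacer, mm_h, mm_n in _scan_plus(sequence, spacer_class, max_score, spacer_tolerance):
            hits.append(RSSHit(heptamer_start=p, spacer_len=spacer,
                               nonamer_start=p + 7 + spacer, strand="+",
                               mismatches_heptamer=mm_h, mismatches_nonamer=mm_n))
    if strands in ("-", "both"):
        rc = revcomp(sequence)
        for p, spacer, mm_h, mm_n in _scan_plus(rc, spacer_class, max_score, spacer_tolerance):
            # heptamer occupies [p, p+7) on the rc; reflect to plus coords
            hept_start = L - (p + 7)
            nona_start = L - (p + 7 + spacer + 9)
            hits.append(RSSHit(heptamer_start=hept_start, spacer_len=spacer,
                               nonamer_start=nona_start, strand="-",
                               mismatches_heptamer=mm_h, mismatches_nonamer=mm_n))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def rss_sequence(spacer: str, orientation: str = "+") -> str:
    """Consensus RSS with the given spacer, as laid out on the plus strand.

    ``orientation="+"``: heptamer first (segment to the left);
    ``orientation="-"``: mirrored layout (segment to the right).
    """
    s = HEPTAMER + spacer + NONAMER
    return s if orientation == "+" else revcomp(s)
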