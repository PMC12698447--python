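"""Small nucleotide/peptide helpers shared across the package.

All genomic coordinates in this package are 0-based, half-open intervals on
the plus strand of the scaffold; conversion to 1-based inclusive happens only
in the GFF3 layer.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate frame 0; trailing partial codon ignored; unknown codons -> X."""
    return "".join(
        CODON_TABLE.get(seq[i:i + 3].upper(), "X")
        for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def has_stop(seq: str) -> bool:
    """True if frame-0 translation of ``seq`` contains a stop codon."""
    return "*" in translate(seq)


def hydrophobic_core(peptide: str, window: int = 6, min_mean: float = 1.5) -> bool:
    """True if some ``window``-residue stretch has mean Kyte-Doolittle > ``min_mean``.

    This is the package's operational signal-peptide test for leader exons.
    """
    if len(peptide) < window:
        return False
    scores = [KYTE_DOOLITTLE.get(aa, -4.5) for aa in peptide]
    acc = sum(scores[:window])
    if acc / window > min_mean:
        return True
    for i in range(window, len(scores)):
        acc += scores[i] - scores[i - window]
        if acc / window > min_mean:
            return True
    return False


def reflect_interval(start: int, end: int, length: int) -> tuple[int, int]:
    """Map a half-open interval through reverse complementation of its sequence."""
    return length - end, length - start


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
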