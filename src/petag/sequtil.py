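"""Small sequence helpers shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, alphabet: str = "ACGT") -> bool:
    """True if ``seq`` is non-empty and uses only ``alphabet`` letters (upper-cased)."""
    s = seq.upper()
    return len(s) > 0 and all(c in alphabet for c in s)


def is_iupac(pattern: str) -> bool:
    return len(pattern) > 0 and all(c in IUPAC for c in pattern.upper())


def iupac_match(base: str, code: str) -> bool:
    """Does a concrete genome base satisfy one IUPAC pattern code?

    An ``N`` in the genome is matched only by pattern code ``N``.
    """
    allowed = IUPAC.get(code.upper())
    if allowed is None:
        raise ValueError(f"not an IUPAC code: {code!r}")
    return base.upper() in allowed


def pam_matches(seq: str, pattern: str) -> bool:
    """Match a genomic sequence against an IUPAC PAM pattern, position-wise."""
    if len(seq) != len(pattern):
        return False
    return all(iupac_match(b, c) for b, c in zip(seq, pattern))


def hamming(a: str, b: str) -> int:
    """Hamming distance; ``N`` (or any non-ACGT letter) never counts as a match."""
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    d = 0
    for x, y in zip(a.upper(), b.upper()):
        if x != y or x not in "ACGT":
            d += 1
    return d
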