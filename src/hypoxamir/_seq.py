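"""Tiny sequence helpers shared across modules.

All sequences are stored on disk in DNA alphabet; U<->T conversion is
internal and lossless.  Coordinates are 0-based half-open internally and
1-based inclusive on GFF output.
"""

from __future__ import annotations

from Bio.Seq import reverse_complement as _bio_revcomp

DNA_ALPHABET = "ACGT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def to_dna(seq: str) -> str:
    """Normalize a sequence to uppercase DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Normalize a sequence to uppercase RNA (T -> U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return _bio_revcomp(seq)


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC DNA pattern (e.g. RCGTG -> CACGY)."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a plain regex character-class string."""
    parts = []
    for c in pattern.upper():
        try:
            opts = IUPAC[c]
        except KeyError:
            raise ValueError(f"not an IUPAC DNA code: {c!r}")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
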