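"""Small nucleotide/codon helpers shared across modules."""

from __future__ import annotations

NUCLEOTIDES = "ACGT"

# Standard genetic code, written out explicitly so that replacement/silent
# classification does not depend on any third-party translation routine.
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")


def translate(nt: str) -> str:
    """Translate ``nt`` (length multiple of 3 assumed; trailing bases dropped).

    Codons containing characters outside ACGT translate to ``X``.
    """
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        aa.append(CODON_TABLE.get(nt[i : i + 3], "X"))
    return "".join(aa)


def has_stop(nt: str) -> bool:
    """True if an in-frame stop codon occurs in frame 0 of ``nt``."""
    for i in range(0, len(nt) - len(nt) % 3, 3):
        if nt[i : i + 3] in STOP_CODONS:
            return True
    return False


def hamming(a: str, b: str) -> int:
    """Exact Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
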