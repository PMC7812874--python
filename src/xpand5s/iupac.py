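"""IUPAC degenerate nucleotide codes and base-pairing predicates.

All sequences are handled internally as uppercase RNA (T is normalised
to U on input).
"""

from __future__ import annotations

EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("GC"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}

WATSON_CRICK: frozenset[tuple[str, str]] = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
)
WOBBLE: frozenset[tuple[str, str]] = frozenset([("G", "U"), ("U", "G")])

_COMPLEMENT = str.maketrans("ACGUTacgut", "UGCAAugcaa")
_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class InvalidCodeError(ValueError):
    """Raised when a symbol is not a valid IUPAC nucleotide code."""


def normalize(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().replace("T", "U")


def expansion(code: str) -> frozenset[str]:
    code = normalize(code)
    try:
        return EXPANSION[code]
    except KeyError:
        raise InvalidCodeError(f"invalid IUPAC code {code!r}") from None


def iupac_match(code: str, base: str) -> bool:
    """True iff ``base`` belongs to the expansion of ``code``."""
    b = normalize(base)
    if b not in EXPANSION or len(EXPANSION[b]) != 1:
        raise InvalidCodeError(f"invalid concrete base {base!r}")
    return b in expansion(code)


def bases_pair(x: str, y: str, wobble: bool = False) -> bool:
    """True iff concrete bases x,y form a Watson-Crick (or wobble) pair."""
    if (x, y) in WATSON_CRICK:
        return True
    return wobble and (x, y) in WOBBLE


def iupac_complementary(a: str, b: str, wobble: bool = False) -> bool:
    """True iff some pair of concrete bases drawn from the two code
    expansions can form a Watson-Crick (or, with ``wobble``, G:U) pair."""
    ea, eb = expansion(a), expansion(b)
    return any(bases_pair(x, y, wobble) for x in ea for y in eb)


def matches_pattern(pattern: str, seq: str) -> bool:
    """Position-wise IUPAC match of equal-length strings."""
    if len(pattern) != len(seq):
        return False
    return all(s in expansion(c) for c, s in zip(pattern, seq))


def reverse_complement(seq: str) -> str:
    """Reverse complement; RNA in, RNA out."""
    return normalize(seq).translate(_COMPLEMENT)[::-1]
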