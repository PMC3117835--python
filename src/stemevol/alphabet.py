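"""Nucleotide alphabet conventions used throughout the package.

Sequences are RNA over {A, C, G, U}; ``-`` is a gap (base absent) and ``~``
marks a non-sequenced region (base unknown). The two are never conflated:
a gap is evidence of absence, a tilde is absence of evidence. IUPAC ambiguity
codes are accepted in input rows and carried through; each counting step
decides locally whether an ambiguous base is usable.
"""

from __future__ import annotations

BASES = ("A", "C", "G", "U")
GAP = "-"
UNKNOWN = "~"

#: the five character states used by discrete ancestral reconstruction and
#: by the substitution matrices, in the conventional row/column order
STATES = ("A", "C", "G", "U", GAP)

#: IUPAC ambiguity codes mapped to the RNA bases they stand for
IUPAC_AMBIGUITY = {
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("GC"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

VALID_ROW_CHARS = frozenset(BASES) | frozenset(IUPAC_AMBIGUITY) | {GAP, UNKNOWN}

#: canonical base pairs: Watson-Crick plus the G-U wobble
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)


def is_base(ch: str) -> bool:
    """True for an unambiguous RNA base."""
    return ch in BASES


def is_ambiguous(ch: str) -> bool:
    """True for an IUPAC ambiguity code (N included)."""
    return ch in IUPAC_AMBIGUITY


def is_canonical(a: str, b: str) -> bool:
    """True if ``a``/``b`` form a Watson-Crick or G-U wobble pair."""
    return (a, b) in CANONICAL_PAIRS


def normalize_char(ch: str) -> str:
    """Uppercase, T->U, '.'->'-'. Raises KeyError-free; validation is elsewhere."""
    up = ch.upper()
    if up == "T":
        return "U"
    if up == ".":
        return GAP
    return up
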