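"""Composite (degenerate) nucleotide alphabet.

A degenerate motif position is modelled as a non-empty subset of the DNA
alphabet {A, C, G, T}.  A motif *pattern* is a tuple of such subsets; a
sequence window matches the pattern when the base at every position is a
member of the corresponding subset.  The composite alphabet Sigma* used by
the exhaustive search consists of all subsets up to a configurable
degeneracy (subset size): the four singletons plus 6 two-base, 4 three-base
and the single four-base character.

Patterns are rendered either as IUPAC one-letter codes (``{A,G}`` -> ``R``)
or as bracket sets (``[AG]``) matching the notation common in the motif
literature; both forms are accepted on input.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes for every non-empty subset of {A,C,G,T}.
IUPAC_TO_SET = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}
SET_TO_IUPAC = {s: c for c, s in IUPAC_TO_SET.items()}

Pattern = tuple[frozenset, ...]


def make_composite_alphabet(max_degeneracy: int) -> list[frozenset]:
    """All non-empty subsets of {A,C,G,T} with at most ``max_degeneracy`` bases.

    Singletons come first, then subsets in order of increasing size and, within
    a size, lexicographically — a fixed order so depth-first searches are
    deterministic.
    """
    if not 1 <= max_degeneracy <= 4:
        raise ValueError(f"max_degeneracy must be in 1..4, got {max_degeneracy}")
    chars: list[frozenset] = [frozenset(b) for b in BASES]
    for size in range(2, max_degeneracy + 1):
        for combo in combinations(BASES, size):
            chars.append(frozenset(combo))
    return chars


def parse_pattern(text: str) -> Pattern:
    """Parse a degenerate pattern given in IUPAC and/or bracket-set notation.

    ``"RG[AG]TGG"`` and ``"[AG]G[AG]TGG"`` denote the same pattern.
    """
    out: list[frozenset] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValueError(f"unterminated bracket set in pattern {text!r}")
            group = text[i + 1 : j]
            if not group or any(b not in BASE_INDEX for b in group):
                raise ValueError(f"invalid bracket set {text[i:j+1]!r}")
            out.append(frozenset(group))
            i = j + 1
        else:
            cu = ch.upper()
            if cu not in IUPAC_TO_SET:
                raise ValueError(f"invalid pattern character {ch!r}")
            out.append(IUPAC_TO_SET[cu])
            i += 1
    if not out:
        raise ValueError("empty pattern")
    return tuple(out)


def pattern_to_iupac(pattern: Iterable[frozenset]) -> str:
    return "".join(SET_TO_IUPAC[frozenset(s)] for s in pattern)


def pattern_to_brackets(pattern: Iterable[frozenset]) -> str:
    """Bracket-set rendering, e.g. ``(frozenset('AG'), frozenset('G'))`` -> ``"[AG]G"``."""
    parts = []
    for s in pattern:
        bases = "".join(sorted(s))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)
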