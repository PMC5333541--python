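"""IUPAC nucleotide ambiguity codes and set algebra on degenerate sequences.

The 15 one-letter codes each denote a set of unambiguous bases (A, C, G, T).
A degenerate sequence denotes the cartesian product of its per-position base
sets; its *multiplicity* is the size of that product, i.e. the number of
unambiguous "isoforms" the sequence expands into.
"""

from __future__ import annotations

import itertools
from typing import Iterable

BASES = "ACGT"

#: symbol -> the set of unambiguous bases it denotes (sorted tuple, A<C<G<T)
CODE_TO_BASES: dict[str, tuple[str, ...]] = {
    "A": ("A",),
    "C": ("C",),
    "G": ("G",),
    "T": ("T",),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
    "B": ("C", "G", "T"),
    "D": ("A", "G", "T"),
    "H": ("A", "C", "T"),
    "V": ("A", "C", "G"),
    "N": ("A", "C", "G", "T"),
}

#: frozenset of bases -> minimal covering code (exact inverse of CODE_TO_BASES)
BASES_TO_CODE: dict[frozenset[str], str] = {
    frozenset(v): k for k, v in CODE_TO_BASES.items()
}

IUPAC_SYMBOLS = frozenset(CODE_TO_BASES)
DEGENERATE_SYMBOLS = frozenset(s for s, b in CODE_TO_BASES.items() if len(b) > 1)


class InvalidIupacError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""

    def __init__(self, symbol: str, position: int):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"invalid IUPAC nucleotide symbol {symbol!r} at position {position}"
        )


def validate(sequence: str) -> str:
    """Return *sequence* unchanged, raising :class:`InvalidIupacError` naming
    the first offending 0-based position otherwise."""
    for i, ch in enumerate(sequence):
        if ch not in IUPAC_SYMBOLS:
            raise InvalidIupacError(ch, i)
    return sequence


def bases(symbol: str) -> tuple[str, ...]:
    """Unambiguous bases denoted by one IUPAC symbol (e.g. ``K -> (G, T)``)."""
    try:
        return CODE_TO_BASES[symbol]
    except KeyError:
        raise InvalidIupacError(symbol, 0) from None


def multiplicity(symbol: str) -> int:
    """Number of bases a symbol denotes: 1 for A/C/G/T, 2 for R/Y/S/W/K/M,
    3 for B/D/H/V, 4 for N."""
    return len(bases(symbol))


def degeneracy_count(sequence: str) -> int:
    """Number of positions carrying a degenerate (non-A/C/G/T) symbol."""
    if not sequence:
        raise ValueError("empty sequence")
    validate(sequence)
    return sum(1 for ch in sequence if ch in DEGENERATE_SYMBOLS)


def sequence_multiplicity(sequence: str) -> int:
    """Product of per-position multiplicities; the number of unambiguous
    isoforms the degenerate sequence expands into (1 if degeneracy-free)."""
    validate(sequence)
    product = 1
    for ch in sequence:
        product *= len(CODE_TO_BASES[ch])
    return product


def expand(sequence: str) -> list[str]:
    """All unambiguous isoforms of a degenerate sequence.

    Deterministic order: the cartesian product expands positions left to
    right with bases ordered A < C < G < T, so the result is sorted when the
    input has uniform per-position ordering (it always is).
    """
    validate(sequence)
    return [
        "".join(p) for p in itertools.product(*(CODE_TO_BASES[ch] for ch in sequence))
    ]


def code_for(base_set: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of unambiguous bases
    (e.g. ``{A, G} -> R``, ``{A, C, G, T} -> N``)."""
    key = frozenset(base_set)
    try:
        return BASES_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a set of unambiguous bases: {sorted(key)!r}") from None


def union_code(symbols: Iterable[str]) -> str:
    """Minimal IUPAC code covering the union of the base sets of *symbols*."""
    union: set[str] = set()
    for s in symbols:
        union.update(bases(s))
    if not union:
        raise ValueError("empty symbol collection")
    return code_for(union)
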