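"""Non-redundant reduction and per-position conservation of recovered fragments.

Exact-string deduplication pools the recovered fragments into non-redundant
(NR) entries with abundances; a coverage count asks how many NR entries
(most abundant first) are needed to represent a given fraction of all
fragments.  Position frequency matrices weight degenerate characters
fractionally — an R contributes 0.5 to A and 0.5 to G — in either of two
modes: *all-fragments* (each fragment counted, i.e. NR entries weighted by
abundance) or *NR* (every distinct sequence counted once, so rare variants
carry the same weight as dominant ones).  A position is called conserved
when its most frequent base reaches the threshold (0.95 by default), and the
consensus collapses each column to the minimal IUPAC code over the bases
whose frequency reaches the inclusion threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import iupac

__all__ = [
    "NrTable",
    "PositionFrequencyMatrix",
    "ConsensusResult",
    "dedupe_nr",
    "reduction_percent",
    "nr_needed",
    "position_frequencies",
    "conserved_positions",
    "consensus_iupac",
    "consensus_result",
]

_BASE_INDEX = {b: i for i, b in enumerate(iupac.BASES)}

#: per-symbol fractional contribution to the A/C/G/T columns
_SHARES: dict[str, np.ndarray] = {}
for _sym, _bases in iupac.CODE_TO_BASES.items():
    _vec = np.zeros(4)
    for _b in _bases:
        _vec[_BASE_INDEX[_b]] = 1.0 / len(_bases)
    _SHARES[_sym] = _vec


@dataclass
class NrTable:
    """Non-redundant fragments: (unique string, abundance) sorted by
    descending abundance, then lexicographically."""

    entries: list[tuple[str, int]]
    total_fragments: int

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    @property
    def reduction_percent(self) -> float:
        return reduction_percent(self.total_fragments, self.n_unique)


@dataclass
class PositionFrequencyMatrix:
    """L x 4 per-position base fractions (columns A, C, G, T).

    Rows over IUPAC-only input sum to 1; characters outside the IUPAC
    alphabet contribute nothing, leaving their rows short of 1 and flagged.
    ``n_sequences`` is the total weight behind the matrix.
    """

    contig_name: str
    freq: np.ndarray
    n_sequences: float

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def flagged_rows(self) -> np.ndarray:
        return self.freq.sum(axis=1) < 1.0 - 1e-9

    @property
    def max_base_freq(self) -> np.ndarray:
        return self.freq.max(axis=1)


@dataclass
class ConsensusResult:
    contig_name: str
    consensus: str
    conserved_mask: np.ndarray
    theta: float
    tau: float

    @property
    def n_conserved(self) -> int:
        return int(self.conserved_mask.sum())


def dedupe_nr(fragments: Iterable[str]) -> NrTable:
    """Exact-string deduplication of equal-length fragments into an
    abundance-sorted NR table."""
    counts = Counter(fragments)
    if not counts:
        raise ValueError("no fragments to deduplicate")
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError(f"fragments have mixed lengths: {sorted(lengths)}")
    entries = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return NrTable(entries=entries, total_fragments=sum(counts.values()))


def reduction_percent(total: int, n_unique: int) -> float:
    """Percent reduction achieved by pooling *total* fragments into
    *n_unique* NR entries: ``100 * (1 - NR/total)``."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * (1.0 - n_unique / total)


def nr_needed(nr: NrTable, fraction: float) -> int:
    """Smallest number of NR entries (most abundant first) whose abundances
    sum to at least ``fraction * total_fragments``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not nr.entries:
        raise ValueError("empty NR table")
    target = fraction * nr.total_fragments
    cumulative = 0
    for m, (_, abundance) in enumerate(nr.entries, start=1):
        cumulative += abundance
        if cumulative >= target - 1e-9:
            return m
    return len(nr.entries)


def position_frequencies(
    sequences: Sequence[str] | NrTable,
    weights: Sequence[float] | None = None,
    contig_name: str = "",
    *,
    mode: str = "all",
) -> PositionFrequencyMatrix:
    """Fractionally-weighted per-position base frequencies.

    Input is either raw fragment strings or an :class:`NrTable`; for an NR
    table ``mode="all"`` weights each unique sequence by its abundance
    (algebraically identical to feeding every fragment) while ``mode="nr"``
    gives every unique sequence weight 1.  Explicit *weights* override both.
    Degenerate characters spread their weight uniformly over their base set.
    """
    if isinstance(sequences, NrTable):
        seqs = [s for s, _ in sequences.entries]
        if weights is None:
            if mode == "all":
                weights = [a for _, a in sequences.entries]
            elif mode == "nr":
                weights = [1.0] * len(seqs)
            else:
                raise ValueError(f"unknown mode {mode!r}")
    else:
        seqs = list(sequences)
        if weights is None:
            weights = [1.0] * len(seqs)
    if not seqs:
        raise ValueError("no sequences")
    if len(weights) != len(seqs):
        raise ValueError("weights length mismatch")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
    L = lengths.pop()

    freq = np.zeros((L, 4))
    total_weight = float(sum(weights))
    if total_weight <= 0:
        raise ValueError("total weight must be positive")
    zero = np.zeros(4)
    for seq, w in zip(seqs, weights):
        for p, ch in enumerate(seq):
            freq[p] += w * _SHARES.get(ch, zero)
    freq /= total_weight
    return PositionFrequencyMatrix(
        contig_name=contig_name, freq=freq, n_sequences=total_weight
    )


def conserved_positions(
    matrix: PositionFrequencyMatrix, theta: float = 0.95
) -> np.ndarray:
    """Boolean mask: position conserved iff its max base frequency >= theta."""
    if not 0.0 < theta <= 1.0:
        raise ValueError(f"theta must be in (0, 1], got {theta}")
    return matrix.max_base_freq >= theta - 1e-12


def consensus_iupac(matrix: PositionFrequencyMatrix, tau: float = 0.05) -> str:
    """Per position, the minimal IUPAC code over bases with frequency >= tau
    (N when no base reaches tau, possible only for tau > 0.25)."""
    if not 0.0 <= tau < 0.5:
        raise ValueError(f"tau must be in [0, 0.5), got {tau}")
    symbols = []
    for row in matrix.freq:
        included = {
            iupac.BASES[i] for i in range(4) if row[i] >= tau - 1e-12 and row[i] > 0
        }
        if tau == 0.0:
            included = {iupac.BASES[i] for i in range(4) if row[i] > 0}
        symbols.append(iupac.code_for(included) if included else "N")
    return "".join(symbols)


def consensus_result(
    matrix: PositionFrequencyMatrix, theta: float = 0.95, tau: float = 0.05
) -> ConsensusResult:
    """Consensus string plus conservation mask at the stated thresholds."""
    mask = conserved_positions(matrix, theta)
    return ConsensusResult(
        contig_name=matrix.contig_name,
        consensus=consensus_iupac(matrix, tau),
        conserved_mask=mask,
        theta=theta,
        tau=tau,
    )
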