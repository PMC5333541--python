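"""Anchor-based recovery of contig-length fragments from database records.

The window with the highest database frequency serves as the anchor: in each
record the first (5'-most) exact match to any anchor isoform is located and
the record is sliced to contig length by extending ``window.index``
nucleotides to the left and the remainder to the right.  Fragments are
therefore aligned by construction — every one carries the anchor at the same
offset — so no alignment step is needed downstream.  Slices that would cross
a record boundary are reported as truncated (and excluded from consensus
analysis); records without any anchor isoform are unmatched.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

from .database_io import SequenceRecord
from .kmer_engine import KmerWindow, ScanResult, expand_isoforms

__all__ = [
    "AnchorSpec",
    "Outcome",
    "RecoveryOutcome",
    "FragmentSet",
    "select_anchor",
    "recover_fragment",
    "recover_all",
]


class Outcome(enum.Enum):
    MATCHED = "matched"
    TRUNCATED = "truncated"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class AnchorSpec:
    """The anchoring window of a contig plus the flank lengths needed to
    rebuild a contig-length fragment around it."""

    contig_name: str
    window: KmerWindow
    contig_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.window.index <= self.contig_length - self.window.k:
            raise ValueError("anchor window does not fit inside the contig")

    @property
    def left_flank(self) -> int:
        return self.window.index

    @property
    def right_flank(self) -> int:
        return self.contig_length - self.window.k - self.window.index

    @property
    def isoforms(self) -> frozenset[str]:
        return frozenset(expand_isoforms(self.window.sequence))


@dataclass(frozen=True)
class RecoveryOutcome:
    record_id: str
    status: Outcome
    fragment: str | None = None
    match_offset: int | None = None  # anchor match start within the record
    duplicate: bool = False  # record carried >= 2 anchor matches


@dataclass
class FragmentSet:
    """All recovery outcomes for one contig over one database."""

    contig_name: str
    contig_length: int
    fragments: list[tuple[str, str]] = field(default_factory=list)
    n_truncated: int = 0
    n_unmatched: int = 0
    n_duplicate_bearing: int = 0
    outcomes: list[RecoveryOutcome] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.fragments) + self.n_truncated + self.n_unmatched


def select_anchor(scan_results: list[ScanResult], contig_length: int) -> AnchorSpec:
    """The window with maximal ``seq_hits`` (ties -> smallest index).

    Raises when every window scored zero, i.e. the contig is absent from
    the database.
    """
    if not scan_results:
        raise ValueError("no scan results")
    best = max(scan_results, key=lambda r: (r.seq_hits, -r.window.index))
    if best.seq_hits == 0:
        raise ValueError(
            f"contig {best.window.contig_name} absent from database "
            "(zero hits for every window)"
        )
    return AnchorSpec(
        contig_name=best.window.contig_name,
        window=best.window,
        contig_length=contig_length,
    )


def _find_matches(sequence: str, isoforms: frozenset[str], k: int) -> list[int]:
    return [
        i for i in range(len(sequence) - k + 1) if sequence[i : i + k] in isoforms
    ]


def recover_fragment(record: SequenceRecord, anchor: AnchorSpec) -> RecoveryOutcome:
    """Slice one contig-length fragment around the first anchor match.

    Outcomes are values, never errors: ``MATCHED`` with the fragment,
    ``TRUNCATED`` when the flanks run past a record end, ``UNMATCHED`` when
    no anchor isoform occurs.
    """
    isoforms = anchor.isoforms
    k = anchor.window.k
    matches = _find_matches(record.sequence, isoforms, k)
    if not matches:
        return RecoveryOutcome(record_id=record.id, status=Outcome.UNMATCHED)
    first = matches[0]
    duplicate = len(matches) >= 2
    start = first - anchor.left_flank
    end = first + k + anchor.right_flank
    if start < 0 or end > len(record.sequence):
        return RecoveryOutcome(
            record_id=record.id,
            status=Outcome.TRUNCATED,
            match_offset=first,
            duplicate=duplicate,
        )
    return RecoveryOutcome(
        record_id=record.id,
        status=Outcome.MATCHED,
        fragment=record.sequence[start:end],
        match_offset=first,
        duplicate=duplicate,
    )


def recover_all(
    records: Iterable[SequenceRecord],
    anchor: AnchorSpec,
    *,
    keep_outcomes: bool = True,
) -> FragmentSet:
    """Apply :func:`recover_fragment` to every record, preserving database
    order, and tally the three outcomes."""
    result = FragmentSet(
        contig_name=anchor.contig_name, contig_length=anchor.contig_length
    )
    n = 0
    for record in records:
        n += 1
        outcome = recover_fragment(record, anchor)
        if outcome.status is Outcome.MATCHED:
            result.fragments.append((record.id, outcome.fragment))
        elif outcome.status is Outcome.TRUNCATED:
            result.n_truncated += 1
        else:
            result.n_unmatched += 1
        if outcome.duplicate:
            result.n_duplicate_bearing += 1
        if keep_outcomes:
            result.outcomes.append(outcome)
    if n == 0:
        raise ValueError("empty database")
    return result
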