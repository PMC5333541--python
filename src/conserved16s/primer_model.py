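"""Degenerate primer contigs for the conserved regions of the 16S rRNA gene.

A *primer contig* is the degenerate consensus obtained by stacking every
published PCR primer that targets one conserved region on the E. coli
coordinate line and taking, per position, the minimal IUPAC code covering the
union of the primers' base sets.  Regions whose primers leave a coordinate
gap split into sub-contigs (a/b/c).  The package ships the fifteen reference
contigs covering conserved regions 1-10 of the gene as packaged data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from . import iupac
from .iupac import degeneracy_count, sequence_multiplicity  # re-exported API

__all__ = [
    "PrimerContig",
    "ContigSummary",
    "ContigGapError",
    "degeneracy_count",
    "sequence_multiplicity",
    "assemble_contig",
    "load_reference_contigs",
]


@dataclass(frozen=True)
class PrimerContig:
    """A degenerate consensus of published primers for one conserved region.

    Coordinates are 1-based inclusive on the E. coli 16S rRNA reference, so
    ``ecoli_end - ecoli_start + 1 == len(sequence)``.
    """

    name: str  # region number plus optional sub-label, e.g. "3", "5b"
    sequence: str
    ecoli_start: int
    ecoli_end: int
    source_refs: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        iupac.validate(self.sequence)
        span = self.ecoli_end - self.ecoli_start + 1
        if span != len(self.sequence):
            raise ValueError(
                f"contig {self.name}: coordinate span {span} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def degenerate_bases(self) -> int:
        return degeneracy_count(self.sequence)


@dataclass(frozen=True)
class ContigSummary:
    """Per-contig bookkeeping at window size k: length, degenerate-base
    count, number of k-mer windows and total isoform count."""

    name: str
    length: int
    degenerate_bases: int
    n_kmers: int
    n_iso_kmers: int


class ContigGapError(ValueError):
    """Split signal: the primers do not tile a contiguous span.

    ``segments`` holds the gap-free groups of ``(sequence, start)`` pairs, in
    coordinate order, so the caller can assemble each as a sub-contig
    (a/b/c).
    """

    def __init__(self, segments: list[list[tuple[str, int]]]):
        self.segments = segments
        spans = ", ".join(
            f"{seg[0][1]}..{max(s + len(q) - 1 for q, s in seg)}" for seg in segments
        )
        super().__init__(
            f"primers form {len(segments)} separate contigs ({spans}); "
            "assemble each segment as a sub-contig"
        )


def assemble_contig(
    primers: Sequence[tuple[str, int]], name: str = "contig"
) -> PrimerContig:
    """Assemble coordinate-anchored primers into one degenerate contig.

    Each primer is ``(IUPAC sequence, ecoli_start)`` with 1-based start.  At
    every covered position the contig carries the minimal IUPAC code for the
    union of the base sets of all primers overlapping it.  Primers that leave
    an uncovered position raise :class:`ContigGapError` carrying the gap-free
    segments rather than silently merging across the gap.
    """
    if not primers:
        raise ValueError("no primers given")
    for seq, start in primers:
        iupac.validate(seq)
        if not seq:
            raise ValueError("empty primer sequence")
        if start < 1:
            raise ValueError(f"coordinates are 1-based; got start {start}")

    ordered = sorted(primers, key=lambda p: (p[1], p[0]))
    # group into gap-free segments by sweeping the covered interval
    segments: list[list[tuple[str, int]]] = []
    seg_end = None
    for seq, start in ordered:
        end = start + len(seq) - 1
        if seg_end is None or start > seg_end + 1:
            segments.append([])
        segments[-1].append((seq, start))
        seg_end = end if seg_end is None or end > seg_end else seg_end
    if len(segments) > 1:
        raise ContigGapError(segments)

    lo = ordered[0][1]
    hi = max(start + len(seq) - 1 for seq, start in ordered)
    columns: list[set[str]] = [set() for _ in range(hi - lo + 1)]
    for seq, start in ordered:
        for offset, symbol in enumerate(seq):
            columns[start - lo + offset].update(iupac.bases(symbol))
    consensus = "".join(iupac.code_for(col) for col in columns)
    return PrimerContig(name=name, sequence=consensus, ecoli_start=lo, ecoli_end=hi)


def load_reference_contigs() -> list[PrimerContig]:
    """The fifteen packaged reference primer contigs (regions 1-10, with
    sub-contigs a/b/c where published primers leave gaps), each anchored on
    E. coli 16S coordinates."""
    path = resources.files(__package__).joinpath("data/primer_contigs.tsv")
    contigs: list[PrimerContig] = []
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            contigs.append(
                PrimerContig(
                    name=row["name"],
                    sequence=row["sequence"],
                    ecoli_start=int(row["start"]),
                    ecoli_end=int(row["end"]),
                )
            )
    if len(contigs) != 15:
        raise RuntimeError(f"reference fixture corrupt: {len(contigs)} contigs")
    return contigs
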