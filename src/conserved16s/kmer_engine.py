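"""k-mer windows of primer contigs, isoform expansion and exact database scans.

A contig of length L yields ``L - k + 1`` overlapping windows (k = 12 by
default throughout the package).  A degenerate window expands into
``sequence_multiplicity`` unambiguous isoforms; the scan counts, for every
window, the database records containing at least one exact substring match
to any isoform.  Matching is exact character equality on normalized (DNA,
ungapped, uppercase) records, forward strand only: ambiguity codes inside a
record never match, which mirrors searching the literal sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .database_io import SequenceRecord
from .iupac import expand as _expand, sequence_multiplicity, validate
from .primer_model import ContigSummary, PrimerContig

__all__ = [
    "KmerWindow",
    "ScanResult",
    "SpecificityCurve",
    "enumerate_windows",
    "expand_isoforms",
    "contig_iso_totals",
    "summarize_contigs",
    "scan_database",
    "specificity_analysis",
]


@dataclass(frozen=True)
class KmerWindow:
    """One k-length window of a contig: 0-based index and isoform count."""

    contig_name: str
    index: int
    sequence: str

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def iso_count(self) -> int:
        return sequence_multiplicity(self.sequence)


@dataclass
class ScanResult:
    """Database hit statistics for one window.

    ``hit_positions`` maps record id -> sorted 0-based match start offsets
    (all isoforms pooled); ``seq_hits`` counts each record once however many
    matches it carries.
    """

    window: KmerWindow
    n_records: int
    seq_hits: int
    n_duplicate_records: int = 0  # records matching at >= 2 distinct positions
    hit_positions: dict[str, list[int]] = field(default_factory=dict)

    @property
    def percent(self) -> float:
        return 100.0 * self.seq_hits / self.n_records if self.n_records else 0.0


@dataclass
class SpecificityCurve:
    """Duplicate-hit counts per k, used to pick the working k-mer size.

    ``duplicate_counts[k]`` sums, over the contig's windows at that k, the
    number of records matching the window at two or more positions.
    ``selected_k`` is the smallest k at the curve's inflection point (largest
    positive second difference), defaulting to 12 on flat or concave curves.
    """

    contig_name: str
    k_values: list[int]
    duplicate_counts: list[int]
    selected_k: int


def enumerate_windows(contig: PrimerContig, k: int) -> list[KmerWindow]:
    """All k-length windows of a contig in order; empty when the contig is
    shorter than k."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    seq = contig.sequence
    return [
        KmerWindow(contig_name=contig.name, index=i, sequence=seq[i : i + k])
        for i in range(len(seq) - k + 1)
    ]


def expand_isoforms(sequence: str) -> list[str]:
    """Unambiguous expansions of a degenerate window, in deterministic
    (lexicographic, A<C<G<T per position) order; length equals
    ``sequence_multiplicity(sequence)``."""
    return _expand(sequence)


def contig_iso_totals(contig: PrimerContig, k: int = 12) -> ContigSummary:
    """Length / degeneracy / window / isoform bookkeeping for one contig."""
    windows = enumerate_windows(contig, k)
    return ContigSummary(
        name=contig.name,
        length=contig.length,
        degenerate_bases=contig.degenerate_bases,
        n_kmers=len(windows),
        n_iso_kmers=sum(w.iso_count for w in windows),
    )


def summarize_contigs(contigs: Sequence[PrimerContig], k: int = 12) -> pd.DataFrame:
    """Per-contig summary table with a trailing Total row."""
    rows = [contig_iso_totals(c, k).__dict__ for c in contigs]
    df = pd.DataFrame(rows)
    total = {
        "name": "Total",
        "length": int(df["length"].sum()),
        "degenerate_bases": int(df["degenerate_bases"].sum()),
        "n_kmers": int(df["n_kmers"].sum()),
        "n_iso_kmers": int(df["n_iso_kmers"].sum()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def _uniform_k(windows: Sequence[KmerWindow]) -> int:
    ks = {w.k for w in windows}
    if len(ks) != 1:
        raise ValueError(f"windows must share one k, got sizes {sorted(ks)}")
    return ks.pop()


def scan_database(
    windows: Sequence[KmerWindow],
    records: Iterable[SequenceRecord],
    *,
    keep_positions: bool = True,
) -> list[ScanResult]:
    """Exact-match scan of every window's isoform set against every record.

    Contract: a record scores one ``seq_hits`` for a window iff any isoform
    of that window occurs as an exact substring; all match start offsets are
    retained (unless ``keep_positions`` is off, which keeps only counts and
    duplicate tallies for large scans).  Single pass over the database with
    a set lookup per record position.
    """
    if not windows:
        return []
    k = _uniform_k(windows)
    for w in windows:
        validate(w.sequence)
    iso_map: dict[str, list[int]] = {}
    for wi, w in enumerate(windows):
        for iso in expand_isoforms(w.sequence):
            iso_map.setdefault(iso, []).append(wi)

    n_records = 0
    hits: list[dict[str, list[int]]] = [dict() for _ in windows]
    dup_counts = [0] * len(windows)
    hit_counts = [0] * len(windows)
    for rec in records:
        n_records += 1
        seq = rec.sequence
        per_window: dict[int, list[int]] = {}
        get = iso_map.get
        for i in range(len(seq) - k + 1):
            wl = get(seq[i : i + k])
            if wl is not None:
                for wi in wl:
                    per_window.setdefault(wi, []).append(i)
        for wi, positions in per_window.items():
            hit_counts[wi] += 1
            if len(positions) >= 2:
                dup_counts[wi] += 1
            if keep_positions:
                hits[wi][rec.id] = positions
    if n_records == 0:
        raise ValueError("empty database")

    return [
        ScanResult(
            window=w,
            n_records=n_records,
            seq_hits=hit_counts[wi],
            n_duplicate_records=dup_counts[wi],
            hit_positions=hits[wi],
        )
        for wi, w in enumerate(windows)
    ]


def _duplicate_total(results: Sequence[ScanResult]) -> int:
    return sum(r.n_duplicate_records for r in results)


def specificity_analysis(
    contig: PrimerContig,
    records: Sequence[SequenceRecord],
    k_range: Sequence[int] = range(9, 16),
) -> SpecificityCurve:
    """Duplicate-reaction curve over k, per contig.

    For each k, sums over the contig's windows the number of records with at
    least two distinct match positions for that window.  Longer k-mers are
    more astringent, so the curve falls with k; the working size sits at the
    inflection point.
    """
    ks = sorted(k_range)
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 1 or ks[-1] > contig.length:
        raise ValueError(
            f"k range {ks[0]}..{ks[-1]} outside contig {contig.name} "
            f"(length {contig.length})"
        )
    counts = [
        _duplicate_total(scan_database(enumerate_windows(contig, k), records))
        for k in ks
    ]
    return SpecificityCurve(
        contig_name=contig.name,
        k_values=ks,
        duplicate_counts=counts,
        selected_k=_select_inflection(ks, counts),
    )


def _select_inflection(ks: list[int], counts: list[int], default: int = 12) -> int:
    """Smallest k with the largest positive second difference of the
    duplicate-count curve; *default* when the curve has no convex kink."""
    best_k, best_sd = None, 0
    for i in range(1, len(ks) - 1):
        sd = counts[i - 1] - 2 * counts[i] + counts[i + 1]
        if sd > best_sd:
            best_k, best_sd = ks[i], sd
    if best_k is not None:
        return best_k
    if ks[0] <= default <= ks[-1]:
        return default
    return ks[len(ks) // 2]
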