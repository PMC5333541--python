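"""FASTA and report I/O, handling the SILVA dialect.

SILVA SSU distributions use the RNA alphabet (U), may carry alignment gap
characters ('-', '.') and occasional IUPAC ambiguity codes, and put a
taxonomy path after the accession in the header.  Normalization maps every
record onto the uppercase, ungapped DNA alphabet the scanner expects:
uppercase, U->T, gaps stripped.  Reading streams one record at a time
(Biopython underneath) so databases of hundreds of thousands of records
never need to fit in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "FastaReadStats",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "write_tsv",
]

_GAP_TRANSLATION = str.maketrans({"-": None, ".": None, "u": "T", "U": "T"})


@dataclass(frozen=True)
class SequenceRecord:
    """One database record: accession-like id, free-text description
    (taxonomy path in SILVA) and normalized sequence."""

    id: str
    sequence: str
    description: str = ""


@dataclass
class FastaReadStats:
    """Side-channel counters filled while streaming a FASTA file."""

    n_read: int = 0
    n_skipped_short: int = 0
    duplicate_ids: list[str] = field(default_factory=list)


def normalize_sequence(raw: str) -> str:
    """Uppercase, U->T, alignment gaps ('-', '.') removed.  Idempotent."""
    return raw.translate(_GAP_TRANSLATION).upper()


def read_fasta(
    path: str | Path,
    min_length: int = 0,
    stats: FastaReadStats | None = None,
) -> Iterator[SequenceRecord]:
    """Stream normalized records from a FASTA file.

    Records shorter than *min_length* after normalization are skipped (and
    counted in *stats* when given); duplicate ids are flagged in *stats*.
    Raises a parse error with the line number when sequence data precedes
    the first header.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first "
                    f"FASTA header ('>')"
                )
            break
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = normalize_sequence(str(rec.seq))
            if len(seq) < min_length:
                if stats is not None:
                    stats.n_skipped_short += 1
                continue
            if stats is not None:
                stats.n_read += 1
                if rec.id in seen:
                    stats.duplicate_ids.append(rec.id)
                seen.add(rec.id)
            description = rec.description[len(rec.id) :].strip()
            yield SequenceRecord(id=rec.id, sequence=seq, description=description)


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | Path,
    *,
    rna: bool = False,
    width: int = 70,
) -> int:
    """Write records as FASTA, optionally in the RNA alphabet (T->U).
    Returns the number of records written."""
    n = 0
    with open(path, "w", encoding="utf-8") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            seq = rec.sequence.replace("T", "U") if rna else rec.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
            n += 1
    return n


def write_tsv(table: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write a report table as UTF-8 TSV with a header row."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(list(table))
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
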