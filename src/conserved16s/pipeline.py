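"""End-to-end orchestration: contigs -> k-mers -> scan -> anchor -> recover
-> NR -> frequencies -> consensus, with report tables on disk.

Reports are deterministic: identical config + seed produce byte-identical
files (no timestamps inside reports; timings go to the stderr log).  The
database is streamed from disk on every pass, so memory stays bounded by
one record regardless of database size.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from . import __version__
from .conservation_stats import (
    consensus_result,
    dedupe_nr,
    nr_needed,
    position_frequencies,
)
from .database_io import (
    FastaReadStats,
    SequenceRecord,
    read_fasta,
    write_fasta,
    write_tsv,
)
from .fragment_recovery import recover_all, select_anchor
from .kmer_engine import enumerate_windows, scan_database, summarize_contigs
from .primer_model import PrimerContig, load_reference_contigs
from .synthetic_data import SimulationConfig, generate_database, write_database

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("conserved16s")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Run parameterization.  The defaults (k=12, theta=0.95, f=0.95)
    reproduce the study parameterization."""

    outdir: Path
    database: Path | None = None
    simulate: SimulationConfig | None = None
    k: int = 12
    contig_names: tuple[str, ...] | None = None  # None -> all 15
    theta: float = 0.95  # conservation threshold on max-base frequency
    tau: float = 0.05  # consensus inclusion threshold
    coverage_fraction: float = 0.95  # NR coverage target
    min_length: int = 0  # database length filter (1200 in the study)
    recover: tuple[str, ...] | None = None  # contigs to recover; None -> all hit

    def to_dict(self) -> dict:
        return {
            "database": str(self.database) if self.database else None,
            "simulate": self.simulate.seed if self.simulate else None,
            "k": self.k,
            "contig_names": list(self.contig_names) if self.contig_names else None,
            "theta": self.theta,
            "tau": self.tau,
            "coverage_fraction": self.coverage_fraction,
            "min_length": self.min_length,
            "recover": list(self.recover) if self.recover else None,
        }


def _select_contigs(names: tuple[str, ...] | None) -> list[PrimerContig]:
    contigs = load_reference_contigs()
    if names is None:
        return contigs
    by_name = {c.name: c for c in contigs}
    missing = [n for n in names if n not in by_name]
    if missing:
        raise PipelineError("contigs", f"unknown contig name(s): {missing}")
    return [by_name[n] for n in names]


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a bundle of output paths and
    headline numbers (also written to ``run_metadata.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = _select_contigs(config.contig_names)
    outputs: dict[str, object] = {"outdir": str(outdir)}

    with _timed("contigs"):
        summary = summarize_contigs(contigs, config.k)
        write_tsv(summary, outdir / "contig_summary.tsv")
        outputs["contig_summary"] = str(outdir / "contig_summary.tsv")

    db_path = config.database
    if config.simulate is not None:
        with _timed("simulate"):
            records, manifest = generate_database(config.simulate)
            db_path = outdir / "database.fasta"
            write_database(records, manifest, db_path, outdir / "manifest.json")
            outputs["database"] = str(db_path)
            outputs["manifest"] = str(outdir / "manifest.json")
    if db_path is None:
        # contig-table-only run
        _write_metadata(config, outputs, outdir)
        return outputs

    def records_stream() -> Iterable[SequenceRecord]:
        return read_fasta(db_path, min_length=config.min_length)

    with _timed("scan"):
        windows = [w for c in contigs for w in enumerate_windows(c, config.k)]
        if not windows:
            raise PipelineError("scan", "no windows (contigs shorter than k?)")
        try:
            results = scan_database(windows, records_stream(), keep_positions=False)
        except ValueError as exc:
            raise PipelineError("scan", str(exc)) from exc
        n_records = results[0].n_records
        scan_rows = [
            {
                "contig": r.window.contig_name,
                "number": r.window.index,
                "sequence": r.window.sequence,
                "hits": r.seq_hits,
                "percent": f"{r.percent:.2f}",
            }
            for r in results
        ]
        write_tsv(scan_rows, outdir / "scan.tsv")
        outputs["scan"] = str(outdir / "scan.tsv")

    with _timed("anchor"):
        by_contig: dict[str, list] = {}
        for r in results:
            by_contig.setdefault(r.window.contig_name, []).append(r)
        anchors = {}
        anchor_rows = []
        for c in contigs:
            contig_results = by_contig[c.name]
            best = max(contig_results, key=lambda r: (r.seq_hits, -r.window.index))
            anchor_rows.append(
                {
                    "contig": c.name,
                    "number": best.window.index,
                    "sequence": best.window.sequence,
                    "hits": best.seq_hits,
                    "percent": f"{best.percent:.2f}",
                }
            )
            if best.seq_hits > 0:
                anchors[c.name] = select_anchor(contig_results, c.length)
        write_tsv(anchor_rows, outdir / "anchors.tsv")
        outputs["anchors"] = str(outdir / "anchors.tsv")

    to_recover = (
        [n for n in anchors]
        if config.recover is None
        else [n for n in config.recover if n in anchors]
    )
    consensus_records: list[SequenceRecord] = []
    contig_stats: dict[str, dict] = {}
    by_name = {c.name: c for c in contigs}
    for name in to_recover:
        contig = by_name[name]
        with _timed(f"recover:{name}"):
            fragset = recover_all(records_stream(), anchors[name], keep_outcomes=True)
            frag_records = [
                SequenceRecord(id=rid, sequence=frag)
                for rid, frag in fragset.fragments
            ]
            write_fasta(frag_records, outdir / f"fragments_{name}.fasta")
            write_tsv(
                [
                    {
                        "record": o.record_id,
                        "outcome": o.status.value,
                        "match_offset": "" if o.match_offset is None else o.match_offset,
                        "duplicate": int(o.duplicate),
                    }
                    for o in fragset.outcomes
                ],
                outdir / f"recovery_{name}.tsv",
            )
        if not fragset.fragments:
            contig_stats[name] = {
                "n_fragments": 0,
                "n_truncated": fragset.n_truncated,
                "n_unmatched": fragset.n_unmatched,
            }
            continue
        with _timed(f"nr:{name}"):
            nr = dedupe_nr(frag for _, frag in fragset.fragments)
            write_tsv(
                [
                    {"sequence": s, "abundance": a}
                    for s, a in nr.entries
                ],
                outdir / f"nr_{name}.tsv",
            )
            needed = nr_needed(nr, config.coverage_fraction)
        with _timed(f"consensus:{name}"):
            mode_results = {}
            for mode in ("all", "nr"):
                matrix = position_frequencies(nr, contig_name=name, mode=mode)
                cons = consensus_result(matrix, theta=config.theta, tau=config.tau)
                freq_rows = [
                    {
                        "position": p,
                        "A": f"{matrix.freq[p, 0]:.6f}",
                        "C": f"{matrix.freq[p, 1]:.6f}",
                        "G": f"{matrix.freq[p, 2]:.6f}",
                        "T": f"{matrix.freq[p, 3]:.6f}",
                        "max": f"{matrix.max_base_freq[p]:.6f}",
                        "conserved": int(cons.conserved_mask[p]),
                    }
                    for p in range(matrix.length)
                ]
                write_tsv(freq_rows, outdir / f"freq_{mode}_{name}.tsv")
                consensus_records.append(
                    SequenceRecord(
                        id=f"{name}|{mode}",
                        sequence=cons.consensus,
                        description=(
                            f"consensus mode={mode} theta={config.theta} "
                            f"tau={config.tau} n_conserved={cons.n_conserved}"
                        ),
                    )
                )
                mode_results[mode] = cons
        contig_stats[name] = {
            "n_fragments": len(fragset.fragments),
            "n_truncated": fragset.n_truncated,
            "n_unmatched": fragset.n_unmatched,
            "n_duplicate_bearing": fragset.n_duplicate_bearing,
            "n_nr": nr.n_unique,
            "reduction_percent": round(nr.reduction_percent, 2),
            "nr_needed": needed,
            "nr_needed_percent_of_nr": round(100.0 * needed / nr.n_unique, 2),
            "n_conserved_all": mode_results["all"].n_conserved,
            "n_conserved_nr": mode_results["nr"].n_conserved,
        }

    consensus_records.extend(
        SequenceRecord(id=f"{c.name}|contig", sequence=c.sequence)
        for c in contigs
        if c.name in to_recover
    )
    consensus_records.sort(key=lambda r: r.id)
    write_fasta(consensus_records, outdir / "consensus.fasta")
    outputs["consensus"] = str(outdir / "consensus.fasta")
    outputs["n_records"] = n_records
    outputs["contig_stats"] = contig_stats
    _write_metadata(config, outputs, outdir)
    return outputs


def _write_metadata(config: RunConfig, outputs: dict, outdir: Path) -> None:
    def _rel(v: str) -> str:
        # keep reports byte-identical across output locations
        try:
            return str(Path(v).relative_to(outdir))
        except ValueError:
            return v

    meta = {
        "tool": "conserved16s",
        "version": __version__,
        "parameters": config.to_dict(),
        "outputs": {
            k: _rel(v) for k, v in outputs.items() if isinstance(v, str)
        },
        "n_records": outputs.get("n_records"),
        "contig_stats": outputs.get("contig_stats"),
    }
    (outdir / "run_metadata.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True), encoding="utf-8"
    )
    outputs["run_metadata"] = str(outdir / "run_metadata.json")
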