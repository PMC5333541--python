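"""SILVA-like synthetic 16S databases with exact ground truth.

The generator emulates the features of a SILVA SSU style database that the
pipeline has to cope with — RNA alphabet on disk, occasional ambiguity
characters, missing 200-300 nt end segments on a fraction of records, and
heavy redundancy with a skewed (Zipf) abundance distribution — while
recording every sampling decision in a manifest so downstream stages can be
checked against known truth.

Model: a random full-length template (1,542 nt, the E. coli 16S length)
carries one fixed isoform of each primer contig at its E. coli coordinates.
A pool of *variants* is derived from the template by independent
per-position substitutions at rate epsilon (uniform over the three
alternative bases), so the true max-base frequency at every contig position
is exactly 1 - epsilon.  Records are copies of variants — abundances follow
a deterministic largest-remainder Zipf allocation — optionally truncated at
one end and sprinkled with ambiguity characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from . import iupac
from .database_io import SequenceRecord, write_fasta
from .primer_model import PrimerContig, load_reference_contigs

__all__ = [
    "SimulationConfig",
    "GroundTruthManifest",
    "generate_database",
    "write_database",
    "regression_fixture",
    "REGRESSION_CONFIG",
]

_BASES = np.array(list(iupac.BASES))
#: ambiguous codes (multiplicity >= 2) containing each base, sorted
_AMBIGUOUS_FOR: dict[str, list[str]] = {
    b: sorted(
        s
        for s in iupac.DEGENERATE_SYMBOLS
        if b in iupac.CODE_TO_BASES[s]
    )
    for b in iupac.BASES
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; the defaults are the study-like conditions.

    ``substitution_rate`` may be a scalar or a per-position vector over the
    template; ``truncation_range`` is the inclusive lo..hi of removed end
    lengths.  ``seed`` is mandatory: the same seed yields byte-identical
    output.
    """

    n_records: int
    seed: int
    template_length: int = 1542
    contigs: tuple[PrimerContig, ...] | None = None  # None -> reference set
    substitution_rate: float | tuple[float, ...] = 0.02
    degenerate_char_rate: float = 0.001
    truncation_prob: float = 0.1
    truncation_range: tuple[int, int] = (200, 300)
    n_variants: int | None = None  # None -> max(1, n_records // 50)
    zipf_exponent: float = 1.5
    rna_alphabet: bool = True

    def __post_init__(self) -> None:
        for name in ("degenerate_char_rate", "truncation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.truncation_range
        if lo > hi or lo < 0:
            raise ValueError(f"bad truncation range {self.truncation_range}")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")

    def resolved_contigs(self) -> tuple[PrimerContig, ...]:
        return self.contigs if self.contigs is not None else tuple(
            load_reference_contigs()
        )

    def resolved_n_variants(self) -> int:
        if self.n_variants is not None:
            return self.n_variants
        return max(1, self.n_records // 50)

    def epsilon_vector(self) -> np.ndarray:
        eps = np.asarray(self.substitution_rate, dtype=float)
        if eps.ndim == 0:
            eps = np.full(self.template_length, float(eps))
        if eps.shape != (self.template_length,):
            raise ValueError("substitution_rate vector length != template_length")
        if (eps < 0).any() or (eps > 1).any():
            raise ValueError("substitution rates must be in [0, 1]")
        return eps


@dataclass
class GroundTruthManifest:
    """Everything the generator decided, reproducible from the seed."""

    seed: int
    config: dict
    template: str  # reference sequence with contig isoforms embedded
    variants: list[dict]  # {id, sequence, abundance}
    records: list[dict]  # {id, variant, truncated_side, truncated_len}
    regions: dict[str, dict]  # contig name -> {start0, end0, planted}

    def variant_sequence(self, variant_id: str) -> str:
        return self._variant_index()[variant_id]

    def _variant_index(self) -> dict[str, str]:
        return {v["id"]: v["sequence"] for v in self.variants}

    def variant_fragment(self, variant_id: str, contig_name: str) -> str:
        """The planted (pre-truncation) contig-region string of a variant."""
        region = self.regions[contig_name]
        return self.variant_sequence(variant_id)[region["start0"] : region["end0"]]

    def record_fragment(self, record_id: str, contig_name: str) -> str:
        rec = next(r for r in self.records if r["id"] == record_id)
        return self.variant_fragment(rec["variant"], contig_name)

    def true_base_distribution(
        self, contig_name: str, epsilon: np.ndarray
    ) -> np.ndarray:
        """Expected L x 4 base distribution over variants for one contig
        region: 1 - eps on the planted base, eps/3 on each alternative."""
        region = self.regions[contig_name]
        start, end = region["start0"], region["end0"]
        planted = self.template[start:end]
        dist = np.empty((end - start, 4))
        for p, base in enumerate(planted):
            e = epsilon[start + p]
            dist[p] = e / 3.0
            dist[p, iupac.BASES.index(base)] = 1.0 - e
        return dist

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "template": self.template,
                "variants": self.variants,
                "records": self.records,
                "regions": self.regions,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            config=d["config"],
            template=d["template"],
            variants=d["variants"],
            records=d["records"],
            regions=d["regions"],
        )


def _zipf_counts(n_records: int, n_variants: int, exponent: float) -> list[int]:
    """Deterministic largest-remainder allocation of records to variants
    with Zipf weights; every variant gets at least one record."""
    if n_variants > n_records:
        raise ValueError("n_variants cannot exceed n_records")
    weights = np.arange(1, n_variants + 1, dtype=float) ** (-exponent)
    weights /= weights.sum()
    spare = n_records - n_variants
    raw = weights * spare
    counts = np.ones(n_variants, dtype=int) + np.floor(raw).astype(int)
    remainder = raw - np.floor(raw)
    deficit = n_records - int(counts.sum())
    for idx in np.argsort(-remainder, kind="stable")[:deficit]:
        counts[idx] += 1
    return counts.tolist()


def generate_database(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], GroundTruthManifest]:
    """Sample a database and its ground truth.

    Returned records are in the normalized DNA alphabet (the RNA flag only
    affects FASTA serialization via :func:`write_database`); the manifest
    reproduces every sampling decision for the given seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.template_length
    contigs = config.resolved_contigs()
    eps = config.epsilon_vector()

    for c in contigs:
        if c.ecoli_end > L:
            raise ValueError(
                f"template length {L} shorter than contig {c.name} "
                f"end {c.ecoli_end}"
            )

    # template with one fixed isoform of each contig embedded
    template = _BASES[rng.integers(0, 4, size=L)]
    regions: dict[str, dict] = {}
    for c in contigs:
        start0 = c.ecoli_start - 1
        planted = [
            b[rng.integers(0, len(b))] if len(b) > 1 else b[0]
            for b in (iupac.bases(s) for s in c.sequence)
        ]
        template[start0 : c.ecoli_end] = planted
        regions[c.name] = {
            "start0": start0,
            "end0": c.ecoli_end,
            "planted": "".join(planted),
        }
    template_str = "".join(template)

    # variant pool: independent per-position substitutions at rate epsilon
    n_variants = config.resolved_n_variants()
    counts = _zipf_counts(config.n_records, n_variants, config.zipf_exponent)
    base_idx = {b: i for i, b in enumerate(iupac.BASES)}
    template_idx = np.array([base_idx[b] for b in template_str])
    variants: list[dict] = []
    for v in range(n_variants):
        mask = rng.random(L) < eps
        idx = template_idx.copy()
        if mask.any():
            # alternative base = (reference + 1..3) mod 4, uniform
            shift = rng.integers(1, 4, size=int(mask.sum()))
            idx[mask] = (idx[mask] + shift) % 4
        variants.append(
            {
                "id": f"V{v:04d}",
                "sequence": "".join(_BASES[idx]),
                "abundance": counts[v],
            }
        )

    # records: shuffled copies of variants, truncated / degenerate-sprinkled
    order = rng.permutation(
        np.repeat(np.arange(n_variants), counts)
    )
    records: list[SequenceRecord] = []
    record_truth: list[dict] = []
    lo, hi = config.truncation_range
    for i, v_idx in enumerate(order):
        variant = variants[int(v_idx)]
        seq = variant["sequence"]
        side, cut = None, 0
        if config.truncation_prob > 0 and rng.random() < config.truncation_prob:
            side = "5p" if rng.random() < 0.5 else "3p"
            cut = int(rng.integers(lo, hi + 1))
            cut = min(cut, len(seq) - 1)
            seq = seq[cut:] if side == "5p" else seq[: len(seq) - cut]
        if config.degenerate_char_rate > 0:
            chars = list(seq)
            mask = rng.random(len(chars)) < config.degenerate_char_rate
            for p in np.nonzero(mask)[0]:
                options = _AMBIGUOUS_FOR[chars[p]]
                chars[p] = options[int(rng.integers(0, len(options)))]
            seq = "".join(chars)
        rec_id = f"SYN{i:06d}"
        records.append(
            SequenceRecord(
                id=rec_id,
                sequence=seq,
                description=f"synthetic 16S;variant={variant['id']}",
            )
        )
        record_truth.append(
            {
                "id": rec_id,
                "variant": variant["id"],
                "truncated_side": side,
                "truncated_len": cut,
            }
        )

    cfg_dict = {
        "n_records": config.n_records,
        "seed": config.seed,
        "template_length": L,
        "substitution_rate": (
            float(eps[0]) if np.allclose(eps, eps[0]) else eps.tolist()
        ),
        "degenerate_char_rate": config.degenerate_char_rate,
        "truncation_prob": config.truncation_prob,
        "truncation_range": list(config.truncation_range),
        "n_variants": n_variants,
        "zipf_exponent": config.zipf_exponent,
        "rna_alphabet": config.rna_alphabet,
    }
    manifest = GroundTruthManifest(
        seed=config.seed,
        config=cfg_dict,
        template=template_str,
        variants=variants,
        records=record_truth,
        regions=regions,
    )
    return records, manifest


def write_database(
    records: Sequence[SequenceRecord],
    manifest: GroundTruthManifest,
    fasta_path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Serialize a generated database: FASTA (RNA alphabet when configured)
    plus the JSON manifest."""
    write_fasta(records, fasta_path, rna=bool(manifest.config.get("rna_alphabet")))
    if manifest_path is not None:
        Path(manifest_path).write_text(manifest.to_json(), encoding="utf-8")


#: pinned configuration of the packaged regression fixture
REGRESSION_CONFIG = SimulationConfig(
    n_records=30,
    seed=20170228,
    n_variants=7,
    substitution_rate=0.01,
    degenerate_char_rate=0.0,
    truncation_prob=0.1,
)


def regression_fixture() -> tuple[list[SequenceRecord], GroundTruthManifest]:
    """The small packaged database (30 records, 7 variants) used by the test
    suite; regenerating with :data:`REGRESSION_CONFIG` reproduces it
    byte-identically."""
    pkg = resources.files(__package__)
    manifest = GroundTruthManifest.from_json(
        pkg.joinpath("data/regression_manifest.json").read_text(encoding="utf-8")
    )
    from .database_io import read_fasta  # local import avoids cycle at import time

    with resources.as_file(pkg.joinpath("data/regression_db.fasta")) as p:
        records = list(read_fasta(p))
    return records, manifest
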