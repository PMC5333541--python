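import pytest

from conserved16s import (
    SequenceRecord,
    SimulationConfig,
    generate_database,
    load_reference_contigs,
)


@pytest.fixture(scope="session")
def contigs():
    return load_reference_contigs()


@pytest.fixture(scope="session")
def contig_by_name(contigs):
    return {c.name: c for c in contigs}


@pytest.fixture(scope="session")
def small_db():
    """100-record synthetic database (DNA alphabet, light mutation) with
    its ground-truth manifest; shared across scan/recovery tests."""
    cfg = SimulationConfig(
        n_records=100,
        seed=7,
        n_variants=10,
        substitution_rate=0.01,
        degenerate_char_rate=0.0,
        truncation_prob=0.1,
        rna_alphabet=False,
    )
    return generate_database(cfg)


def make_records(*sequences: str) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=f"r{i}", sequence=s) for i, s in enumerate(sequences, 1)
    ]
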