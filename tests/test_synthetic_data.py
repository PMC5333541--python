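"""The SILVA-like generator: determinism, ground truth, packaged fixture."""

import numpy as np
import pytest
from scipy import stats as scipy_stats

from conserved16s import (
    SimulationConfig,
    dedupe_nr,
    enumerate_windows,
    expand_isoforms,
    generate_database,
    nr_needed,
    regression_fixture,
    scan_database,
    write_database,
)
from conserved16s.synthetic_data import REGRESSION_CONFIG, _zipf_counts


class TestZipfAllocation:
    def test_counts_sum_and_minimum(self):
        counts = _zipf_counts(100, 10, 1.5)
        assert sum(counts) == 100
        assert min(counts) >= 1
        assert counts == sorted(counts, reverse=True)

    def test_more_variants_than_records_rejected(self):
        with pytest.raises(ValueError):
            _zipf_counts(5, 10, 1.5)


class TestGenerateDatabase:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_records=20, seed=99, n_variants=4)
        paths = []
        for run in ("a", "b"):
            records, manifest = generate_database(cfg)
            fasta = tmp_path / f"{run}.fasta"
            mjson = tmp_path / f"{run}.json"
            write_database(records, manifest, fasta, mjson)
            paths.append((fasta.read_bytes(), mjson.read_bytes()))
        assert paths[0] == paths[1]

    def test_clean_database_scans_at_full_frequency(self, contigs):
        """With no mutation, truncation or redundancy noise, every contig
        window hits 100% of records."""
        cfg = SimulationConfig(
            n_records=10,
            seed=5,
            n_variants=1,
            substitution_rate=0.0,
            degenerate_char_rate=0.0,
            truncation_prob=0.0,
            rna_alphabet=False,
        )
        records, manifest = generate_database(cfg)
        windows = [w for c in contigs for w in enumerate_windows(c, 12)]
        for res in scan_database(windows, records):
            assert res.percent == 100.0

    def test_planted_regions_are_contig_isoforms(self, contigs):
        cfg = SimulationConfig(
            n_records=2, seed=8, n_variants=1, substitution_rate=0.0,
            truncation_prob=0.0, degenerate_char_rate=0.0, rna_alphabet=False,
        )
        _, manifest = generate_database(cfg)
        for c in contigs:
            planted = manifest.regions[c.name]["planted"]
            assert planted in expand_isoforms(c.sequence)

    def test_truncation_removes_configured_end_lengths(self):
        cfg = SimulationConfig(
            n_records=200, seed=13, n_variants=5, truncation_prob=0.5,
            truncation_range=(200, 300), degenerate_char_rate=0.0,
            rna_alphabet=False,
        )
        records, manifest = generate_database(cfg)
        by_id = {r.id: r for r in records}
        n_truncated = 0
        for rec in manifest.records:
            seq = by_id[rec["id"]].sequence
            if rec["truncated_side"] is None:
                assert len(seq) == 1542
            else:
                n_truncated += 1
                assert 200 <= rec["truncated_len"] <= 300
                assert len(seq) == 1542 - rec["truncated_len"]
                variant = manifest.variant_sequence(rec["variant"])
                if rec["truncated_side"] == "5p":
                    assert variant.endswith(seq)
                else:
                    assert variant.startswith(seq)
        # binomial 4-sigma band around p = 0.5
        assert abs(n_truncated / 200 - 0.5) < 4 * np.sqrt(0.25 / 200)

    def test_ambiguity_characters_injected_at_configured_rate(self):
        cfg = SimulationConfig(
            n_records=50, seed=21, n_variants=2, substitution_rate=0.0,
            truncation_prob=0.0, degenerate_char_rate=0.02, rna_alphabet=False,
        )
        records, _ = generate_database(cfg)
        n_ambig = sum(
            1 for r in records for ch in r.sequence if ch not in "ACGT"
        )
        n_total = sum(len(r.sequence) for r in records)
        rate = n_ambig / n_total
        assert abs(rate - 0.02) < 4 * np.sqrt(0.02 * 0.98 / n_total)

    def test_substitutions_match_configured_rate(self):
        """Chi-square sanity: observed per-position substitution counts over
        many variants are consistent with epsilon."""
        eps = 0.05
        cfg = SimulationConfig(
            n_records=400, seed=17, n_variants=400, substitution_rate=eps,
            truncation_prob=0.0, degenerate_char_rate=0.0, rna_alphabet=False,
        )
        _, manifest = generate_database(cfg)
        template = manifest.template
        diffs = sum(
            sum(a != b for a, b in zip(v["sequence"], template))
            for v in manifest.variants
        )
        total = 400 * len(template)
        observed = [diffs, total - diffs]
        expected = [eps * total, (1 - eps) * total]
        assert scipy_stats.chisquare(observed, expected).pvalue > 1e-4

    def test_template_shorter_than_contig_coordinates_rejected(self):
        with pytest.raises(ValueError, match="template length"):
            generate_database(
                SimulationConfig(n_records=1, seed=1, template_length=100)
            )

    def test_rna_flag_emits_u_on_disk(self, tmp_path):
        cfg = SimulationConfig(n_records=2, seed=3, n_variants=1)
        records, manifest = generate_database(cfg)
        write_database(records, manifest, tmp_path / "db.fasta")
        body = (tmp_path / "db.fasta").read_text()
        assert "U" in body and "T" not in body.split("\n", 1)[1]


class TestRegressionFixture:
    def test_loads_and_matches_generator_output(self, tmp_path):
        """The packaged FASTA/manifest are exactly what REGRESSION_CONFIG
        regenerates."""
        records, manifest = regression_fixture()
        assert len(records) == 30
        regen_records, regen_manifest = generate_database(REGRESSION_CONFIG)
        assert [r.sequence for r in records] == [
            r.sequence for r in regen_records
        ]
        assert manifest.to_json() == regen_manifest.to_json()

    def test_known_variant_composition(self):
        _, manifest = regression_fixture()
        abundances = [v["abundance"] for v in manifest.variants]
        assert len(abundances) == 7
        assert sum(abundances) == 30
        assert abundances == _zipf_counts(30, 7, 1.5)

    def test_nr_composition_of_planted_fragments_matches_manifest(self):
        """NR reduction of the planted contig-3 fragments equals the oracle
        computed from the manifest's variant assignment."""
        records, manifest = regression_fixture()
        from collections import Counter

        expected = Counter(
            manifest.variant_fragment(r["variant"], "3")
            for r in manifest.records
        )
        table = dedupe_nr(
            manifest.variant_fragment(r["variant"], "3")
            for r in manifest.records
        )
        assert dict(table.entries) == dict(expected)
        # cumulative-sum oracle for the coverage count
        abundances = sorted(expected.values(), reverse=True)
        target = 0.95 * sum(abundances)
        cumulative, m = 0, 0
        for a in abundances:
            cumulative += a
            m += 1
            if cumulative >= target:
                break
        assert nr_needed(table, 0.95) == m
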