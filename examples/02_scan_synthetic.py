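"""Exact 12-mer scan of a synthetic SILVA-like database.

Simulates 500 full-length 16S-like records (2% per-position substitution,
10% missing-end records, skewed redundancy), scans every contig's 12-mer
isoforms against them, and prints the best-covered window per contig — the
window that would serve as the fragment-recovery anchor.
"""

from conserved16s import (
    SimulationConfig,
    enumerate_windows,
    generate_database,
    load_reference_contigs,
    scan_database,
)

records, _ = generate_database(
    SimulationConfig(n_records=500, seed=11, rna_alphabet=False)
)
contigs = load_reference_contigs()
windows = [w for c in contigs for w in enumerate_windows(c, 12)]
results = scan_database(windows, records, keep_positions=False)

print(f"{'contig':>6} {'window':>6} {'sequence':<14} {'hits':>5} {'percent':>8}")
for c in contigs:
    best = max(
        (r for r in results if r.window.contig_name == c.name),
        key=lambda r: (r.seq_hits, -r.window.index),
    )
    print(
        f"{c.name:>6} {best.window.index:>6} {best.window.sequence:<14} "
        f"{best.seq_hits:>5} {best.percent:>7.2f}%"
    )
print(
    "\nNo window reaches 100%: records missing a 200-300 nt end segment "
    "lose the extreme regions (1, 10) entirely, and because records are "
    "redundant copies of a small variant pool, a mutation in a dominant "
    "variant depresses a window's coverage by that variant's whole share."
)
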