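"""k-size specificity: how often does a k-mer hit the same record twice?

A primer-sized probe should locate one position per 16S record.  For each
k from 9 to 15 this counts, over the windows of contig 3, records matched
at two or more positions ("duplicate reactions") in a synthetic database
carrying an extra planted repeat, and reports the k selected at the
curve's inflection point.
"""

import numpy as np

from conserved16s import (
    SequenceRecord,
    SimulationConfig,
    generate_database,
    load_reference_contigs,
    specificity_analysis,
)

records, _ = generate_database(
    SimulationConfig(n_records=300, seed=31, rna_alphabet=False)
)
# plant a second copy of a contig-3 sub-segment in some records so short
# k-mers show duplicate reactions
contig = next(c for c in load_reference_contigs() if c.name == "3")
rng = np.random.default_rng(31)
segment = "ACTGAGAAACGGTCCAAACT"  # one isoform of the contig's 5' end
records = [
    (
        SequenceRecord(id=r.id, sequence=r.sequence + segment)
        if rng.random() < 0.3
        else r
    )
    for r in records
]

curve = specificity_analysis(contig, records, range(9, 16))
print(" k  duplicate records")
for k, d in zip(curve.k_values, curve.duplicate_counts):
    marker = "  <- selected" if k == curve.selected_k else ""
    print(f"{k:>2}  {d:>5}{marker}")
print(
    "\nDuplicates fall as k grows; the inflection point marks the "
    "shortest k that is already specific (12 in the study)."
)
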