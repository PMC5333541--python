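# Methods

## Primer contigs

A *primer contig* stacks every published primer targeting one conserved
region of the 16S rRNA gene on the *E. coli* coordinate line (1-based,
inclusive) and takes per position the minimal IUPAC code covering the
union of the primers' base sets; primers that leave an uncovered position
split the region into sub-contigs (a/b/c), signalled explicitly by
`assemble_contig` rather than merged silently. The fifteen reference
contigs are packaged as a TSV fixture (`data/primer_contigs.tsv`); every
row was verified span-consistent (end − start + 1 equals the sequence
length) before freezing. K, absent from some multiplicity listings, is a
two-fold code (T/G) like the other two-base symbols.

## Windows, isoforms, scanning

A contig of length L yields L − k + 1 windows (k = 12 default; the window
index is 0-based). A window expands into the cartesian product of its
per-position base sets; the isoform count equals the product of
multiplicities, and the expansion order is deterministic (A < C < G < T
per position). Scanning is exact substring equality of any isoform
against normalized records, forward strand only: SILVA stores SSU
sequences in the gene's sense orientation, so no reverse-complement pass
is made, and ambiguity characters *inside* records never match (searching
the literal sequence). The implementation is a single streaming pass with
a hash lookup per record position; its contract — and its test oracle —
is the naive per-record, per-isoform search.

Records counted once per window regardless of match count; records
matching a window at ≥2 distinct positions are "duplicate reactions".
The specificity curve sums duplicate counts over a contig's windows for
each k in 9..15 and selects the smallest k at the largest positive second
difference of that curve (the inflection), defaulting to 12 when the
curve is flat or concave. The per-contig aggregation and the
second-difference rule are this package's concretizations of the
qualitative inflection-point criterion.

## Normalization

FASTA records (Biopython underneath) are uppercased, U→T mapped, and
alignment gaps ('-', '.') stripped, making both the aligned and unaligned
SILVA distributions usable and letting DNA probes match RNA-alphabet
records. Normalization is idempotent; records shorter than `min_length`
after normalization are skipped and counted (the study's filter is 1,200
nt, applied via configuration, not hardcoded). Reading is streaming:
memory is bounded by one record.

## Fragment recovery

The anchor of a contig is its highest-hit window (ties: smallest index).
Each record is sliced `[m − left, m + k + right)` around the 5′-most
anchor match m, with left = window index and right = L − k − index, so
every recovered fragment has exactly contig length and carries the anchor
at the same offset — fragments are aligned by construction and no
alignment step exists. Slices crossing a record boundary are *truncated*;
records without a match are *unmatched*; both are counted and excluded
from consensus analysis (padding would fabricate sequence; the low
coverage of the gene's extreme regions is attributed to missing ends, not
padded over). On records with several anchor matches the first is used
and the record is flagged duplicate-bearing.

## NR reduction and conservation

Fragments deduplicate by exact string equality into NR entries sorted by
descending abundance, then lexicographically (deterministic).
`nr_needed(f)` is the smallest m whose top-m abundances reach
f · total (f = 0.95 default). Position frequency matrices weight each
character fractionally over its base set (R → 0.5 A + 0.5 G); "all" mode
weights NR entries by abundance — algebraically identical to counting
every fragment — while "nr" mode gives each distinct sequence weight 1,
so rare variants count as much as dominant ones. Rows over IUPAC-only
input sum to 1 (±1e-9); characters outside the alphabet contribute
nothing and flag their rows. A position is conserved when its max-base
frequency ≥ θ (0.95, the study threshold; the comparison is inclusive
with a 1e-12 float guard). The consensus code per position covers every
base with frequency ≥ τ; τ defaults to 0.05 and is always printed with
reports, since high-degeneracy NR consensuses imply a low inclusion
threshold and no explicit rule is fixed by the study.

## Synthetic databases

The generator emulates the features of a SILVA-like repository that
matter to the pipeline, with every decision recorded in a manifest:

- **Template**: random 1,542 nt (the *E. coli* 16S length) with one fixed
  isoform of each contig embedded at its coordinates. One isoform per
  database (not per variant) makes the true max-base frequency at every
  contig position exactly 1 − ε.
- **Variants**: independent per-position substitutions at rate ε (scalar
  or per-position vector; default 0.02), uniform over the three
  alternative bases — an explicit error model, not a phylogenetic one.
- **Redundancy**: records are copies of variants with Zipf-weighted
  (exponent 1.5) abundances allocated by a deterministic largest-remainder
  rule (each variant ≥1 record), so NR composition is an exact oracle.
  Default pool size is n/50.
- **End truncation**: with probability 0.1 a record loses a uniform
  200–300 nt prefix or suffix (both ends equally likely, since both gene
  extremes show depressed coverage in real repositories).
- **Ambiguity characters**: each base is rewritten with probability 0.001
  to a random ambiguous code containing it.
- **Alphabet**: U is emitted on serialization when `rna_alphabet` is set;
  in-memory records are always normalized DNA.

Identical seeds give byte-identical FASTA and manifest; a 30-record
fixture is packaged and a test regenerates it exactly. What the generator
does **not** emulate: phylogenetic correlation between variants, chimeras,
indels, and sequencing-quality artifacts. Passing tests therefore
demonstrate the pipeline's correctness against known truth, not the
biological values any real repository would yield.

A statistical note that shapes the tests: with redundancy on, per-position
frequencies are weighted averages over the (small) variant pool, so their
sampling variance is governed by the pool, not the record count. Checks
that expect binomial-in-n concentration around 1 − ε run with redundancy
off (one variant per record); redundancy-dependent quantities (NR tables,
coverage counts) are checked against the manifest oracle instead. Recovered
fragments are also conditioned on an intact anchor, so non-degenerate
anchor positions show frequency 1.0 rather than 1 − ε — a property of
anchor-based recovery itself, visible in the reported worst-case frequency
error (exactly ε).

## Problem sizes and numerical choices

Desk-scale runs use seeded synthetic databases of 25–5,000 records
(5,000 for parameter recovery, 3,000 for conservation-mask recovery,
2,000 per database in the acceptance script, 400 for the end-to-end
determinism run) — large enough for 4σ binomial bands around the planted
rates while keeping any single check in seconds. The same code streams a
full SILVA release (~513k records) in hours on one CPU; those
repository-scale numbers are supported but not asserted anywhere in CI.
Ties are broken deterministically throughout (smallest window index,
lexicographic NR order); thresholds compare inclusively with 1e-9–1e-12
float guards; percentages print to 2 decimals.

## Limitations

- Exact matching only: a single substitution, indel or ambiguity
  character inside a record defeats a probe — by design, since the point
  is to measure literal coverage, but it conflates sequencing error with
  biological variation.
- Forward strand only; databases must store the gene in sense
  orientation.
- Truncated fragments are discarded, so consensus denominators shrink
  near the gene's extremes.
- The consensus inclusion threshold τ is a reporting convention; no
  single value is canonical.
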