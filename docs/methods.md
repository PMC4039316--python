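# Methods

## Overview

varigen treats genome simulation as frequency-table sampling. A
variation background — "what a population's variants look like" — is
summarized in three tables estimated from observed variant files:

- **Fragment profiles by GC bin.** Each reference chromosome is cut
  into fragments of `fragment_length` bp (default 1,000; the final
  partial fragment is kept). For each fragment the observed variants
  of each class starting inside it are counted, and its GC fraction is
  computed over unambiguous bases. Profiles are grouped per chromosome
  into GC bins (default 10 equal-width bins over [0, 1]; arbitrary
  strictly increasing edges spanning [0, 1] are accepted). Binning is
  half-open `[e_i, e_{i+1})` with the final bin closed so GC = 1 is
  representable.
- **Size distribution.** For every class except SNV, the pooled
  genome-wide fraction of that class's variants falling in each
  configured size range (default ranges 1–10, 11–100, 101–10,000 bp).
- **SNV transition matrix.** For each reference base, the empirical
  distribution of substitute bases among observed SNVs; a base with no
  observations falls back to a uniform 1/3 row with a warning.

Simulation inverts the summary: each parent fragment is fitted to its
GC bin, one observed profile is drawn uniformly from the bin as the
fragment's mutation budget, and the budget is applied at uniformly
random non-overlapping sites. The simulated genome therefore
reproduces the *frequency distribution* of variation conditioned on GC
— never the positions or alleles of the source data.

## Assumptions

- Variant counts in a fragment depend on chromosome and GC content
  only; no linkage, hotspots, selection, or covariates beyond GC.
- Fragments are statistically independent and mutated independently;
  variants never span a fragment boundary (a documented limitation:
  events longer than the distance to the fragment end are placed
  entirely within the fragment or skipped).
- Within a size range, sizes are uniform; inserted and altered
  sequence content is uniform over A/C/G/T.
- Inversion means reverse complement; tandem duplication means exactly
  one extra adjacent copy.

## Coordinates and the mutation log

All file formats are 1-based inclusive; in-memory intervals are
0-based half-open. Every applied edit is logged as a replacement:
`ref_seq` at `parent_start` becomes `alt_seq` (empty `ref_seq` =
insertion immediately before `parent_start`; empty `alt_seq` =
deletion). Log coordinates are **parent** coordinates, which makes the
log a self-contained recipe independent of how edits shift positions.

Site selection reserves all intervals in parent-fragment coordinates
against one shared, pairwise-disjoint set; classes are then applied in
the fixed order deletion → insertion → sequence alteration → inversion
→ SNV → tandem duplication, with each parent interval translated
through the length deltas of previously applied edits. Because the
intervals are disjoint, the final fragment equals the splice of all
replacements into the parent fragment, and replay is implemented as
exactly that sort-and-splice — an algorithm independent of the
engine's incremental path, verified byte-for-byte in the tests. We
place all sites against the parent fragment rather than re-drawing on
the partially mutated sequence: this keeps parent intervals disjoint
(so the log stays replayable and auditable) at the cost of never
placing a mutation inside previously inserted material.

Engineered structural variants are spliced into the *assembled*
(already mutated) genome in descending coordinate order per
chromosome, so earlier splices cannot shift later ones; their log
entries are flagged `origin=engineered` and replayed in log order at
their recorded coordinates after the background phase. A
translocation is logged as two replacement entries, one per swapped
interval.

## Randomness and determinism

Each fragment's stream is `PCG64(SeedSequence(entropy=base_seed,
spawn_key=(genome_index, crc32(chromosome), fragment_index)))`. The
derivation depends only on those four values, so any worker count, any
scheduling order, and any subset re-run produce identical output;
parallelism is a plain process pool over fragments with results
gathered by fragment index.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `fragment_length` | 1,000 | bp | small enough for GC to be locally meaningful, large enough to hold multi-variant budgets |
| GC `bin_edges` | deciles of [0,1] | fraction | finer bins did not improve the GC–SNV association in the source analyses; custom edges (e.g. a 25–35% bin) supported |
| ambiguity threshold | 0.9 | fraction of non-ACGT bases | fragments above it (centromere/telomere runs) get undefined GC and are excluded from estimation |
| placement attempts | 100 | draws per mutation | bounds work on crowded small fragments; failures are recorded per class in `MutationOutcome.skipped`, never fatal |
| VCF export `max_indel_size` | 100 | bp | keeps the export within plain REF/ALT dialect; larger events and symbolic classes stay in the TSV log |

## Synthetic fixtures

The fixture generator emulates the statistical shape of population
variant catalogues, not their content: per-base reference draws with a
per-chromosome GC target; per-fragment, per-class Poisson variant
counts (default 8 SNV, 1.5 sequence alteration, 1.0 insertion, 1.0
deletion, 0.1 inversion, 0.1 tandem duplication per kb — SNVs
dominating, then alterations and indels, large classes rare); sizes
96% in 1–10 bp and 4% in 11–100 bp; a transition-biased SNV spectrum
whose C row is the published genome-wide rate set (C→T 0.69, C→A 0.16,
C→G 0.15); and a validation-tag mix spanning normal and
disease-catalogue labels. Poisson placement is the minimal assumption
the estimators must recover; real data additionally shows clumping,
LD, and hotspots, so passing closure tests demonstrates estimator
correctness, not realism of any particular human callset. Positions
are uniform, so a small fraction of duplicate loci is collapsed by the
uniqueness filter (≈0.3% at default rates), slightly deflating
recovered rates — well inside the 3σ test tolerances.

## Numerical choices and degenerate inputs

- Probabilities are validated to sum to 1 within 1e-9; frequency-table
  TSVs are written at full float precision and read back with
  round-trip parsing, so serialization is an identity.
- GC of a sequence with no unambiguous base is undefined (`None`):
  such fragments are excluded from estimation and pass through
  generation unmutated.
- An empty GC bin falls back to the nearest non-empty bin by
  bin-center distance, ties to the lower bin; a chromosome with no
  profiles at all is an error.
- Sequence alteration redraws until it differs from the original in at
  least one position; SNV sampling never returns the identity base by
  construction.
- Duplicate FASTA record names, missing/duplicate fragment indices at
  assembly, overlapping engineered SVs, and table/config
  fragment-length mismatches are hard errors raised before output is
  written.

## Problem sizes used in the test suite

The statistical suites run on synthetic fixtures of 50 kb–1 Mb with
10³–10⁴ simulated fragments and 10⁴–10⁵ elementary draws, sizes at
which every 3σ check has comfortable resolving power for the
parameters above while the whole suite stays fast. Distribution
recovery is assessed over ≥10⁴ fragments; closure of the estimators is
assessed on a 1 Mb fixture.

## Known limitations

- No variant may span a fragment boundary, and no mutation lands in
  material inserted earlier in the same fragment.
- Structural realism is limited: no copy-number stacks (duplication is
  exactly ×2), no inversion breakpoint microhomology, no complex
  rearrangements except as user-specified engineered SVs.
- GVF/VCF support is a documented minimal dialect (coordinates, class
  term, one tag attribute); complex VCF shapes (MNPs, breakend pairs,
  nested symbolic alleles) are dropped with a logged count.
- VCF export covers SNVs and small indels only; inversions,
  duplications and alterations remain TSV-only.
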