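# varigen

**varigen** generates artificial whole-genome FASTA sequences whose
variation statistics match an observed population, for benchmarking
aligners, variant callers and other sequencing pipelines against a
ground truth that is known by construction. Instead of injecting
mutations at arbitrary rates, varigen first *mines* observed variant
files (GVF or VCF) against a reference to build a set of
variation-frequency tables, then samples those tables
fragment-by-fragment to mutate a parent genome. Every edit is recorded
in a mutation log that regenerates the simulated genome byte-for-byte.

## The model

The genome is processed in fixed-length fragments (default L = 1 kb),
the unit of both frequency estimation and mutation.

**Frequency analysis** (observed data → tables):

1. Parse GVF/VCF files; keep variants that are unique per chromosome
   location and carry a requested validation tag (e.g. `1000Genomes`,
   `HapMap` for a "normal" background; `COSMIC`, `DGVa` for a highly
   variant one). Supported classes: SNV, deletion, insertion,
   sequence alteration, inversion, tandem duplication.
2. Segment each reference chromosome into fragments; count the observed
   variants of each class per fragment and compute the fragment's GC
   fraction from the reference sequence.
3. Group fragment profiles into GC bins per chromosome (default 10
   equal-width bins; custom edges supported). GC content is the one
   structural covariate the tables condition on.
4. Estimate two genome-wide distributions: size probabilities
   P(size-range | class) for every class other than SNV, and an SNV
   transition matrix P(alt base | ref base) with empty rows falling
   back to uniform.

**Generation** (tables → genomes), per fragment:

1. Compute the fragment's GC fraction and fit it to the chromosome's
   bins (nearest non-empty bin on an empty hit; all-ambiguous fragments
   pass through unmutated).
2. Sample one observed fragment profile uniformly from the bin — its
   per-class counts are the fragment's mutation budget. The simulated
   fragment reproduces the *number* of mutations of an observed
   fragment, never its specific mutations.
3. Draw non-overlapping sites uniformly at random (rejection with a
   100-attempt cap; unplaceable mutations are counted, not fatal) and
   apply the budget class by class — deletions first, tandem
   duplications last. Sizes come from the size table, substitute bases
   from the transition matrix, inserted/altered sequence content is
   uniform over A/C/G/T, inversion is reverse complement, tandem
   duplication appends one extra copy.

Fragments are mutated independently under per-fragment random streams
derived from (base seed, genome index, chromosome, fragment index), so
output is byte-identical for any worker count, and reassembled in index
order. Engineered structural variants (deletion, insertion, inversion,
duplication, translocation — e.g. a tumour-like breakpoint) can be
spliced into the assembled genome afterwards.

## Worked example

Everything below runs from the shell; no external data is needed — the
`fixtures` subcommand writes a synthetic reference and variant file
with known statistics.

```
$ varigen fixtures --out-fasta ref.fa --out-variants vars.gvf \
    --chrom-lengths chr1:200000,chr2:100000 --seed 5
wrote ref.fa and vars.gvf

$ varigen analyze --reference ref.fa --variants vars.gvf --dialect GVF \
    --include-tags 1000Genomes,HapMap --out freq
parsed 2713 unique variants
frequency table written to freq

$ varigen generate --reference ref.fa --freq-dir freq --n-genomes 2 \
    --seed 11 --out genomes
INFO:varigen.orchestrate:genome sim000: per-class totals {'SNV': 1804,
  'insertion': 263, 'sequence_alteration': 348, 'deletion': 194,
  'tandem_duplication': 23, 'inversion': 15}
INFO:varigen.orchestrate:genome sim001: per-class totals {'deletion': 206,
  'insertion': 272, 'sequence_alteration': 375, 'SNV': 1890,
  'inversion': 23, 'tandem_duplication': 19}
sim000: 2 chromosomes written
sim001: 2 chromosomes written
```

`freq/` holds four TSV tables (`profiles.tsv`, `size_dist.tsv`,
`snv_matrix.tsv`, `meta.tsv`). On this fixture the estimated deletion
size table is `(1-10 bp: 0.955, 11-100 bp: 0.045)` and the mean
per-fragment budget is about 6.2 SNVs, 0.67 deletions, 0.85 insertions,
1.17 sequence alterations per kb — the per-genome totals above scatter
around those means times 300 fragments, while the per-fragment
placements differ between genomes. Estimates at this scale carry
visible sampling error (a few hundred observations per matrix row);
they converge to the configured parameters as the fixture grows.

Each genome directory contains one FASTA per chromosome, a
`mutations.tsv` log and a `manifest.json`. The log is a complete
recipe:

```
$ varigen replay --reference ref.fa --log genomes/sim000/mutations.tsv \
    --out replayed
replayed 2 chromosomes to replayed
$ diff <(tail -n +2 genomes/sim000/chr1.fa) <(tail -n +2 replayed/chr1.fa) \
    && echo identical
identical
```

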