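# Methods

## The null model for box occurrence

Sequence is modelled as a first-order Markov chain over {A,C,G,T}: the first
base is an independent draw from the mononucleotide probabilities and every
later base depends only on its immediate predecessor through the 4×4
conditional transition matrix p(b₂|b₁). The chance of an exact hexamer per
start position is the chain product p(b₁)·∏p(bᵢ₊₁|bᵢ); a degenerate motif's
per-position probability sums this over its exact variants. The dinucleotide
terms are *conditional* probabilities — the joint-frequency reading of the
same symbols would neither define a chain nor normalize (the sum over all
4096 hexamers must be 1, which the test suite checks exhaustively).

Strand policy is shared between scanning and expectation so the two stay
commensurable. Under both-strand counting a non-palindromic motif
accumulates forward matches plus matches of its reverse-complement variants;
a palindromic motif (A-box TACGTA, T-box AACGTT) matches both strands at the
same positions, so it is counted once per position — scanning reports one
forward hit, and the probability adds no reverse term. Every start position
is tested, so overlapping occurrences are all counted; the expectation
counts every start position too, making the two conventions consistent.

A window of L bp has L − k + 1 hexamer start positions (1995 for the default
2000-bp windows), and the expected count is p_motif × (L − k + 1). By
linearity of expectation this mean is exact despite the dependence between
overlapping windows; the *variance* of counts is approximated as binomial,
which is only used to set simulation tolerances (3 standard errors of the
mean), not for inference. Exact overlapping-word count distributions and
compound-Poisson corrections are out of scope.

## Composition estimation

Mononucleotide probabilities come from base counts, transitions from
adjacent-pair counts. Pairs never span sequence or fragment boundaries, and
any base or pair involving N is excluded. Two background flavours are
supported: whole-genome (all fragments) and GC-stratified (only fragments
whose GC lies within a tolerance — default ±2%, boundaries closed on both
ends — of a focal value such as the study promoter's GC). Fragments with
more than 10% N are dropped from background estimation to avoid
assembly-gap bias. A base never observed keeps probability zero and the
model flags it as degenerate rather than failing.

## Promoters, fragments, coordinates

A promoter is the fixed-length region (default 2000 bp) immediately 5′ of
the annotated CDS start codon — not the transcription start site — so it
includes the 5′UTR. GFF3 input is 1-based inclusive; internally every
interval is 0-based half-open; human-readable positions are ATG-relative,
with −1 the base immediately 5′ of the A of ATG. On the + strand the
interval is [cds_start−1−L, cds_start−1); on the − strand it is
[cds_start, cds_start+L) reverse-complemented. When a gene has several
transcripts the first-listed one is used. Intervals are clipped at contig
boundaries and flagged truncated; truncated promoters are excluded from
per-promoter count distributions by default (their counts are not
comparable at fixed window length) but kept, flagged, in family track
tables.

Genome fragmentation cuts each contig into non-overlapping windows starting
at offset 0, discarding the trailing remainder, so all fragments share one
width and their counts are comparable. Windows containing N never match any
motif.

## Tunable parameters

| parameter | default | why |
|---|---|---|
| promoter length | 2000 bp | the study convention for upstream regions |
| fragment window | 2000 bp | matches promoter length so expectations transfer |
| GC tolerance | ±0.02 | the stated stratification band |
| strand policy | both | non-palindromic boxes occur in either orientation |
| max N fraction per fragment | 0.10 | drops assembly-gap windows from estimation |
| shared-motif threshold (family tables) | 0.50 | flags boxes present in ≥half the family |

## Synthetic data

The generator produces what the analysis assumes and nothing more: iid
genomes at a target GC (36% for a genome-like background, 28.4% for an
AT-rich promoter-like one), first-order Markov genomes from an explicit
transition matrix, exact motif words planted at known positions/strands
(overwriting background bases so coordinates stay put), and FASTA+GFF3
fixture pairs with genes placed to leave full-length promoters. One integer
seed feeds per-contig `numpy` SeedSequence substreams, so fixtures are
byte-stable and adding a contig never perturbs earlier ones.

What the generator does *not* emulate: isochore/GC-landscape structure,
repeats, assembly gaps, higher-order composition, or selection on motifs.
Passing tests therefore demonstrate internal consistency of scanner,
estimator and expectation — not that any real genome is first-order Markov;
on real data observed/expected folds deviating from 1 are the biological
signal, not an error.

## Numerical and design choices

- Enrichment fold is observed/expected and is undefined (an error) at
  expected = 0; observed = 0 gives fold 0.
- GC content excludes N from numerator and denominator; an all-N sequence is
  an error rather than a silent 0.
- The GC filter is closed on both boundaries, so a ±2% band around 28.4%
  retains exactly 26.4%..30.4%.
- Modal exon-class fold in structure summaries is modal-class size over
  runner-up size; ties in class size break toward the smaller exon count.
- Medians of even-sized cohorts are the mean of the two central values; skew
  is operationalized as sign(mean − median) per length measure, a coarse
  direction indicator rather than a moment estimate.
- Likely-partial genes (single exon, ≤600 bp) are included in summaries by
  default and dropped only under `exclude_partial`.
- The calibration suite uses 1000 fragments × 2000 bp and a 1-Mb sequence
  for parameter recovery; at these sizes the 3-standard-error band and the
  ±0.01 transition tolerance give comfortable, non-flaky margins under the
  fixed seeds.

## Known limitations

Exact-word matching only: no position-weight matrices, mismatch tolerance or
motif discovery — relaxed binding sites will be missed, which matters for
cross-species comparisons at large evolutionary distances. First-transcript
selection ignores isoform diversity. The binomial variance approximation
understates dispersion for self-overlapping motifs. Ortholog retrieval,
alignment and tree building are upstream of this package: family definitions
are user-provided.
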