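# Methods

This note records the models, conventions and design choices behind
`termflex`, and what the synthetic-data tests do and do not establish
about real sequencing data.

## Data model and coordinates

Sequences are handled on the uppercase DNA alphabet; `U` is
transliterated to `T` at ingest so RNA-written oligonucleotide designs
and DNA genomes coexist. External coordinates are 1-based inclusive on
both strands. A fragment's 5′-end position is the leftmost genomic base
of its match on the plus strand and the **rightmost** genomic base on
the minus strand — the biological 5′ terminus in both cases. Internally
arrays are 0-based; conversion happens only at the I/O boundary
(bedGraph output uses the format's 0-based half-open convention).

## Preprocessing

Defaults: Phred floor Q20 with ≥ 90% of bases passing; adapter-remnant
motif `ATCACCGACTGCCCA` (the 5′-terminal sequence of the 3′ adapter),
cut before its **first** occurrence — adapter ligation is 3′-terminal,
and the earliest match protects against adapter dimers; insert window
16–50 nt. The motif match is exact: no mismatch tolerance is offered,
since quality-filtered data keeps the miss rate low. 5′-adapter removal
is not implemented. The pipeline order is fixed (quality → adapter →
length); the post-length-selection count defines N_qc, the
normalisation denominator (reads per million QC reads), so unmapped and
modified reads still contribute to the denominator. Reads arriving
without quality strings (FASTA) pass the quality stage unchecked with a
logged warning.

## Exact mapping

Matching is exact on both strands (built on the C substring search of
the runtime, verified against a naive sliding comparison in the test
suite). Overlapping self-occurrences count as distinct loci. A read
matching n loci contributes 1/n of a read to each 5′-end position, so
total raw profile weight equals the number of mapped reads — an
invariant asserted in tests. Reads containing `N` are unmapped by
definition. Profile similarity uses the Pearson product-moment
coefficient over the concatenated per-position values of both strands;
zero-variance profiles yield NaN rather than an arbitrary value.

## Differential secretion screen

Normalised profiles are summed in 5 bp windows at 1 bp steps, averaged
across replicates, and tested per window:

1. **Depth floor.** max(wt_exo, mut_exo) ≥ 25 normalised reads. The
   floor is taken on the larger secretome mean so that loci silenced in
   one condition are not discarded before the ratio is even formed.
2. **Secretion loss.** wt_exo / mut_exo ≥ 1.5. Zero denominators
   produce +inf, which passes any ≥ test.
3. **Intracellular maintenance.** mut_in / wt_in ≥ 1.0 × (1 − t) with
   tolerance t = 0.1 by default. A strict parity floor is not usable on
   counted data: at true parity the measured ratio falls below 1 in
   about half of replicates, so "comparable levels" is asserted with
   10% slack, which covers replicate counting noise at the depths the
   floor admits while still rejecting genuine intracellular loss.

Overlapping qualifying windows on one strand merge into a locus
(idempotent and order-independent); borders are the union extent; the
reported abundances are taken at the qualifying window with the
strongest wild-type secretome signal, and the peak is the position of
maximum per-position wild-type secretome coverage inside the locus,
leftmost on ties. No multiple-testing correction is applied at this
stage — the screen is a candidate generator, not a test.

## Deviation classification

Reads are collected by an exact anchor prefix (12–14 nt, the genomic
sequence at the locus 5′ end), which admits reads that no longer map to
the genome in full. The post-anchor portion is compared with the
templated continuation under two interpretations:

- a **gap-free positional comparison**, the common case; and
- a **banded edit-distance alignment** (band 3, unit costs,
  deterministic diagonal-first traceback, largest genomic end on ties)
  that can explain a shifted 3′ segment as an indel.

Each interpretation is segmented by a **changepoint** into a templated
prefix (matches score +1, everything else −1) and a non-templated
suffix (mismatches and insertions +1, matches −1, deletions 0); the
interpretation with the higher changepoint score wins, the gap-free one
on ties, and the suffix is the called 3′ extension. This segmentation
is deliberate: a genuinely random tail matches the genomic continuation
at ~1/4 of its positions by chance, so any rule that truncates the
extension at the last coincidentally matching base mutilates exactly
the reads the analysis exists to find, while a cheap genomic
explanation (a single indel followed by templated sequence) correctly
beats calling a long extension.

Extensions are categorised by the field rules: 1–3 nt of any sequence,
or ≥ 4 nt with ≤ 2 distinct nucleotides → non-template addition;
≥ 4 nt with ≥ 3 distinct nucleotides → chimera. Substitutions in the
templated prefix count as mismatches only outside the read's terminal
triplets (first/last 3 bases; terminal deviations belong to the
anchor/extension logic); alignment gaps count as indels. A read is
tallied once — extension categories take precedence, then indel, then
mismatch — while all individual deviations are recorded. Only 3′
extensions are scored: anchor collection fixes the 5′ end by
construction.

Replicate summaries follow read-count gates: per-replicate percentages
averaged when both replicates hold ≥ 100 reads; pooled percentages when
the total reaches 80; otherwise the sample is reported as ignored.

## RandExt

For parameters (k, L), only reads of exactly k + L nt enter a run
(adapter trimming is re-applied defensively); a convenience cropping
mode is deliberately absent from the default path. A read qualifies
when (a) it has no full-length exact genomic match on either strand,
(b) its 5′ k-mer occurs in the genome, and (c) its L-flank diverges
from the templated continuation at one or more k-mer occurrences:
positional matches ≤ L − 4, i.e. complete divergence at L = 4.
Continuations truncated by a genome end count missing bases as
mismatches (divergence-favouring). Qualifying reads are attributed at
full weight to **every** occurrence passing (c) — multi-locus anchors
(e.g. shared tRNA 5′ termini) genuinely cross-contribute — and groups
sharing ≥ 50% of their reads with another position are annotated as
potentially cross-contributed rather than silently deduplicated.

Shannon diversity H = −Σ p_i ln p_i (nats) is computed over the
copy-number frequencies of unique read sequences per
(position, strand, k, L) group, from raw counts — frequencies are
scale-invariant, so library normalisation cannot change H. Because H
depends non-linearly on the read profile, values from different runs
are never averaged; the grid scan (defaults k = 13–22, L = 4–10, both
fully configurable) records the per-position maximum and the
lexicographically smallest (k, L) achieving it. Positions with
H > 2.0 (default) are flagged. Note that e^2 ≈ 7.4 effective
equally-frequent variants is the intuitive meaning of the threshold.

## Community response statistics

Zero cells receive one pseudocount before per-sample percentages are
formed. Inclusion requires ≥ 0.01% relative abundance in the
direction-relevant sample (treated for increases, control for
suppressions) in ≥ 4 of 5 subject pairs. Fold-change ratios are
computed on percentages; the Z-score uses the sample standard deviation
(n − 1, the spreadsheet convention) against the null FCR = 1, with a
one-sided standard-normal tail probability evaluated both directly and
in log space so extreme Z-scores stay informative. Variability of
pooled FCRs is summarised by the mean absolute deviation around the
mean (not the median — consistent with the name). Direction labels are
carried explicitly rather than encoded in p-value signs.

## Synthetic data

The generator emulates the structure the pipeline assumes: uniform
random genomes (optionally with embedded literal motifs such as the
shared 19-mer of the four identical leucine tRNAs), fragments cleaved
at defined positions on both strands, and per-locus extension models —
none, templated continuation, A-rich homopolymer tails (geometric
length, 80% A / 20% C), uniform random N-mers (optionally resampled
until they pass the divergence rule), and a fixed chimeric nanomere
(`GCCAAGGCG`). Substitution/indel noise is uniform per base;
a configurable fraction of reads carries an adapter remnant plus a
short random tail; FASTQ qualities are constant Q30. Condition factors
scale per-locus depth deterministically (depth × factor reads), so a
planted 3-fold secretion difference is exact by construction, and each
library derives its random stream from (seed, condition, replicate) via
a stable checksum — output is byte-identical across processes for a
fixed seed.

What the simulator does **not** model: Ion Torrent flow-space error
structure, realistic library-size and length distributions,
ligation-bias in adapter remnants, and expression heterogeneity beyond
planted factors. Passing recovery tests therefore demonstrates
correctness of the decision rules and arithmetic under controlled
conditions, not performance on real libraries, where error modes are
correlated and depth is uneven.

## Problem sizes and numerics

The test suite and the acceptance script run on 40 kb genomes with
~100 planted loci at depth 120 (screen recovery), 10 kb genomes with
200-read loci (RandExt recovery), and exhaustive enumerations where
the space is small (4^1–4^6 extensions; 256 × 256 flank pairs) —
sizes chosen so planted effects sit well clear of sampling noise while
each stage's behaviour remains exactly checkable. Shannon indices are
asserted to 1e-12 against brute force; profile TSVs round-trip floats
exactly via `repr`/round-trip parsing; ratio guards return ±inf or NaN
markers instead of raising inside vectorised paths; all tie-breaks
(peak position, grid cell, alignment traceback, changepoint split) are
deterministic and documented above.

## Known limitations

- The exact mapper is a per-read substring scan: simple, exact, and
  fast at toolkit scale, but not built for mammalian-genome workloads.
- The screen's window statistics are descriptive; no FDR control.
- Chimera partners are not identified, only categorised.
- 5′-end heterogeneity is outside scope by design: the anchor and the
  peak-pinpointing step intentionally ignore fragments with shifted 5′
  termini.
- The intracellular-parity tolerance (10%) is a pragmatic default for
  replicate counting noise; very shallow libraries may need a larger
  value, deep ones a smaller one.
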