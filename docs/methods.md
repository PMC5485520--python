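# Methods

`emmir` re-implements, at desk scale, the classic plant small-RNA analysis
chain: adapter trimming and tag collapsing, exact-match genome mapping with
ncRNA triage, conserved miRNA assignment, novel miRNA prediction by
inverted-repeat detection plus hairpin evaluation, TPM-based differential
expression with an exact count test, complementarity-rule target scanning,
composition summaries, and 2^−ΔΔCT qRT-PCR quantification. Every stage is
driven by explicit, documented rules so that each can be verified against an
independent oracle or a planted synthetic truth.

## The synthetic study

The generator replaces sequencing libraries with a fully specified model:

- **Genome.** An i.i.d. background sequence (default 100 kb, GC 0.45 —
  wheat-like). Planted pre-miRNA precursors are perfect inverted repeats
  `arm5 + loop + revcomp(arm5)` with stem 18–25 bp, loop 4–15 nt, and a
  20–22 nt mature lying entirely on one randomly chosen arm. Stem/loop
  draws are rejection-sampled so each precursor is at least 62 nt, the
  minimum compatible with the default hairpin-length criterion, and the
  stem is never shorter than the mature. Precursors are placed ≥ 700 bp
  apart (clusters never merge under the 200 bp locus rule) and on either
  strand with probability 1/2.
- **Counts.** Library design is 2 conditions (salt/control) × 2 replicates
  at 100,000 reads per library. Per-miRNA expected counts are proportional
  to a log-normal base abundance times the fold change in salt libraries,
  renormalized to the miRNA share of the fixed library depth — sequencing
  is therefore compositional, as real libraries are. Counts are negative
  binomial with a single shared dispersion φ (variance μ + φμ²; default
  φ = 0.1, a biological CV of ~0.32, typical of plant sRNA replicates);
  φ = 0 degenerates to Poisson, enabling exact round-trip tests.
- **Reads.** Each miRNA read is its mature sequence plus the Illumina
  small-RNA 3′ adapter; a configurable fraction (default 0.2) of each
  library consists of random 18–28 nt fragments of synthetic rRNA / tRNA /
  snoRNA / other references (rRNA-dominated, as in real libraries).
  Qualities are uniform: the published filter chain's quality threshold is
  not recoverable, so quality filtering is modeled as a pass-through and
  "low quality" means reads containing N or non-ACGT characters.

What the simulation does *not* emulate: sequencing errors, PCR duplication,
isomiR heterogeneity, tissue structure, genome repeats and paralogy, or a
realistic transcriptome. Passing recovery tests therefore demonstrate that
the pipeline's logic is correct under its stated model, not that it would
reach the same sensitivity on real wheat libraries.

## Preprocessing

The 3′ adapter is removed at its leftmost full occurrence, else as the
longest exact adapter prefix (≥ 6 nt) ending the read; adapter-only reads
are rejected. Surviving reads of 18–30 nt without N collapse into unique
tags carrying per-library counts; tag serials are assigned by descending
total count (ties by sequence) so all outputs are reproducible. Read
conservation (`in = kept + rejected`) is asserted per library at run time.

## Mapping and triage

Mapping is exact-match on both strands through a k-mer index (k = 12,
seed-and-verify over every k-gram, complete by pigeonhole), reporting all
hits up to a cap of 100 with an explicit truncation flag. Tags are
classified with the priority rRNA > tRNA > snoRNA > other ncRNA >
high-repeat (> 20 genomic hits) > low-expression (total count 1) >
candidate; ncRNA assignment is exact substring membership in a reference
sequence on either strand, and annotated tags leave the candidate pool
before repeat status is judged.

## Novel miRNA prediction

Candidate hits within 200 bp on one chromosome and strand chain into loci;
each locus is extracted with ±200 nt flanks (minus-strand loci reverse
complemented).

**Inverted repeats.** The window is locally aligned against its own
downstream reverse complement by dynamic programming with match +3,
mismatch −3, and a linear gap cost of 6 per gapped position, reporting
alignments scoring ≥ 40 with span ≤ 240 nt and arms separated by ≥ 3 nt.
Two tables are filled: `D[i,j]`, the best stem whose outermost column
pairs positions i and j, and `G[i,j]`, its inner relaxation; since
terminal gap columns can only lower a score, restricting outer columns to
substitutions is lossless. Overlapping candidates are pruned greedily by
(score, leftmost start, shortest span), so each stem is reported once.
G·U is a mismatch here (DNA-alphabet alignment); a 14 bp perfect stem
scores 42 (reported) and a 13 bp stem 39 (below threshold) by arithmetic.
The suite checks the DP against an independent Smith–Waterman split-point
oracle (Biopython `PairwiseAligner` over every prefix/suffix split).

**Folding.** Each repeat, padded by 10 nt per side, is folded by maximum
weighted nested base pairing (GC = 3, AU = 2, GU = 1, minimum loop 3,
deterministic traceback). This is a Nussinov-style combinatorial folder,
not a thermodynamic model: the reported `mfe_proxy` is the negated pair
weight and is only an ordering proxy. It is exhaustively verifiable and
sufficient for the stem-presence and pairing-count criteria the hairpin
evaluation uses; it would not be adequate for free-energy-based filtering.

**Hairpin evaluation.** A candidate mature placement passes when all of:
mature 18–25 nt; no mature base paired to another mature base (the mature
does not straddle the terminal loop); ≤ 4 unpaired mature positions; no
run of > 2 consecutive unpaired mature positions; at most one asymmetric
bulge > 2 nt in the mature/star duplex; hairpin ≥ 60 nt. All thresholds
are configurable; failures report every violated criterion. The most
abundant tag inside the extended repeat that passes becomes the mature;
identical matures from different loci collapse into one record with
multiple precursors, and ids are assigned in genomic order.

Conserved assignment is independent of hairpin support: a tag joins a
reference mature (length within ±1 nt, overhang bases uncounted) when an
ungapped comparison shows ≤ 2 substitutions, tie-broken by reference order
and recorded. Reference U is normalized to T.

## Differential expression

TPM is `count / total × 10⁶`; with totals defined as per-library count
sums each TPM column sums to 10⁶ exactly. The pipeline uses per-library
mapped-read totals.

The two-group test is an exact conditional negative-binomial test:
replicate counts are scaled to the geometric-mean depth, rounded, and
pooled per condition; given the grand total T, the salt pool follows a
negative hypergeometric law with shape parameters (n_salt/φ, n_control/φ),
degenerating to Binomial(T, n_salt/(n_salt+n_control)) at φ = 0. The
two-sided p-value is the total probability of outcomes no more probable
than the one observed (hence exactly 1 for a perfectly balanced split).
The common dispersion is estimated by an equal-weight per-miRNA
method-of-moments average, `mean((v − m)/m²)` over miRNAs with scaled mean
above 0.5, floored at zero; equal weighting is deliberate — a pooled
`Σ(v−m)/Σm²` ratio is dominated by the few most abundant miRNAs, whose
two-replicate variance estimates are the noisiest in absolute terms, and
was observed to destabilize the null calibration. No tagwise shrinkage,
TMM normalization or multiple-testing gate is applied: marks threshold the
raw p-value at α = 0.05 (a Benjamini–Hochberg column is emitted for
reference), with UP/DOWN by the salt/control TPM ratio computed with a
0.5-count pseudocount on both sides.

Because normalization is by library size only, strong induction of a
sizeable miRNA fraction deflates all other TPMs (compositional bias);
unchanged miRNAs can then drift to significant ratios below 1. This is a
property of the method being reproduced, not a defect of the
implementation, and it is visible both in the demo analysis and in the
published table's modest-ratio DOWN calls.

## Target prediction

A site is the reverse complement of the mature with ≤ 3 substitutions, no
indels, and perfect matches opposite miRNA positions 10 and 11 (1-based
from the 5′ end; the transcript base opposite position p is
`site_start + L − p`). G·U does not count as a match. Only the transcript
sense strand is scanned (cDNA is oriented). All overlapping sites are
reported; summaries deduplicate per transcript.

## qRT-PCR

ΔCT pairs target and reference wells by replicate index within a sample;
fold = 2^−(ΔCT_treatment − ΔCT_control), so the control is 1 by
construction, folds are reciprocal under sample swap, and any global Ct
shift cancels. Replicate ΔCT sets are compared with an unpaired two-sided
Student's t-test (pooled variance; Welch by flag); the degenerate
zero-variance case returns p = 1 when means agree. Ct values outside
(0, 45) are rejected as implausible.

## Summary tables

Percent cells are `100·count/denominator` rounded half-up to two decimals
(half-up, not banker's: the printed cells require 0.1863… → 0.19-style
behavior on some rows). Denominators: high-quality over raw total, matched
and unique over high-quality, unique-matched over unique, and category
rows over the category totals. The printed redundancy row of the original
summary follows no recoverable denominator convention and is not emitted.
Nucleotide-bias matrices give one vote per distinct sequence and report T
as U.

## Problem sizes and determinism

The test and acceptance workloads use a 40 kb genome with 20 planted
hairpins at ~25× mature coverage for discovery recovery, 2000 miRNAs ×
(2+2) libraries at 100,000 reads for the count-test calibration, and
random sequences ≤ 60 nt (200 cases) for the alignment oracle — sizes at
which every brute-force oracle is itself computable. All randomness flows
from named integer seeds; identical seeds give byte-identical FASTQ and
table outputs. The specificity control uses a genome over the {A, C}
alphabet, which admits no Watson–Crick or G·U pair and is therefore
provably hairpin-free regardless of seed.

## Known limitations

- The folder ignores thermodynamics; hairpin calls rely on pairing counts.
- No miRNA* read-support requirement is imposed.
- Conserved records carry no precursor interval (as in homology-only
  assignment).
- The exact test uses one common dispersion; genuinely tagwise variability
  is absorbed, not modeled.
- Exact-substring ncRNA triage cannot emulate covariance-model searches.
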