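# Methods

This note documents the models, conventions and numerical choices behind
`tagdge`, in the order the pipeline runs.

## Tag model

A tag is the 21 nt sequence CATG + 17 nt released by NlaIII digestion
followed by MmeI cutting 17 bp downstream. The virtual reference library
indexes **every** CATG occurrence on the sense strand of every transcript
that retains a full 17 nt downstream (overlapping occurrences each count;
windows containing N are excluded because clean tags cannot contain N).
Indexing all sites rather than only the 3'-most tolerates partial
digestion; reads are nonetheless 3'-biased (see simulator). Coordinates
are 0-based and `site_offset` points at the C of CATG.

Antisense transcription is detected at match time: a clean tag whose
reverse complement equals a sense reference tag is an antisense hit. Only
sense-strand tags are indexed; because CATG is palindromic, an antisense
tag is the reverse complement of a sense tag and ends, rather than
starts, with CATG.

## Read cleaning

Reads are nominally 49 nt: the 21 nt tag followed by a fixed 3' adaptor.
The filter cascade runs in a fixed order per library: (1) the adaptor is
located by exact substring search and the read trimmed from its start —
a read that is adaptor from position 0 is an "empty" (adaptor-only) read;
(2) tags containing N are dropped; (3) tags whose trimmed length is not
21 nt are dropped; (4) after tallying, tags with copy number 1
(singletons) are dropped. One-mismatch adaptor finding was rejected in
favour of determinism; a read whose adaptor was hit by a sequencing error
therefore fails the length filter, which is the realistic outcome of the
same event. Copy-number classes for the abundance profile are
[2,5], (5,50], (50,100], (100,∞); the class boundaries in the protocol
this mirrors are stated ambiguously ("2 to 5", "5 and 50"), so the
half-open convention here is a documented choice, not canonical.

## Tag-to-gene assignment

Exact matches (sense, then antisense via reverse complement) are found
first; only when neither strand matches exactly is a single mismatch
considered, restricted to the 17 nt variable region — a mismatch in the
CATG anchor would contradict the enzymatic origin of the tag. Category
precedence per tag: host gene hits (one distinct gene ⇒ unambiguous,
several ⇒ ambiguous and excluded from counting); otherwise an exact
pathogen-gene hit; otherwise an exact genome 21-mer hit on either strand
(diagnostic only); otherwise unknown. Host precedence over pathogen
reflects that the RNA pool is overwhelmingly host-derived. Pathogen
matching is exact-only. A tag hitting the same gene exactly on both
strands is recorded as strand "both" and counted as sense.

Per-gene expression sums copies of unambiguous sense tags;
antisense copies are tallied separately and excluded from
TPM = count × 10⁶ / total clean tags. Whether antisense hits should
contribute to expression is genuinely open; excluding them is the
conservative choice and the antisense signal remains available in the
strand summary.

## Differential expression

The predictive distribution of a count `y` in library 2 given `x` in
library 1 under equal expression is
p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)), a negative
binomial with x+1 successes and success probability N1/(N1+N2). The
two-sided p doubles the smaller tail (both tails include the observed
count) and is capped at 1.

Numerics: the pmf is evaluated in log space with log-gamma (factorials
overflow near x+y ≈ 170) over a grid extended 20 predictive SDs plus the
geometric decay scale 40·(1+N2/N1) past the mean, so the truncated tail
remainder is below 1e-17; both tails are read off forward and reverse
cumulative sums. Agreement with direct summation of the density is at
the 1e-13 level over the tested grid.

Conventions worth knowing:

- The test conditions on the **control** count. The predictive
  conditioning is not exchange-symmetric at the discrete boundary
  (the exact identity is P_swapped(X≤x|y) = 1 − P(Y≤y|x), so the two
  doubled-tail values differ by boundary pmf terms); fixing the
  conditioning side makes results well-defined, analogous to choosing the
  conditioning margin in Fisher's exact test.
- Being an exact test on discrete counts, it is conservative:
  P(p ≤ α) ≤ α, with the deficit concentrated in low-count genes. On
  simulated null libraries (1,000 genes, 10⁶ tags) the pooled fraction of
  p ≤ 0.05 is ≈ 0.044.
- Multiplicity: BH step-up over exactly the genes detected (≥ 1
  unambiguous sense tag) in either library of the pair — undetectable
  genes would only dilute the adjustment. The procedure behind "FDR" is a
  stated choice; BH is the field default.
- DEG call: FDR ≤ 0.001 **and** |log2 TPM ratio| ≥ 1. The log2 ratio uses
  a pseudocount of one tag copy in the larger library
  (10⁶/max(N1,N2) TPM), so presence/absence genes get large finite
  ratios. Whether the original ratio used TPM or raw counts is only
  distinguishable when N1 ≠ N2; TPM is used here.

Cross-timepoint comparison intersects the per-timepoint DEG sets and
decomposes each intersection into consistent-up, consistent-down and
discordant direction patterns.

## Enrichment

Per term: hypergeometric upper tail P(X ≥ k) with k DE genes among m
background genes in the term, K DE genes and N background genes in
total. The background is the genes detected in the compared library
pair, not the whole transcriptome. Two multiplicity treatments are
emitted side by side because tag-DGE pathway reports use both: a
Bonferroni-corrected P (reported set, p ≤ 0.05) and a BH Q-value
(significant set, Q ≤ 0.05). GO terms are flat sets; no ancestor
propagation.

## QC

Saturation subsamples the clean-tag counts without replacement
(multivariate hypergeometric, seeded) at an ascending depth grid and
counts genes detected via ≥ 1 unambiguous tag, averaged over replicates.
Repeatability is the Pearson correlation of log2 TPM (same pseudocount
rule) over genes detected in either of two parallel libraries. qPCR
relative expression is 2^−ΔΔCt with replicates aggregated by mean Ct,
the control sample at the same timepoint as calibrator, and replicate
SDs of both ΔCts combined in quadrature and propagated to the
expression scale; concordance is the fraction of genes whose sequencing
log2 ratio and log2(2^−ΔΔCt) agree in sign.

## Synthetic data generator

The generator emulates a six-library infection time course
(infected/control at 8, 15, 24 hpi) so that every stage is testable by
parameter recovery. What it models, with defaults and rationale:

- **Transcriptomes**: 1,000 host and 200 pathogen genes, i.i.d. bases at
  50% GC, lengths uniform in 200–1500 nt; every gene is guaranteed ≥ 1
  CATG+17 site (one is written 21 nt from the 3' end if composition
  yields none). Gene ids are namespaced (`bm_`/`bb_`).
- **Abundances**: log-normal with σ = 2.0, normalized per organism, so a
  few transcripts carry most of the mass (top 5% ≥ 50%) — the
  hallmark of real tag libraries.
- **Differential expression**: exactly round(0.05 × n_host) genes per
  timepoint, drawn independently per timepoint, fold changes uniform in
  2–8, directions 2:1 up:down to mirror the skew of observed infection
  responses. Infected-library weights are renormalized after applying
  fold changes (a real compositional effect: strong induction slightly
  dilutes every other gene).
- **Read sampling**: exactly `depth_per_library` reads, multinomial over
  {adaptor-only 1%, noise 1%, pathogen f_t, host remainder}; per gene,
  the 3'-most site is used with probability 0.9, internal sites uniformly
  otherwise (oligo-dT capture implies 3' bias, but partial digestion
  populates internal sites).
- **Antisense**: 55% of host genes are flagged (matching the observed
  ~53–56% of genes with antisense transcripts); flagged genes emit the
  reverse complement of a sense tag for 70% of their reads, which brings
  the aggregate sense:antisense copy ratio near the observed ~1.6:1.
- **Pathogen admixture**: only in infected libraries, at 0.05%, 0.68%
  and 0.30% of gene-derived reads at 8, 15, 24 hpi — the span reported
  for early-infection libraries. The fraction is defined against
  gene-derived reads because the observable it emulates is a share of
  clean, mapped tags.
- **Artifacts**: per-base errors at 0.001 substitute a uniform choice
  among the other three bases and N (error positions are drawn with
  replacement; collisions are negligible at realistic rates); noise
  reads carry uniform-random 21-mers, which are almost surely singletons
  and exercise the copy-number filter; adaptor-only reads exercise the
  empty-read filter. Quality strings are constant (quality-aware
  filtering is out of scope).
- **Determinism**: a fixed seed gives bit-identical FASTQ (per numpy
  version); each library's stream is derived from (seed, timepoint,
  condition, replicate), so libraries are independently reproducible and
  parallel replicates of the same truth are available.
- **qPCR**: target Ct tracks −log2(expression) with the infected sample
  shifted by −log2(fold change); the reference gene is flat; Gaussian
  cycle noise (default SD 0.3) per replicate.
- **Annotations**: random gene→pathway/GO tables, with optional planting
  of a designated pathway over chosen genes for enrichment-recovery
  studies.

What the generator does **not** model — and hence what passing tests do
not establish about real data: realistic host/pathogen sequence
composition, isoforms and overlapping genes, PCR duplication,
quality-dependent error profiles, reference incompleteness (the large
"unknown tag" fraction of real libraries comes mostly from
unannotated transcripts, so the simulated unknown share is much
smaller), and biological replicate variance (each library is one
homogeneous RNA pool; the design has one library per condition per
timepoint, so the test is purely technical-sampling based, as in the
protocol it mirrors).

## Problem sizes used in validation

The test suite exercises the statistics at the generator's default
scale: null calibration on 20 seed-pairs of 10⁶-tag libraries;
recovery of 50 planted 8-fold changes among 1,000 genes at 2×10⁶
tags/library over 20 seeds (mean sensitivity ≥ 0.9, false-discovery
proportion ≤ 0.05); antisense gene fractions {0, 0.15, 0.3} recovered
within ±0.05; pathogen admixtures 0.05–0.68% recovered within binomial
error of the post-filter expectation; saturation ≥ 98% of full detection
at 75% depth; qPCR sign concordance ≥ 0.9 for genes with |log2 fc| ≥ 1.
Unit tests use smaller worlds (tens of genes, 10⁴–10⁵ reads) chosen to
keep each property sharply attributable.

## Known limitations

- The exact test's conservativeness means two-sided null calibration
  sits slightly below nominal at loose levels (see above); the joint DEG
  threshold is unaffected.
- Genome-level mapping is an exact 21-mer index intended for diagnostics
  on small genomes, not a spliced aligner.
- Multi-gene pathogen hits are classed ambiguous rather than assigned;
  with random references this is vanishingly rare.
- The singleton filter removes a few percent of the rarest organism's
  tags (≈ 6% of pathogen copies at the 0.05% admixture), so recovered
  admixture shares are slightly below the emitted fraction by design.
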