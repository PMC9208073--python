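# Methods

This package reimplements the downstream analysis of a paired
tumor/normal whole-exome (WES) study of metastatic clear cell renal
cell carcinoma (ccRCC): tumor purity estimation from heterozygous-SNP
allelic fractions, purity-corrected somatic variant filtering with a
COSMIC rescue rule, tumor mutational burden (TMB), copy-number calling
with circular binary segmentation (CBS) and cytoband recurrence,
clonality-based multi-sample phylogenies, and therapy-naive versus
pretreated cohort contrasts.  A synthetic cohort generator provides
ground-truthed inputs with the same statistical structure, so every
stage is testable without external data.

## Admixture model

All stages share one model of an impure specimen: a fraction `p`
(purity) of cells are tumor, the rest diploid normal.  At a locus with
tumor total copy number `CN` carrying a mutation on `m` copies
(multiplicity) in a fraction `c` of tumor cells (clonality / cancer
cell fraction):

- expected variant allele fraction
  `E[VAF] = c * p * m / (p*CN + 2*(1-p))`;
- expected tumor/normal coverage ratio `r = (p*CN + 2*(1-p)) / 2`;
- a germline-het SNP with `k` alt copies has expected tumor alt
  fraction `(p*k + (1-p)) / (p*CN + 2*(1-p))`.

The corrected VAF rescales an observed VAF to the pure-tumor scale,
`VAF_corr = min(1, VAF * (p*CN + 2*(1-p)) / (p*CN))` (a clonal het at
CN 2 maps to 0.5); clonality inverts the first formula with the cap
removed, flagging values above 1.2 as model violations.

## Purity estimation

Purity is estimated from the allelic imbalance of germline-het SNPs
over hemizygous (one-copy) losses: folding the tumor alt fraction to
`b = max(f, 1-f)` removes allele identity, and under a one-copy loss
`E[b] = 1/(2-p)`, so `p = 2 - 1/median(b)`, clamped to (0.05, 1].

The two-pass design: (1) segment the *uncorrected* log2 coverage-ratio
profile; (2) segments with mean log2 in [-1, -0.02] are loss
candidates — the upper bound excludes gains (which are also
allelically imbalanced but would invert incorrectly), the lower bound
excludes homozygous deletions (no tumor allele signal); (3) each
candidate's SNPs are screened against the null that `b` is folded
binomial noise at the observed depths (the folded-noise median is
`0.5 + 0.674 * 0.5/sqrt(depth)`), because a chromosome whose coverage
merely drifted low shows no imbalance; (4) the most significant
segment anchors the estimate and other passing segments pool into it
only when their median `b` agrees within three combined standard
errors.  A percentile bootstrap over SNPs (200 resamples, seeded)
gives the interval.

Samples with fewer than 10 informative SNPs on imbalanced candidates
fall back to purity 1.0 with a loud warning and are analyzed
uncorrected — every sample is analyzed, conservatively.  Known
limitations: a sample with a single small loss may not reach 10 SNPs
(334 SNPs spread over the exome put only ~8 on one arm); a sample with
*no* real loss can, rarely, anchor on a drifted segment and report a
spuriously low purity; and when segmentation fails to split an arm
event from its neutral partner arm at low purity, the pooled median
mixes the two clusters and biases the estimate toward lower purity.
On the default simulator settings the estimator recovers true purity
with mean absolute error ~0.02 over the 0.2–0.9 grid.

## Somatic variant filtering and TMB

Filter chain, in fixed precedence per variant: present in the matched
normal (>= 2 alt reads and >= 2% normal VAF) -> synonymous -> fewer
than 10 aligned tumor reads at the locus -> corrected VAF below 10%.
A variant failing only the last rule is rescued when reported in
COSMIC at least 10 times with corrected tumor VAF > 5% and normal VAF
< 1%.  Local CN for the correction comes from the overlying corrected
segment mean (`CN = max(1, round(2 * 2^seg_mean))`, diploid where
unsegmented); multiplicity is promoted from 1 to CN when the raw VAF
exceeds the multiplicity-1 ceiling by more than two binomial standard
deviations (LOH-locked mutations).  The 10-read rule is read as total
tumor depth (alt support is policed by the VAF rules), and TMB counts
kept non-synonymous *events* (an indel counts once) per megabase of
capture regions passing the coverage filter.

Capture regions are excluded when coverage is below 100 reads in
*both* tumor and normal (literal reading; an OR switch is provided in
the configuration, since the alternative discards regions well covered
in one sample).

## Copy-number calling

Per sample: normalize each library to its own total read count, form
per-region log2(tumor/normal) ratios, and segment each chromosome with
CBS: exhaustively find the arc (i, j] maximizing a t-like contrast
between arc and complement (pooled SD fixed at the chromosome SD,
which is permutation-invariant), accept the split when the permutation
p-value over seeded shuffles falls below alpha = 0.01 (1000
permutations, with early stopping once significance is impossible),
recurse, then merge adjacent segments whose means differ by < 0.1.
The merge step doubles as a guard against spurious micro-splits on
flat profiles.

Purity correction `r' = (r - (1-p))/p` is applied to *segment mean*
ratios, not region by region: per-region corrected ratios have their
noise amplified by `1/p`, and below ~50% purity a sizable share of
regions inside a true loss fall at or below zero, so flooring and
log-transforming them region-wise biases segment means far below the
truth (observed: a true one-copy loss at purity 0.38 reported at
log2 ~ -2.1 instead of ~ -0.8).  Correcting the stable segment means
keeps the published thresholds anchored to integer CN in a pure tumor:
amplified (> 1), gain (0.5, 1], neutral [-0.5, 0.5], loss [-1, -0.5),
deletion (< -1).  Note a clean hemizygous loss in a pure tumor sits
exactly at -1, the loss/deletion boundary; noise decides the label,
which is why recurrence counting pools loss with deletion (and gain
with amplification).

Segments are annotated with overlapped cytobands; CNA burden is the
fraction of retained capture-region bp in non-neutral segments (sex
chromosomes excluded by default — the single-copy male X breaks the
diploid baseline); samples with fraction altered > 0.5 are flagged for
manual ploidy review, without auto-correction.  Cohort recurrence
counts each patient once per cytoband if any of their samples carries
the event.  No GC correction is performed (a configuration hook
exists); the ratio normalization means a heavily altered genome shifts
the neutral baseline slightly upward, which the wide neutral band
absorbs.

## Phylogenies

For each patient with >= 2 samples, every variant that passed the
filters in at least one sample is scored for clonality in all samples;
presence = clonality >= 0.25 (default threshold, above the binomial
noise floor at depth ~100 and purity >= 0.4).  Variants lying in a
deeply deleted segment (mean < log2(0.25), i.e. under half a copy) in
some sample are treated as missing data and excluded — the five-class
"deletion" label is not used for masking because a hemizygous loss in
a pure tumor sits at the -1 boundary yet still yields reads.

Variants sharing a sample-presence pattern form one character; if the
pattern family is laminar (every pair nested or disjoint) the unique
perfect phylogeny rooted at the germline is assembled, with edge
length equal to the pattern's SNV count: the trunk carries mutations
shared by all samples, leaf edges the private ones.  Conflicting
patterns are resolved by greedily discarding the lowest-count pattern
(deterministic tie-breaks), with discards recorded — a qualitative
reconstruction, with no bootstrap support, matching how such trees are
read in practice.  Samples are leaves; internal nodes are unobserved
ancestors.  Reported metrics: truncal fraction (truncal edge length /
total SNVs used), maximum depth and branching-node count.

## Cohort statistics

Gene mutation frequencies are patient-level proportions (a patient
counts once per gene).  Contrasts between therapy-naive and pretreated
*samples* — per-gene corrected VAF (per-mutation pooling), TMB, indel
fraction and CNA burden — use the two-sided Mann-Whitney-Wilcoxon
test: exact null distribution when the smaller group has <= 8
observations without ties, otherwise the normal approximation with tie
and continuity corrections.  Benjamini-Hochberg FDR is applied across
the per-gene VAF family (the multiple-testing method is a package
choice; the per-gene family covers genes with >= 5 kept calls
cohort-wide).  Metrics with fewer than two observations in a group
report p = NA with a warning.  Patients contributing samples to both
groups appear in both, mirroring sample-level contrasts.

## Synthetic cohort generator

The generator emulates the cohort the analysis is designed for, and
its defaults are the study conditions: 44 patients, 13 of whom
contribute 2–4 multi-region samples (~68 samples), per-sample purity
uniform on 0.2–0.9, mean capture-region depth 100x, 334 het SNPs per
sample, 38/68 of samples pretreated.  Each patient has a random clonal
tree over samples rooted at the germline; truncal / branch / private
edges carry Poisson(40 / 15 / 8) SNVs.  Recurrently mutated genes are
planted at their observed patient-level frequencies (SETD2 0.62, PBRM1
0.57, APC 0.43, VHL 0.36, ...; truncal with probability 0.8), and
segmental events at the recurrent cytobands at their observed cohort
frequencies (3p25 loss 36/44, 9p21 loss 30/44, 14q25 loss 17/44, 6p21
deletion 18/44, 13q14 loss 23/44, 5q gain 21/44).  Hemizygous losses
and gains are arm-scale, as they typically are in ccRCC; homozygous
deletions stay focal to their band.  A VHL-pathway hit (VHL mutation
or 3p25 loss) is forced into the trunk with probability 0.9 when not
drawn naturally.

Reads: coverage is negative binomial (size 300, i.e. ~7% extra-Poisson
CV at depth 100 — realistic exome overdispersion after normalization);
variant alt reads are binomial at the admixture-model VAF; the normal
shows sequencing error at 0.2% (exercising the <1%-normal-VAF rescue
arm), 2% of variants leak as germline het (exercising the in-normal
filter), 25% of background SNVs are synonymous (exercising that
filter), and ~1 subclonal COSMIC-hotspot variant per patient at
clonality 0.15 exercises the rescue rule.  The genome is a simplified
scaffold: 22 autosomes of 100 Mb with 80 evenly spaced 5-kb capture
regions each, generic p/q cytobands with the driver bands carved out,
and known ccRCC genes placed at fixed loci (VHL inside 3p25, RB1
inside 13q14, CDKN1A inside 6p21, HIF1A inside 14q25...).

What the generator does **not** emulate — hence what passing tests do
not show about real data: mappability/GC coverage waves and batch
effects, subclonal copy number, mutation signatures and trinucleotide
context, FFPE artifacts, kit-specific capture-region geometry (real
exomes have ~200k irregular regions), sample swaps or contamination.
Recovery rates measured here are upper bounds for real cohorts.

## Numerical choices

- All randomness flows through seeded `numpy` generators; per-sample
  streams are spawned from a root `SeedSequence`, so outputs are
  byte-identical across reruns with one seed (verified end to end).
- CBS: min segment width 3; permutation p uses the (1+x)/(1+n)
  estimator; early stopping halts a test as soon as p < alpha is
  impossible; the post-hoc merge threshold is 0.1 log2 units.
- Corrected ratios are floored at 0.01 before log2 so values stay
  finite; deep-deletion masking uses log2(0.25).
- Degenerate inputs: chromosomes shorter than twice the minimum
  segment width form a single segment; zero-normal-read regions are
  dropped with a warning; a patient with one sample is skipped by the
  phylogeny stage with an explicit error; an empty cohort produces
  valid, header-only tables.
- Problem sizes in the recovery benchmarks (purity grid 8 x 20
  replicates, 200-region CBS profiles at 1000 permutations, 50
  simulated patients for tree recovery, 2000 null simulations for test
  calibration, one 44-patient cohort run twice for determinism) match
  the scale the analysis targets while keeping a full evaluation run
  in minutes on one core.
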