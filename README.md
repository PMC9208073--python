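# ccrcc-wes

Downstream analysis of paired tumor/normal whole-exome sequencing for
metastatic clear cell renal cell carcinoma (ccRCC) cohorts, for
bioinformaticians who have per-capture-region read counts, somatic
variant tables and heterozygous-SNP allelic fractions in hand and want
the full post-calling analysis: tumor purity, purity-corrected somatic
filtering, TMB, copy-number calls with recurrence by cytoband,
multi-region clonal phylogenies and pre-/post-therapy contrasts.  A
seeded synthetic cohort generator with full ground truth makes every
stage testable offline.

## The model

A specimen with tumor purity *p* mixes tumor cells (local total copy
number *CN*, mutation on *m* copies in a fraction *c* of tumor cells)
with diploid normal cells.  Everything downstream follows from the
admixture identities

    E[VAF]   = c·p·m / (p·CN + 2(1−p))          observed allele fraction
    VAF_corr = min(1, VAF·(p·CN + 2(1−p))/(p·CN))   pure-tumor scale
    E[r]     = (p·CN + 2(1−p)) / 2              tumor/normal coverage ratio

- **Purity** inverts the folded allelic fraction *b* = max(f, 1−f) of
  germline-het SNPs over hemizygous losses: E[b] = 1/(2−p), so
  p̂ = 2 − 1/median(b), with candidate loss segments from a first-pass
  CBS run and an allelic-imbalance screen against folded binomial noise.
- **Variant filtering**: drop if present in the matched normal, if
  synonymous, if < 10 aligned tumor reads, or if corrected VAF < 10% —
  unless rescued as a COSMIC-recurrent mutation (≥ 10 reports,
  corrected VAF > 5%, normal VAF < 1%).  TMB = kept non-synonymous
  mutations per Mb of well-covered capture territory.
- **Copy number**: per-region log2 tumor/normal ratios segmented by an
  in-repo circular binary segmentation (permutation-tested arc
  statistic); segment means rescaled to the pure-tumor scale and
  classified amplified / gain / neutral / loss / deletion at
  log2 = 1, 0.5, −0.5, −1.
- **Phylogenies**: per patient, SNV presence (clonality ≥ 0.25) across
  samples is grouped into patterns and the unique perfect phylogeny is
  assembled rooted at the germline, edge lengths = SNV counts;
  conflicting patterns are discarded greedily and reported.
- **Cohort statistics**: patient-level gene frequencies; Mann–Whitney–
  Wilcoxon contrasts of per-gene VAF, TMB, indel fraction and CNA
  burden between therapy-naive and pretreated samples, with
  Benjamini–Hochberg FDR across the per-gene family.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations.

## Worked example

Simulate a 3-patient cohort (one patient with three multi-region
samples) and run the whole pipeline:

    ccrcc-wes simulate --config sim.yaml --out demo/in --seed 17
    ccrcc-wes run-all --in demo/in --out demo/out

with `sim.yaml` containing

    n_patients: 3
    n_multi_sample_patients: 1
    multi_sample_range: [3, 3]
    purity_range: [0.5, 0.9]
    rng_seed: 17

`demo/out/purity.tsv` then reads

    sample_id  purity    n_informative_snps  ci_low    ci_high   method_flag
    P001-S1    0.612903  21                  0.568627  0.672452  informative
    P002-S1    1.000000  7                   1.000000  1.000000  fallback_neutral
    P003-S1    0.714286  15                  0.627908  0.784314  informative
    P003-S2    0.604652  13                  0.574469  0.666667  informative
    P003-S3    0.537861  24                  0.498577  0.600335  informative

The generating truth for these samples was 0.632, 0.719, 0.663, 0.629
and 0.573: four estimates land within ±0.07 of truth, while P002-S1
had only 7 informative SNPs over its candidate loss segments (below
the 10-SNP minimum) and fell back to purity 1.0 — it is analyzed
uncorrected, with the fallback flagged.  The multi-region patient's
tree (`demo/out/P003.tree.nwk`)

    (((P003-S1:5,P003-S3:15):10,P003-S2:7):33)germline;

recovers the simulated topology exactly — S1 and S3 share a branch of
10 SNVs (12 planted), the trunk carries 33 SNVs (41 planted, the gap
being mostly planted synonymous mutations that the filters remove by
design) — and `recurrence.tsv` shows both multi-patient losses planted
at 3p25/9p21 recovered in 2 patients each.  Per-sample TMB lands at
4.9–9.1 mutations/Mb over ~6.6 Mb of well-covered synthetic capture
territory.

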