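# finehap

Haplotype fine-mapping of a disease locus, built as a tested, reusable
pipeline and exercised end-to-end on synthetic cohorts.

The scientific setting is a locus where genome-wide association signals are
carried by long haplotypes: five tag SNPs define the common locus
haplotypes, one haplotype background confers elevated disease risk in one
population, and the question is *which variants private to that background
explain the extra risk*. Real cohorts of this design are access-controlled,
so the package ships a first-class synthetic-cohort generator that
reproduces the statistical structure — two populations with long-LD versus
short-LD haplotypes over a ~300-kb locus, a low-recombination core, a
high-risk target haplotype carrying injected specific variants at
within-carrier frequencies 0.75–0.97 and (near-)zero elsewhere, case/control
status under additive haplotype log-odds, one cis-regulated expression
trait, seven correlated quantitative traits and an ordinal severity outcome
— together with full ground truth for recovery tests.

## The methods

- **Haplotype EM** (`finehap.em`): multi-SNP haplotype frequencies from
  unphased genotypes by expectation–maximization over the latent phase;
  the E-step weights each compatible unordered haplotype pair
  (h<sub>a</sub>, h<sub>b</sub>) by (2 − δ<sub>ab</sub>) p<sub>a</sub> p<sub>b</sub>
  under Hardy–Weinberg, the M-step re-counts haplotypes.
- **Posterior-weighted haplotype GLM** (`finehap.em.haplotype_glm`): a
  logistic model additive in haplotype dosage, fitted on pair-expanded
  pseudo-observations whose weights fold in both the phase prior and the
  outcome likelihood; Wald standard errors come from the observed-data
  information of the phase-mixture likelihood (Louis' identity). Haplotypes
  below 5% frequency are pooled as "rare"; effects are reported as OR with
  95% CI against a stated reference haplotype.
- **Copying-model painting** (`finehap.paint`): each chromosome is modelled
  as an imperfect mosaic of donor chromosomes (Li–Stephens HMM) with switch
  probability 1 − e<sup>−ρ d<sub>j</sub></sup> per interval and mismatch
  emission θ; scaled forward–backward gives per-site donor posteriors,
  collapsed onto tag-haplotype labels; Viterbi gives hard paths.
- **Critical region and specific variants** (`finehap.region`): the maximal
  segment at which every target-haplotype homozygote chromosome is painted
  with the target label, bounded by ≥2 switch events per flank, extended 5%
  per side (23.9 kb → +1.2 kb/side → 26.3 kb is the worked example);
  per-group majority consensus sequences; a site is *specific* iff the
  target consensus allele differs from every other group's unambiguous
  consensus allele; per-background frequency tables and LD r².
- **Association stages** (`finehap.assoc`): cis-eQTL OLS within ±500 kb of
  each TSS with covariates and SVD latent factors, BH-FDR at ≤0.10;
  conditional models; a single-variance-component REML mixed model on the
  kinship eigenbasis; proportional-odds severity regression; stratified
  additive tests; and a Monte Carlo global-null test — the probability
  under z ~ MVN(0, R) of at least k of m two-sided tests with p < α.

## Worked example

Run the numbered analyses (each writes plain-text artifacts under
`results/`):

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_haplotype_association.py
python analysis/03_paint_critical_region.py
python analysis/04_specific_variants.py
python analysis/05_associations.py
```

With seed 1 the run prints, among other things:

```
target-haplotype homozygotes (AA): 28
[AA] n=1060; phase posterior median 1.000 (IQR 1.000-1.000, min 0.912)
   01101: freq 0.150 OR 1.68 [1.27, 2.22] p 0.00024
shared segment: 39809716-39852998 (43.3 kb), ...
63 sites in the 47.7-kb region; 9 specific to the target haplotype
truth comparison: recall 1.00, precision 1.00 against the 9 injected variants
eQTL scan: 243 tests, ... 10 significant at FDR<=0.10 (genes: ['G09', 'G14'];
cis-regulated gene: G14)
```

Reading: the EM/GLM stage estimates the target haplotype (tag string
`01101`, simulated log-OR log 1.67) at OR 1.68; painting the 56 homozygote
chromosomes delineates the shared core segment; consensus comparison inside
the extended region recovers exactly the nine injected specific variants
(frequencies ~0.8–0.94 on the target background, 0 on the European-like
backgrounds); and the eQTL scan finds the planted cis gene. The same chain
is available in one call as `finehap.pipeline.run_pipeline(RunConfig(...),
outdir)`.

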