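# Methods

This note documents the models, parameter choices and numerical decisions
behind `finehap`, and what the synthetic data can and cannot show.

## Synthetic cohorts

Chromosomes are founder mosaics. Each population holds a founder pool
(default 40 founders per population) over `n_sites` (default 400) sites
spanning ~298 kb; a chromosome starts on a uniformly chosen founder and,
between consecutive sites, switches to a uniformly chosen *other* founder
with probability 1 − exp(−ρ·d<sub>j</sub>), where d<sub>j</sub> is the
inter-site distance in Morgans. Each emitted allele is flipped with
mutation probability μ (default 10⁻⁴). The population LD contrast is
carried entirely by the switch scale ρ: the European-like population uses
ρ = 500 (≈1–2 switches per chromosome across the locus), the African-like
population ρ = 2000 (≈6–7). This is not a coalescent model — there is no
drift, no tract-length realism, and founder diversity stands in for
ancestral diversity. Passing tests therefore demonstrate correctness of the
*methods* under the assumed structure, not performance on real genomes.

The recombination landscape is piecewise constant: 1.5 cM/Mb background
with a 0.01 cM/Mb core spanning 60 kb in the locus centre, mimicking a
hotspot-bounded haplotype block. This is what makes a multi-kilobase
segment shared by all target homozygotes possible at realistic sample
sizes; on a flat map the intersection of mosaic segments across dozens of
chromosomes collapses.

Five tag sites cluster across ~30 kb in the core. Founders are assigned tag
haplotypes by deterministic largest-remainder counts from the stated
population frequencies (European-like: hap1 0.56, hap2 0.36, rare 0.08;
African-like: hap1 0.31, hap2 0.28, hap3 0.175, hap4 0.145, rare 0.05), so
the frequencies are conditions of the study rather than random outcomes. A
chromosome's label is its realized allele string at the tag sites.

Ancestral site frequencies are drawn once, shared by both populations:
uniform on (0.1, 0.5) with a 30% monomorphic reserve (plus an extra 30%
inside the core). The tag-cluster interior is ancestrally invariant — the
injected variants are the novel variation on the target background, which
mirrors the study design in which the discovered variants were absent from
reference backgrounds. Specific variants (default k = 9) are injected at
monomorphic sites inside the *true* shared target segment (computed from
the recorded donor paths, so every injected position provably lies inside
it), carried with per-variant probability drawn from U(0.75, 0.97) on
target-labelled chromosomes and 0.02 on other African-like chromosomes
(exactly 0 on European-like ones).

Phenotypes follow the forward models stated in the interfaces: logistic
case/control status with per-haplotype log-odds (defaults log 1.35 for the
European risk background and log 1.67 for the target — the study-scale
effects), baseline prevalence 0.35 on the covariate-free liability (the
cohorts are case-enriched); one expression trait with β = 0.75 residual-SD
per target-haplotype allele inside a 27-gene matrix whose other genes are
noise plus a hidden binary batch (what the latent-factor stage absorbs);
seven traits with effects (−0.15, 0, 0, 0, −0.12, 0, −0.12) SD/allele under
a block-structured correlation (lung-function block 0.3–0.6,
inflammation/allergy block 0.15–0.35); severity from a proportional-odds
model with slope 1.58 and thresholds (−0.840, 0.353), chosen so the
baseline category split is ≈ 19:18:26 over 63 — matching the severity
cohort's composition. Expression and trait effect sizes are free parameters
of the simulation (the source estimates are on latent-adjusted scales); the
chosen values give partial power at the default sample sizes, so both
significant and non-significant stages occur, as in real data. Covariates
are one binary sex analogue, a 3-level site analogue and three continuous
PC analogues with small fixed liability effects.

Kinship is optional and block-diagonal (full-sib blocks, off-diagonal 0.5),
with a matched Cholesky-based polygenic draw. All generation is
bit-reproducible from `SimConfig.seed`.

## Haplotype EM and the posterior-weighted GLM

Compatible unordered haplotype pairs are enumerated per individual
(2^(h−1) pairs for h ambiguous splits; missing genotypes are expanded over
both alleles rather than dropping the individual; the heterozygosity cap
defaults to 20 sites). EM starts from uniform frequencies over the
haplotypes compatible with the sample; optional Dirichlet-perturbed
restarts escape symmetric stationary points (e.g. a lone double
heterozygote is a saddle at (¼,¼,¼,¼)). Convergence is relative
log-likelihood change < 10⁻⁸ with a 5000-iteration cap; the observed-data
log-likelihood is asserted non-decreasing at every step. Tied phasings keep
both pairs at equal weight — phase is never assigned arbitrarily.

The haplotype GLM expands each individual over its compatible pairs,
weights rows by the posterior probability of the pair given genotype *and*
outcome, and refits a weighted logistic regression until the coefficient
change falls below 10⁻⁶, holding the EM frequencies fixed. This is EM for
the joint phase-outcome model with known frequencies, so the point estimate
is the MLE of the observed mixture likelihood. Naive weighted-GLM standard
errors understate uncertainty when phase is genuinely ambiguous (they
treat the expansion as real data); Wald SEs are instead computed from the
observed-data information via Louis' identity, which restores nominal CI
coverage (~0.95 at n = 2000 in the calibration suite) and type-I error.
Coefficients above 15 in absolute value are reported as separation
failures. Haplotypes under the 5% frequency threshold are pooled into one
"rare" class; the threshold equals the reporting threshold.

## Copying-model painting

The copying HMM uses transition "stay" probability (1 − s_j) + s_j/D and
"move" probability s_j/D to each other donor, s_j = 1 − exp(−ρ·d_j), with
emission 1 − θ on allele match. Forward–backward uses per-site rescaling
with stored scale factors (no underflow at 10⁵ sites; exercised at 2×10⁴ in
tests). Viterbi runs in log space with ties broken toward the lower donor
index. Defaults when parameters are not given: ρ scaled so the expected
switch count across the painted region equals the donor count, and θ half
the Watterson-style rate 1/Σ<sub>i&lt;D</sub>(1/i) — both overridable;
parameter estimation by EM is out of scope. Donors get a uniform prior, and
panel members are painted leave-one-out (the target is removed from its own
donor set; its homolog stays).

Because synthetic donors are mosaics of a small founder pool, many donors
are locally identical and the *donor-level* maximum posterior is diffuse
(mass splits across identical donors); the *label-level* posterior —
summing donors by tag haplotype — is what carries the signal and is near 1
in practice. The painting-quality summary reports the donor-level statistic
as defined (median per-chromosome maximum posterior); interpret it with
this in mind on synthetic panels.

Switch points are reported wherever the per-site argmax label changes.
Within a tract where the outgoing and incoming donors are identical the
switch position is unidentifiable; recovery tests therefore credit a
detection anywhere within that tract (±1 interval).

## Critical region and specific variants

The shared segment is the maximal run of consecutive sites at which every
target-homozygote chromosome's argmax label equals the target label.
Boundary evidence counts distinct chromosomes whose label differs from the
target at the first flanking non-shared site on each side; "bounded by at
least two events" is interpreted per flank at that first site (an
alternative reading — events anywhere in a flanking window — would give
larger counts; the strict reading is conservative and is reported with a
below-threshold flag rather than suppressing the interval). Candidate runs
are scanned widest-first with ties to the left.

Extension: per-side extension = frac × width, rounded to 0.1 kb per side
(this reproduces 23.9 kb → 1.2 kb/side → 26.3 kb; `per_side_rounding=0`
gives exact arithmetic). Consensus is a chromosome-level majority (two
chromosomes per homozygous individual); exact ties yield an ambiguity code
and ambiguous sites are excluded from specificity calls rather than treated
as matching. A site is specific iff the target's unambiguous consensus
allele differs from every other group's unambiguous consensus allele.
Coordinates are 0-based half-open internally and 1-based inclusive in
reports; BED files are 0-based half-open.

LD r² is computed from phased haplotype frequencies; monomorphic sites
yield NaN. Loop annotation keeps interval pairs with score ≥ 5 and links a
variant to a promoter when it lies within 1 kb (inclusive) of one anchor
whose partner overlaps the promoter.

## Association stages

Latent factors are the top left-singular directions (over individuals) of
the covariate-residualized, gene-standardized expression matrix. The source
design used 11 factors against genome-wide expression; with the synthetic
27-gene matrix that many expression-derived factors over-condition — they
absorb the planted cis effect and induce collider associations in null
genes — so the pipeline default is 2 (enough for the planted batch). The
operation itself takes any count.

The cis scan is OLS of expression on dosage given covariates and factors,
for variant–gene pairs with |position − TSS| ≤ 500 kb and MAF ≥ 0.05
(sub-threshold variants are excluded and logged); all pairs form one
BH family, thresholded at FDR ≤ 0.10. The kinship LMM is single-component
REML: eigen-decompose K once, profile β and σ²ₑ out on that basis, optimize
the variance ratio by a coarse log-grid plus bounded scalar refinement;
K = I collapses exactly to OLS. Ordinal severity uses a proportional-odds
logit fit by maximum likelihood (BFGS); with two categories it reduces to
binary logistic regression. The stratified additive test fits a logistic
model of status on the modifier dosage within each homozygote stratum and
reports a no-variation result instead of failing when the modifier is
constant.

The global-null test draws z ~ MVN(0, R) (Cholesky, chunked at 2×10⁵
draws), counts components with two-sided p < α = 0.05, and reports the
proportion of draws with count ≥ k plus its binomial standard error;
k defaults to the observed exceedance count and R to the correlation of
covariate-residualized traits. Monte Carlo (default 10⁶ draws, seeded) was
chosen over analytic orthant evaluation for transparency; with R = I it
converges to the binomial tail (0.003757 for m = 7, k = 3).

## Problem sizes and determinism

Default study conditions: 100 + 1060 individuals, 400 sites, 40 founders
per population. The calibration suites use 200 replicates at n = 2000 for
GLM coverage, 100 planted-truth seeds for discovery, 10⁶ draws for the
global null, and reduced cohorts (60 + 400 individuals, 200 sites) for
end-to-end tests; these sizes give stable Monte Carlo assertions at the
stated tolerances. Every stage seed is derived deterministically from the
global seed and the stage name (CRC-based SeedSequence), so reruns are
bit-identical for deterministic stages and reproducible for stochastic
ones.

## Known limitations

- No coalescent realism: founder mosaics have geometric tract lengths and
  no genealogy; painting-quality magnitudes on synthetic panels are not
  comparable to real-data values.
- The haplotype GLM holds EM frequencies fixed when reweighting (the
  original formulation updates them jointly); SEs ignore frequency-estimate
  uncertainty. Calibration tests show nominal coverage at the study's
  sample sizes, but very small samples with heavy phase ambiguity may
  deviate.
- Copying-model ρ and θ are fixed defaults, not estimated.
- The LMM fits one genetic variance component; no multiple random effects.
- The eQTL stage assumes log-scale expression input; count preprocessing is
  the caller's responsibility.
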