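# Methods

`grspipe` implements a complete genetic-risk-score (GRS) analysis for a
polygenic autoimmune disease — systemic lupus erythematosus (SLE) is the
motivating case, with lupus nephritis (renal involvement) as the severity
proxy — together with a synthetic-cohort generator that provides ground truth
for every stage.  This note records the models, the numerical choices, and
what the tests do and do not establish.

## Synthetic cohorts

### Genotypes and linkage disequilibrium

Haplotypes follow a first-order copying chain along a single synthetic
chromosome with a fixed 5 kb inter-SNP spacing.  The allele at SNP *j* copies
the allele at SNP *j−1* with probability `ld_rho`, otherwise it is drawn
fresh at a base frequency `u_j ~ Uniform(maf_range)`.  Consequences used
throughout:

* stationary marginal frequency `m_j = ρ m_{j−1} + (1−ρ) u_j`;
* allelic covariance `Cov(X_a, X_b) = ρ^{b−a} m_a (1−m_a)` — LD decays
  geometrically with SNP distance.

This is the smallest model with a single knob (`ld_rho`, default 0.6) that
makes clumping non-trivial: neighbouring SNPs tag each other with r² ≈ ρ²
(genotype scale), so index selection must actually resolve LD.  Genotypes are
sums of two independent haplotypes (Hardy–Weinberg by construction).  Allele
pairs are drawn only from non-ambiguous combinations so that cross-dataset
harmonisation (which drops A/T and C/G variants) never silently shrinks a
simulated panel.

### Liability threshold disease model

`n_causal` SNPs receive i.i.d. normal effects β, rescaled so that the genetic
value `G = Σ β_j (g_j − 2 m_j)` has variance exactly `h2_liab`.  The
rescaling uses the exact variance under the chain covariance (including the
causal–causal LD cross-terms, truncated where ρ^gap < 1e−10), not the
linkage-equilibrium approximation `Σ 2 m q β²`; with LD present the two can
differ by a few percent, which matters when a recovery test compares an
achieved AUC against a theoretical ceiling with a ±0.02 band.  Liability is
`L = G + e`, `e ~ N(0, 1 − h2_liab)`; a sample is a case when `L` exceeds
`Φ⁻¹(1 − prevalence)`.

### Retrospective (case-control) sampling

Cohorts with fixed case and control quotas are drawn by simulating population
individuals until both quotas fill.  Implementation: liability needs only the
causal columns, so a screening pass simulates just those columns using the
exact skip-transition matrices of the chain (products of the per-SNP 2×2
transitions between consecutive causal sites); retained samples then have
their non-causal columns filled from the exact conditional distribution of
the chain given the causal alleles (forward sampling against precomputed
backward 2×2 products within each inter-causal segment).  This is equal in
law to brute-force simulation of whole individuals — the unit suite checks
marginal frequencies, adjacent-SNP correlation and the genotype→G identity on
the sampled cohorts — and makes a 1%-prevalence cohort of 11,000 samples ×
20,000 SNPs (≈ 410,000 simulated individuals) feasible in about a minute.

### Severity and onset

Within cases, renal involvement is Bernoulli with
`logit P = sev_intercept + sev_slope · G_std`, and onset age is
`onset_mean + onset_slope · G_std + N(0, onset_sd)` floored at one year,
where `G_std = G / √h2_liab` (population standardisation).  Defaults
(`sev_intercept −0.4`, `sev_slope 0.5` per SD, `onset_mean 33 y`,
`onset_slope −2 y` per SD, `onset_sd 10 y`) give a renal fraction near 40%
and onset means near 30/35 years in the high/low-load halves — the scale of
phenotype differences reported for lupus cohorts.  Severity depends on
genetic load only (no renal-specific loci), which is exactly the hypothesis
the severity analyses are designed to detect.

### Second ancestry

`fst > 0` drifts the base frequencies by the Balding–Nichols model
(`Beta(p(1−F)/F, q(1−F)/F)`), keeping variant identities and causal effects;
drifted frequencies are clipped to [1e−6, 1−1e−6] to stay polymorphic.  This
emulates cross-ancestry training/testing where allele frequencies (hence LD
and per-SNP power) differ but the causal architecture is shared — an
idealisation: real cross-ancestry transfer also involves different LD maps
and effect-size heterogeneity, which the generator does not model.

### What passing tests do not show

The generator has no genotyping error, no missingness by default, no
realistic human LD blocks, no sex chromosomes, and its severity mechanism is
exactly the load-only model.  Green tests therefore demonstrate that the
statistical machinery is correct and calibrated under the stated assumptions,
not that the pipeline's numbers would be reproduced on real cohort data.

## GWAS stages

* **Variant QC** uses closed lower bounds (MAF ≥ 0.001 and INFO ≥ 0.7 pass at
  the paper-style thresholds), with inclusive region exclusion; the MHC
  extended region is chr6:24–36 Mb.
* **Relatedness** is method-of-moments IBD (PI_HAT = P(IBD=1)/2 + P(IBD=2))
  from identity-by-state counts.  Expectations are computed as draws *without
  replacement* from the observed allele pool (2N alleles), which removes the
  small-sample bias of plug-in frequency formulas; the IBD probabilities are
  combined signed and only the final PI_HAT is clipped to [0, 1], since
  clipping the components individually biases null pairs upward.  Within a
  flagged pair the higher-missingness member is removed.
* **PCA** standardises dosages by √(2p(1−p)), imputes missing to the mean,
  and fixes component signs by making the largest-magnitude loading positive.
* **Association** defaults to per-SNP logistic Wald.  Fits are a batched
  Newton–Raphson vectorised across SNPs (closed-form 2×2 solve when the only
  covariate is the intercept), warm-started at the outcome log-odds, step
  tolerance 1e−6 (quadratic convergence leaves the solution accurate to
  ~1e−12), step clipped to ±4 per iteration, and |β| > 15 treated as
  separation and flagged with missing effect.  Results agree with
  statsmodels' per-SNP fits to ~1e−13.  The allelic test is the 2N-allele
  Pearson chi-square; the trend test is the 1-df Cochran–Armitage
  (χ² = N r²).  For the chi-square tests the table reports β = ln OR with
  Woolf SE, z = β/SE, and P from the named statistic.
* **Inflation** is λ = median(Z²)/0.4549 with QQ coordinates.
* **Meta-analysis** is fixed-effects inverse variance after harmonising each
  SNP to the alleles of the first table carrying it (sign flip on swapped
  alleles, strand flip where unambiguous, strand-ambiguous mismatches
  dropped); single-study SNPs are carried through flagged.

## Clumping and thresholding

Greedy clumping scans candidate indexes (P < p1) in ascending P; every
unassigned same-chromosome SNP within ±`window_kb` with r² ≥ `r2_max`
against the index joins its clump.  P ties are broken by (chromosome,
position, id), making the result independent of input row order.  The
secondary P threshold is fixed at 1.0 (any SNP may be absorbed), matching the
reference tool's default.  r² is the squared Pearson correlation of dosages
(composite LD) over pairwise-complete samples; a vector constant on the
shared support is "undefined" and treated as not-in-LD.  The scalar and
vectorised r² paths share one sums-of-products formula so threshold
comparisons at exact grid values (r² = 0.2) cannot disagree in the last ulp
— the brute-force oracle comparison found exactly such a case.  The default
grid is the published 8 × 2 × 2 sweep (p1 ∈ {0.1, 0.01, 1e−3, …, 5e−8},
r² ∈ {0.2, 0.5}, window ∈ {250, 1000} kb) = 32 score configurations.

## Scoring

Weights are per-allele log odds ratios.  Alignment to a target dataset keeps
the weight untouched and instead flips the dosage (`2 − g`) when the effect
allele is the dataset's allele2; strand flips are applied only where
unambiguous; A/T and C/G variants are always dropped.  Missing dosages are
imputed to 2 × (effect-allele frequency of the scored dataset) by default
(`mean_dosage`), or the SNP is omitted for that sample (`omit`).  MHC tag
SNPs (rs2187668/rs9267992 for European training, rs9271366/rs9275328 for
Chinese training) take their weights from the training association table and
are added only for within-population scoring.

## Polygenicity test

Target Z scores are polarized so the effect allele is the discovery risk
allele (discovery β > 0); SNPs with discovery β = 0 have no defined risk
allele and are dropped.  Within discovery-P deciles ((lo, hi], so P = 1 falls
in the top bin) a one-sample t-test evaluates mean(Z) = 0.  The reported P is
two-sided — conservative given the one-directional alternative; a bin with
fewer than two SNPs or zero variance is reported degenerate (all-zero bins as
p = 1).  Inputs should be LD-thinned first (the pipeline clumps the discovery
table at r² = 0.1, 250 kb before polarizing); the type-I calibration test
simulates unlinked SNPs for this reason.

## Evaluation

* **AUC** is the Mann–Whitney statistic with ties counted ½; variance and CIs
  use the DeLong structural components with a normal approximation, truncated
  to [0, 1] (degenerate zero-variance cases give point CIs).  The paired
  comparison is the DeLong Z test on the AUC difference.  The implementation
  reproduces R `pROC::roc.test` to reporting precision; against an exact
  permutation reference the normal approximation is within 0.0074 for
  n ≥ 120 but can deviate by ~0.05 at n ≈ 30 — an inherent small-sample
  property of the method worth remembering when comparing AUCs in small
  strata.
* **Quintiles** are assigned by stable-sorted score order with near-equal
  sizes (ties fall to the lower quintile).  Each upper quintile versus the
  lowest gives an odds ratio with Woolf log-scale 95% CI and a Pearson
  chi-square P; an empty cell triggers a flagged Haldane–Anscombe 0.5
  correction of the OR and CI.
* **Two-way ANOVA** of the score on age group (default cutoff 30 years,
  parameterised) and renal group uses sequential type-I sums of squares in
  the order age, renal, interaction; under a balanced design this equals the
  type-III analysis.  An empty design cell drops the interaction, flagged.
* **GLM** supports logistic and linear families with named predictors and
  product interactions; rank-deficient designs raise an error naming the
  collinear terms, and logistic coefficients with |β| > 15 are flagged as
  separation-suspect.
* **Power** is the allelic two-proportion normal approximation: alleles are
  counted as 2N independent trials, `p1 = p0·OR/(1 + p0(OR−1))`, null SE from
  the count-weighted pooled frequency, and both rejection tails are summed so
  the null (OR = 1) power equals α.  This closed form is the package's
  defined contract for the power operation (a genotypic 2-df model would need
  assumptions — prevalence, dominance — that the scenario does not pin down).
  At the within-case renal GWAS sizes (1152 vs 1949) it gives power 0.87 for
  OR 1.5 at RAF 0.2 and α = 5e−8.

## Pipeline

`run_experiment` drives everything from one config: a shared genome, cohorts
with roles (discovery / test / cross-population) and quotas, the clumping
grid, and policies (missing-data rule, MHC tags, age cutoff, severity-GRS
spec).  All randomness derives from the master seed: the genome from the seed
itself, each cohort from a fixed child stream, so a re-run is byte-identical.
Cross-population pairs never receive MHC tags.  The severity analyses score
each cohort's cases with the discovery-trained GRS at the configured spec
(default p1 = 1e−5, r² = 0.2, 250 kb), falling back to the loosest grid
threshold when nothing clears it on a small panel.

## Problem sizes

The acceptance suite runs the recovery experiment at the study-condition
sizes (20,000 SNPs, 2,000 causal, h² = 0.3, prevalence 1%, 4,000/7,000
training and 1,500/2,500 test samples); null calibration uses 10⁴ SNPs ×
2,000 samples plus 200 replicate pairs of 600-SNP cohorts for the binned-Z
type-I rate.  `scripts/acceptance.py` reruns the same analyses at roughly
half that panel size (10,000 SNPs, 1,000 causal, 2,000/3,500 + 1,000/1,700
samples), which leaves every estimate's Monte-Carlo error well inside the
comparison bands while keeping a full from-scratch run in the minutes range.

## Known limitations

Single synthetic chromosome (no inter-chromosomal structure); composite-LD
clumping only (no reference-panel LD); no imputation, phasing or HLA
modelling; cross-ancestry drift changes frequencies but not effect sizes or
LD topology; the DeLong small-sample caveat above.
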