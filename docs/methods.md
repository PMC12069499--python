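# Methods

## The scientific setting

In a parent–offspring trio design, a *parent-of-origin effect* (POE) on a
quantitative trait is an asymmetry between the mother's and the father's
influence: either the offspring trait associates more strongly with one
parent's phenotype (phenotypic POE, which may reflect intrauterine
programming, imprinting or maternal-line inheritance), or an allele's effect
depends on which parent transmitted it (genetic POE, the signature of
genomic imprinting). `triopoe` implements both layers plus the supporting
machinery: trait preprocessing, trio genotype QC, deterministic allele-origin
assignment, and a fully truth-tracked synthetic cohort generator.

## Phenotypic models

**Cross-sectional.** For trait *y* at visit *v* in stratum *s* (all offspring,
sons, daughters), each parental effect is the OLS slope in

    y_off = a + b_par · z(x_par) + c' · covariates + e

where `z(x_par)` is the parent's (transformed) trait z-scored on the
analysis sample, so `b_par` is per parental SD. Covariate tokens: `age`,
`sex` (0 = male, 1 = female; automatically dropped inside a sex stratum),
`bmi`, `parent_age`, `parent_bmi`. The anthropometric default is
(`age`, `sex`); the cardiometabolic default adds BMI of offspring and
parent(s). When the outcome trait is BMI itself the BMI covariate is dropped
(adjusting an outcome for itself would be tautological). Listwise deletion is
per model, so maternal and paternal fits may have different n — as in the
source tables. Underpowered or rank-deficient cells become explicit
`SkipRecord`s, never silent omissions.

**The Wald POE test.** With maternal coefficient b1 (SE1) and paternal b2
(SE2),

    Z = (b1 − b2) / sqrt(SE1² + SE2² − 2·cov(b1, b2)),   p = 2·(1 − Φ(|Z|)).

The covariance term enters twice, as the variance of a coefficient
difference requires; with the default separately fitted models it is taken
as zero (`cov_method="zero"`, validated against the published Z values),
with `"joint"` it comes from the coefficient covariance of a both-parents
model, and with `"bootstrap"` from paired resampling of whole trios
(default 200 resamples). Significance flags: nominal p < 0.05 and the fixed
study-wise threshold p ≤ 0.001 (the source analysis states the Bonferroni
threshold rather than the test count, so the threshold is what is
implemented).

**Mid-parent heritability.** The classical estimator regresses the offspring
trait on the mean of the two parental z-scores (not re-standardized), so
with equal parental contributions the slope approaches the *sum* of the
per-parent standardized slopes; trios missing either parent are excluded.

**Longitudinal.** Offspring measurements are stacked over visits and fitted
with both parental predictors jointly plus a random intercept per family
(`statsmodels` MixedLM). With one offspring per family the family and
individual levels coincide, so the model carries two variance components in
its result (`family`, `individual`) with the individual one reported as 0;
the residual captures the inter-observation variability. Estimation is REML
by default — chosen so that in the degenerate limit (single visit, zero
random variance) the fixed-effect covariance equals the df-corrected OLS
covariance exactly and the longitudinal contrast coincides with the joint
cross-sectional Wald Z; `reml=False` gives ML. A single-visit fit is treated
as a precondition error unless `allow_single_visit=True`, and whenever every
family contributes one observation the intercept variance is unidentifiable
and is pinned at 0 with a note, the fit falling back to the equivalent OLS.
Parental traits are measured once ("baseline") in the generator; with
multi-wave parental data the wave closest to the offspring visit would be
the natural time-varying predictor, but only the baseline route is exercised
here.

## Genetic models

**QC.** SNPs are excluded when missingness (over all samples) exceeds 5 %,
founder minor-allele frequency falls below 1 %, or the founder
Hardy–Weinberg exact-test p falls below 0.05 (all thresholds configurable).
MAF and HWE deliberately use founders only: offspring genotypes are
correlated with their parents' and would distort both statistics. The report
lists every statistic and the first failing rule per SNP.

**HWE exact test.** The two-sided conditional exact test: given the allele
counts, every attainable heterozygote count has a multinomial probability,
and p is the sum of the probabilities not exceeding that of the observed
configuration. The implementation enumerates in log space (`gammaln`),
normalizes with `logsumexp`, and keeps exact ties together with a 1e-10
log-slack; a chi-square fallback is used above 5000 founders. The test suite
checks it against an exact-rational (Fraction) brute-force enumeration.

**Mendelian errors and origin assignment.** A trio genotype combination is a
Mendelian error iff it is impossible under biparental transmission (the full
27-cell truth table is checked against brute-force enumeration). Origin
assignment is a deterministic case analysis: homozygous offspring force both
origins; a heterozygous offspring is resolved whenever at least one parent
is homozygous; the offspring-AB/mother-AB/father-AB trio is AMBIGUOUS; any
missing genotype gives MISSING. AMBIGUOUS trios are excluded from the
origin-based models — population phasing could resolve some of them but is
out of scope, and exclusion is conservative. Trios flagged as Mendelian
errors contribute no origin call for that SNP (the SNP itself is retained
unless it fails QC).

**Association.** With major allele A and minor allele B, and m/p marking the
transmitting parent, three contrasts are fitted on the log-transformed,
z-scored trait: maternal ApBm vs AA, paternal AmBp vs AA, and poe
ApBm vs AmBp (reciprocal heterozygotes). BB homozygotes, carrying no origin
information for a single-copy contrast, are not used. The fit is a Gaussian
GEE with independence working correlation, clustered on family, with robust
sandwich SEs; since each family contributes one offspring the clusters are
singletons and the fit provably equals heteroskedasticity-robust (HC0) OLS —
an equivalence the suite asserts at 1e-8. Default covariates are offspring
age, sex and BMI (the source's table legend includes BMI where its methods
text lists age and sex only; both sets are expressible, BMI is simply
dropped when absent or when the outcome is BMI). Any additional covariate
name (e.g. gestational age for birthweight) is looked up as a trait at the
analysis visit. Groups below 10 offspring (configurable) yield a skip record
with the counts.

## Trait preprocessing

* Rank-based inverse-normal transform, Blom variant:
  Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks for ties and missing values
  propagating. The offset is configurable; Blom is the default because no
  specific variant is mandated by the source analysis.
* log / log2 / log-then-z (`log_z`) / z-score transforms; a per-trait
  registry (`transforms={trait: kind}`) drives the pipeline. Which trait got
  which transform is not stated in the source, so the registry is explicit
  configuration rather than hard-coded policy.
* Derived indices: BMI = weight/height², WHR = waist/hip, and Friedewald
  LDL = TC − HDL − TG/2.2 in mmol/l (divisor and validity bound
  configurable for mg/dl); triglycerides above the validity bound return
  missing with a warning. HOMA2 indices are consumed as pre-computed traits
  (they come from an external calculator).

## The synthetic generator

Per family: parental latent traits are independent standard normals (an
optional spousal-correlation knob exists because real assortative mating is
not characterized in the source); founder SNP genotypes are two Bernoulli(MAF)
alleles (Hardy–Weinberg); each parent transmits one allele uniformly at
random; offspring sex is Bernoulli(prop_female). The offspring latent trait
at visit v is

    bm(v, sex)·z_mother + bp(v, sex)·z_father + Σ_SNPs (em·Bm + ep·Bp)
      + family intercept + residual

with Bm/Bp the transmitted minor-allele indicators, so `em ≠ ep` is an
imprinted locus. Stored values are affine in the latent
(`mean + sd · latent`), or `exp(mean + sd·latent)` for `skew="lognormal"`
(mean/sd then live on the log scale), which makes the log-transform branch of
the pipeline exact. Offspring traits default to mean 0, SD 1, so fitted
slopes estimate the configured betas directly; visit ages get ±0.5 y uniform
jitter so age covariates are non-degenerate; a missing-parent rate blanks
one parent's phenotypes per affected family (never both). Genotype
missingness and genotyping errors are injected per SNP at configured rates,
every perturbation logged in the truth record. All randomness flows from the
single config seed; identical configs produce byte-identical cohorts.

The bundled `pmns_like_config` encodes the source design: ~700 trios, visits
at birth/6/12/24 y, 48 % female offspring, 8 % families with one parent
unphenotyped, per-visit maternal/paternal slopes set to the published
all-offspring estimates (magnitudes 0.03–0.48), and three imprinted-SNP
analogues with allele-origin effects of the order of the published
reciprocal-heterozygote estimates (0.13–0.35 SD, MAF 0.25–0.45).
`pcs_like_config` is the ~400-trio replication design with visits at
4/8/21 y.

**What the generator does not emulate:** trait–trait correlation structure
beyond the shared family intercept, assortative mating (off by default),
secular trends, measurement batch effects, multiple offspring per family,
and population stratification. Passing tests therefore demonstrate that the
estimators recover the truth under the stated generative model, not that any
particular real-data finding is correct.

## Verification sizes and numerical choices

Type-I calibration runs 1000 replicates of 500 trios under an effect-equal
null (bm = bp = 0.2; allele effects equal) and requires both the phenotypic
Wald test and the genetic reciprocal-heterozygote GEE to reject within the
binomial 95 % band around 0.05. Parameter recovery runs 100 replicates of
700 trios with bm = 0.3 / bp = 0.1 and a 0.3 SD maternal-allele effect,
requiring ≥93 % two-SE coverage and ≥80 % maternal-bias detection power for
the pooled longitudinal contrast. The HWE implementation is compared with
the exact-rational oracle on every table with total ≤ 50 plus a seeded
sample of tables with totals up to 200 at 1e-12. Published-table
reproduction checks all 108 printed Z cells; the three cells whose printed
coefficients are internally inconsistent with their own printed Z/p pair are
flagged in the bundled table (`note` column) and asserted to be exactly
those three.

## Known limitations

* Phenotypic POE is associational; nothing here distinguishes imprinting
  from intrauterine environment or maternal-line mitochondrial effects.
* The zero-covariance Wald default slightly misstates the variance when the
  two parental estimates are correlated (shared offspring outcome, or
  assortative mating); the joint and bootstrap covariance routes exist for
  sensitivity analysis.
* AMBIGUOUS (double-heterozygote) trios are dropped from the genetic models,
  costing power at high MAF; resolving them requires population phasing.
* The GEE layer assumes one offspring per family in its singleton-cluster
  equivalence; multi-sibling extensions would need the full cluster
  machinery (the GEE route already supports it, but the generator does not
  produce siblings).
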