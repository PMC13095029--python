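# Methods

This note documents the models, generative assumptions, defaults, and
numerical choices behind `kirhla`, in the spirit of a statistical-software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The statistical model

For mother-offspring pair *i* (birth weight `BW_i` in grams):

```
BW_i = β0 + β1 F_i + β2 M_i + β3 F_i M_i + β4' Cov_i + u_m(i) + ε_i
u_m ~ N(0, τ²)   (one intercept per mother, shared by siblings)
ε_i ~ N(0, σ²)
```

Six models arise from crossing three fetal HLA-C codings — C2 presence
(0/1), relative C2 count (0/1/2: fewer/equal/more C2 alleles than the
mother), and exclusively-paternal C2 (0/1) — with two maternal KIR
dosages (B-haplotype copies; KIR2DS1 copies). Covariates are offspring
sex (0 female / 1 male), gestational age in weeks (where the cohort
recorded it), genotyping batch (indicator-coded), the first five genetic
principal components of mother and of child, and optionally year of
birth. The interaction coefficient β3, in grams per unit of the product
term, is the target of inference; a reference magnitude of 250 g — the
effect size the pipeline is designed to detect or refute — anchors the
power study.

### Parental-origin inference

With unphased mother-offspring C1/C2 genotypes, enumerate every
consistent (maternal-transmitted, paternal) allele assignment. The
paternal-origin indicator is 1 when the fetus carries a C2 that is
*exclusively* paternal — which happens only for mother C1/C1, fetus
C1/C2. When mother and fetus are both C1/C2 the transmitted allele cannot
be identified (the fetal C2 may be either parent's); such pairs are
excluded from the paternal-origin models only. Two genotype combinations
(mother C1/C1 with fetus C2/C2, and the reverse) are Mendelian-impossible
and excluded everywhere with an audit reason — under imputation error
they are expected in real data, so they are logged, not fatal.

### Estimation and inference

The only mixed model the analysis needs is a Gaussian LMM with a single
random intercept. Its marginal covariance is block diagonal,
`V_j = σ²(I + λ J_{n_j})` with `λ = τ²/σ²`, so β and σ² profile out in
closed form per λ (Sherman-Morrison on each family block) and REML
reduces to a one-dimensional optimisation in λ (`kirhla.lmm`). Numerical
choices:

* REML by default (ML available); Wald z confidence intervals and
  p-values on fixed effects — conventional for cohort sizes in the
  hundreds and above, and what inverse-variance meta-analysis consumes.
* λ is searched on a log scale by bounded minimisation, then polished by
  root-finding on the analytic derivative of the profiled criterion; the
  boundary estimate τ² = 0 is admissible (expected when sibships are
  rare), never an error.
* The design is internally centred and scaled (estimates mapped back
  afterwards), which conditions the normal equations and makes estimates
  invariant to covariate recentring up to ~1e-10.
* When every mother has one child the criterion is flat in λ and the
  estimates and standard errors coincide with OLS identically — a tested
  equivalence.
* statsmodels `MixedLM` is exposed as `engine="statsmodels"` and used in
  the test suite as an independent oracle; the closed-form path exists
  because the Monte-Carlo studies need thousands of fits.

A required *genetic* regressor (fetal, maternal, or product term) that is
constant across the design rows raises a degenerate-design error naming
the column. Constant *covariates* (e.g. a single genotyping batch) are
pruned and reported in the fit metadata instead — erroring there would
make perfectly analysable single-batch cohorts unusable.

### Meta-analysis

Per-cohort β3 estimates are pooled fixed-effect with weights 1/SE²;
pooled SE = (Σ 1/SE²)^(−1/2), normal reference for the CI and p-value
(not t: standard IVW practice at these sizes). Cochran's Q and I² are
computed as diagnostics only and never drive model choice. Forest-style
tables list cohort rows (sorted by cohort id) then the pooled row, per
model.

## 2. Genotype derivation

* **Hard calls.** Dosages and imputation quality scores in [0, 2] map to
  0 (d ≤ 0.3), 1 (0.7 ≤ d ≤ 1.3), 2 (d ≥ 1.7), missing otherwise;
  boundaries inclusive. One rule serves both SNP2HLA-style dosages and
  HLA*IMP:02-style Q-values (for allele-pair records with quality Q, the
  C2 dosage is Q × C2-allele count), keeping a single code path.
* **Ligand groups.** First-field HLA-C allele family only: C1 =
  {01, 03, 07, 08, 12, 14, 16}, C2 = {02, 04, 05, 06, 15, 17, 18}.
  Families outside both lists raise an unclassified-allele error and the
  record is excluded downstream with a logged reason.
* **KIR dosages.** Posterior-expectation copy number per locus
  (`Σ state·P(state)`); point-mass posteriors give exactly 0/1/2. Dosages
  enter regression continuously by default, with a switch to hard-call
  them first — the upstream convention quotes zero-uncertainty integer
  mappings, and both conventions are supported because neither is
  universal.

## 3. Phenotype QC

Applied in order, each exclusion carrying exactly one reason code, with
audit counts reconciling input = output + exclusions:

1. **Gestation window**: keep 37 ≤ GA < 43 weeks; cohorts without GA skip
   the filter.
2. **Self-report cleaning** (biobank-style cohorts): average repeated
   self-reported weights; exclude when repeats disagree by ≥ 1 kg or the
   mean falls outside 2.5-4.5 kg.
3. **SD outliers**: exclude |BW − mean| > k·SD, with mean/SD computed
   once on the records entering the stage (a single pass, no
   re-iteration). The default k = round(Φ⁻¹(1 − 1/(2n))) — the
   symmetric-range multiplier within which all n Gaussian observations
   are expected to fall — gives k = 3 at n = 625 and k = 4 at n = 4,550.
   Cohorts whose published k does not follow from their analysis n take
   an explicit per-cohort override; the mapping is deliberately explicit
   and overridable rather than opaque.

## 4. SNP panel harmonization

Pre-KIR-imputation filters on phased HAPS/SAMPLE panels against a
reference frequency list, applied extract → flip → frequency-filter
(idempotent on their own output):

* region: chromosome 19, 53,000,000-58,000,000 bp, build 37, 1-based
  inclusive;
* palindromic (A/T, C/G) variants are strand-flipped when the
  *complemented* cohort frequency matches the reference within a
  tolerance (default 0.05, a choice of this package) while the raw
  frequency does not;
* drop when |cohort − reference| frequency difference > 0.10; drop when
  the cohort frequency lies in the 45-55% ambiguity band (at 50% a strand
  flip is frequency-invariant, hence undecidable). A cross-dataset
  variant of the band rule (frequency straddling 50% between cohort and
  reference while within the band in both) is implemented and checked
  first so its reason code is informative, but it is logically contained
  in the within-cohort band rule and is configurable off.

## 5. The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes:

* maternal HLA-C genotypes: two alleles i.i.d. Bernoulli(C2 frequency) —
  Hardy-Weinberg equilibrium;
* transmission: one maternal allele chosen uniformly, plus one paternal
  allele drawn from the population frequency (random mating; fathers are
  never observed, matching the study design);
* maternal KIR: two haplotypes i.i.d. Bernoulli(B frequency); KIR2DS1
  copies Binomial(number of B haplotypes, carriage probability) — the
  only linkage modelled;
* birth weight: the model of §1 with the generative β's, plus sex,
  gestational age (Normal(39.9, 1.2) weeks, centred at 40 in the linear
  predictor), and PC effects; a mother-level Normal(0, τ) intercept
  shared by siblings; each mother contributes a second child with the
  sibship probability;
* all randomness flows from one integer seed; identical configurations
  give byte-identical cohorts.

Defaults (all configurable): C2 allele frequency 0.35, KIR B haplotype
frequency 0.45, KIR2DS1 carriage 0.9 per B copy — plausible
European-range values chosen once, since the analysis literature reports
no single canonical set; intercept 3,500 g with residual SD 434 g and
mother-level SD 180 g, giving a total birth-weight SD of ~470 g to match
the descriptive statistics of term-birth cohorts; sibship rate 0.1 so the
random-intercept machinery is genuinely exercised; sex effect +130 g
(male), gestational-age effect +150 g/week; genetic effects β1 = β2 =
β3 = 0 (the null) unless a study injects them.

### The imputation-error channel

Each sample × locus call (maternal and fetal C2-allele count; maternal
B-haplotype and KIR2DS1 copy numbers, each on states {0, 1, 2}) is
independently retained with probability equal to the locus accuracy,
otherwise replaced by one of the two alternative states uniformly — a
categorical mis-call model, the simplest mechanism consistent with a
scalar per-locus accuracy. Posterior rows place a configurable modal mass
on the observed state with the remainder spread uniformly; the default
modal mass is 1.0 (point mass), which makes accuracy 1.0 an exact
identity channel — with softened posteriors the expectation dosage is an
affine function of the observed state and would rescale regression
coefficients even without mis-calls, conflating posterior sharpness with
accuracy.

### What the generator does and does not emulate

It reproduces HWE, Mendelian transmission, KIR2DS1-on-B linkage, family
clustering, covariate structure, and nondifferential genotype
misclassification. It does **not** simulate SNP-level haplotypes, LD
beyond the single KIR2DS1-B parameter, population stratification
(PCs are pure noise unless given an effect), assortative mating,
differential or correlated imputation error, or non-European frequency
regimes. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly under the stated generative model — unbiased
effect recovery, calibrated type-I error and CI coverage, power
attenuation under mis-calling — not that any particular real-data result
is correct.

## 6. The power study

For each grid cell (KIR accuracy, effect size, sample size) the study is
replayed end to end: simulate → corrupt → derive → fit the C2-presence ×
KIR2DS1 model (model 2) → record Wald rejections at α for both the
maternal main effect and the interaction. The effect size is injected
into β2 and β3 simultaneously, so one fit serves both endpoints; the
interaction test is unaffected by the β2 shift (the main-effect term
absorbs it). Accuracy sweeps vary the KIR channel; the HLA channel stays
at its configured accuracy. Defaults: 200 replicates per cell for power
(binomial SE ≤ 0.016 at nominal-0.95 cells), 1,000 for size calibration;
α = 0.05. Replicate counts and exact error mechanism are this package's
choices, recorded in the output metadata. Cells whose replicates all fail
(e.g. no genotype variation) are flagged, never silently dropped.

## 7. Problem sizes used by the shipped studies

The acceptance test suite runs: 1,000 null cohorts of n = 2,000 for
type-I calibration (99% binomial band 0.036-0.064 around 0.05); 200
cohorts at the full study size n = 10,602 with β3 = 250 g for recovery
and coverage; and 200 replicates per accuracy ∈ {1.0, 0.7} at n = 10,602
for power. `scripts/acceptance.py` repeats the same computations at 500 /
150 / 100 replicates. These sizes put Monte-Carlo SEs in the 0.5-2%
range, which is the precision the assertions need.

## 8. Known limitations

* Wald (not likelihood-ratio or Kenward-Roger) inference; at the cohort
  sizes involved the difference is negligible, at n below a few hundred
  coverage may dip slightly.
* The mother-level variance is weakly identified at a 10% sibship rate;
  its point estimate is noisy (often at the zero boundary), though fixed
  effects and their SEs are robust to this.
* Hard-call thresholds create a missingness zone (0.3-0.7, 1.3-1.7) whose
  informativeness is ignored (missing-at-random exclusion).
* The cross-dataset ambiguity rule cannot drop anything the within-cohort
  band rule does not already drop (see §4); it exists for audit clarity.
* VCF/BGEN ingestion, four-digit HLA imputation, phasing, non-C loci,
  random-effects meta-analysis, and running the upstream imputation tools
  themselves are out of scope.
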