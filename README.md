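# kirhla

Maternal **KIR** × fetal **HLA-C** birth-weight interaction analysis as a
tested, reusable Python pipeline.

## The scientific problem

During pregnancy, maternal killer immunoglobulin-like receptors (KIR) on
uterine natural killer cells interact with HLA-C molecules on fetal
trophoblast. HLA-C alleles split into two ligand groups by the amino acid
at position 80 — C1 (asparagine) and C2 (lysine) — and KIR genotypes form
two broad haplotypes, A (mainly inhibitory) and B (mainly activating, the
latter carrying the C2-binding activating receptor gene *KIR2DS1*). A
widely cited hypothesis holds that particular maternal-KIR / fetal-HLA-C2
combinations shift offspring birth weight by as much as ~250 g, with the
effect tied to fetal C2 of *paternal* origin.

Testing this at biobank scale requires a pipeline: imputed KIR and HLA
calls must be hard-called and classified, parental origin of fetal C2
inferred from mother-offspring genotypes alone, phenotypes cleaned, a
family-clustered regression fitted per cohort, and cohorts pooled by
meta-analysis. `kirhla` implements that pipeline end to end, driven by a
synthetic mother-offspring cohort generator so every stage runs — and is
testable — with no access-controlled data.

It is written for statistical geneticists and perinatal epidemiologists
who want to replicate, extend, or stress-test maternal-fetal genotype
(MFG) interaction analyses.

## The models

For pair *i*, birth weight in grams is modelled as

```
BW_i = β0 + β1·F_i + β2·M_i + β3·F_i·M_i + β4·Cov_i + u_mother(i) + ε_i
```

with a Gaussian random intercept `u` per mother (siblings share it) and
six (F, M) combinations:

| model | fetal term F                         | maternal term M        |
|-------|--------------------------------------|------------------------|
| 1, 2  | C2 presence (0/1)                    | KIR B dosage / KIR2DS1 |
| 3, 4  | relative C2 count (0/1/2 = fewer/equal/more than mother) | KIR B dosage / KIR2DS1 |
| 5, 6  | exclusively-paternal C2 (0/1)        | KIR B dosage / KIR2DS1 |

Parental origin is decidable from mother-offspring genotypes except for
the doubly heterozygous pair (mother C1/C2, fetus C1/C2), which is
excluded from models 5-6. The interaction coefficient β3 is the quantity
of interest; per-cohort β3 estimates are pooled by fixed-effect
inverse-variance weighting, and a Monte-Carlo module quantifies power as a
function of KIR imputation accuracy, sample size, and effect size.

Estimation is profiled REML for the single-random-intercept model with
Wald (normal-reference) inference; statsmodels `MixedLM` is available as a
cross-check engine. See `docs/methods.md` for assumptions, defaults, and
numerical choices.

## Worked example

`examples/01_simulate_and_fit.py` simulates 2,000 pairs with a 250 g
KIR2DS1 × fetal-C2 interaction, derives the regressors through an exact
imputation channel, and fits all six models:

```
simulated 2000 pairs (1818 mothers), 0 excluded at derivation

model  interaction est (g)     SE      95% CI              p
  1         253.1         30.2  [  194.0,   312.2]   4.65e-17
  2         291.1         30.2  [  231.8,   350.3]   5.93e-22
  3          86.2         23.1  [   40.9,   131.5]   0.000194
  4         103.7         23.4  [   57.8,   149.6]   9.6e-06
  5         165.7         46.5  [   74.6,   256.9]   0.000366
  6         188.3         48.7  [   92.8,   283.7]   0.000111
```

Model 2 is the generative model: its CI brackets the injected 250 g. The
other rows show how the same signal appears under alternative fetal
codings and the correlated KIR-B dosage. The remaining examples cover
meta-analysis across five synthetic cohorts (`02`), the power-vs-accuracy
grid (`03`), SNP panel harmonization (`04`), and phenotype QC (`05`); each
prints what its numbers mean.

A thin CLI wraps the same library calls:

```bash
kirhla --config run.yaml all     # simulate -> derive -> qc -> fit -> meta
kirhla --config run.yaml power
```

## Layout

```
src/kirhla/
  simulate.py     synthetic cohorts + imputation-error channel
  derive.py       hard calls, C1/C2 groups, parental origin, KIR dosages
  harmonize.py    pre-imputation SNP panel filters (HAPS/SAMPLE)
  qc.py           phenotype inclusion/exclusion rules
  lmm.py          profiled-REML random-intercept solver
  association.py  the six interaction models
  meta.py         fixed-effect IVW pooling, forest tables
  power.py        power under imputation error
  io.py           table dialects, Oxford HAPS/SAMPLE, run config
  cli.py          thin click front end
```
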