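# Methods

## Polygenic score

A score panel is a list of variants, each carrying the eGFR-*lowering*
allele, the other allele, and a positive weight w_j (mL/min/1.73 m² per
allele, the magnitude of the GWAS effect).  For individual i with
effect-allele dosages d_ij ∈ [0, 2]:

- unweighted score: Σ_j d_ij (a plain allele count),
- weighted score: (Σ_j d_ij w_j) / w̄ with w̄ = (Σ_j w_j)/M.

Division by the **mean** weight, not the raw weighted sum, puts the
weighted score in "alleles of average effect" units: a one-unit change
corresponds to one average-effect allele, and both score types land on
the same ~2·M·f̄ scale (for the 634-variant creatinine panel, means
around 610-630).  Missing dosages renormalize per individual: w̄ is
taken over that individual's non-missing variants and the number of
variants used is reported, so a cohort missing one panel variant remains
comparable to a complete one.

Harmonization keeps variants present in both the scoring file and the
dosage data; an A/B-vs-B/A orientation mismatch flips the dosage to
2 − d; strand-ambiguous (A/T, C/G) pairs are matched by id and allele
pair only and flagged — no frequency-based strand inference, which is
defensible when both cohorts share one imputation panel.  Negative
source weights are re-oriented at load.  The imputation-quality filter
(r² < 0.8) applies to the allele-frequency comparison, not to scoring.

## eGFR

CKD-EPI 2009 (creatinine, mg/dL) and 2012 (cystatin C, mg/L):

    eGFR = I · min(B/κ, 1)^α · max(B/κ, 1)^β · a^age · f^[female] · r^[black]

with (I, a, f) = (141, 0.993, 1.018) and sex-specific κ/α
(0.7/−0.329 female, 0.9/−0.411 male), β = −1.209 for creatinine;
(133, 0.996, 0.932), κ = 0.8, α = −0.499, β = −1.328 for cystatin.
The race coefficient (1.159) is implemented for fidelity to the
published 2009 form but defaults to off.  Because the eGFR at the knot
equals the prefactor P = I·a^age·f·r, the equation inverts in closed
form branch-by-branch; the round trip is exact to ~1e-12 relative,
which the synthetic generator exploits to emit serum concentrations.

QC: cystatin validity categories 2-4 are excluded from cystatin
analyses only; the general-adult cohort is capped at age < 70 so the
two cohorts span disjoint age ranges; CKD is flagged at eGFR_crea < 60
(strict inequality).

## Association model

Stage 1 residualizes eGFR on covariates by OLS (intercept always
included).  The ladder: model 1 = age + sex + 10 genetic PCs; model 2
adds BMI; model 3 adds diabetes + hypertension; model 4 adds CAD +
high-ceiling diuretics.  The PCs sit in the residualization stage (not
the stage-2 regression), so stage 2 is strictly Y_i = β0 + β1·PGS_i + ε_i.
Reported per model: the residual outcome variance (n−1 denominator),
β1 with normal-theory SE/CI/p, and R².

R² is computed through the single-predictor identity
R² = β1²·s²(PGS)/s²(Y) — algebraically equal to the OLS coefficient of
determination, and stored this way so the decomposition holds to
machine precision on every fit (the pipeline asserts it).  The R²
confidence interval is a seeded nonparametric pairs bootstrap
(percentile, default 1,000 replicates), which carries no
distributional assumption.  p-values below 1e-300
are formatted as "< 1e-300".

The univariable screen regresses raw eGFR on each covariable
separately; smoking enters as two dummies (former, current) fitted
jointly and reported with the joint R².  The stepwise variance profile
adds covariates cumulatively (PGS last) and reports residual variances
with a fixed n−1 denominator, which makes the profile provably
non-increasing.  PGS distributions are compared across cohorts with the
two-sided Mann-Whitney U test: exact enumeration when the smaller
sample has ≤ 8 values and no ties, tie-corrected normal approximation
otherwise.

## Frequency comparison

Dosages are rounded half-up to best-guess genotypes.  Per variant, the
2×2 effect/other allele-count table (2N alleles per cohort) is tested
with the Pearson chi-square, 1 df, **without** Yates continuity
correction (a documented switch turns it on); tiers are nominal
(p < 0.05) and Bonferroni (p < 0.05/m).  Expected cell counts < 1 are
flagged; variants monomorphic across both cohorts are skipped.

Two exact binomial summaries (matching R's `binom.test`, i.e. the
minimum-likelihood two-sided rule with a 1e-7 relative tolerance on the
point-probability comparison):

- enrichment: k nominally significant variants out of n tested vs
  p0 = 0.05, one-sided P(X ≥ k);
- direction: among the nominal variants, the count with the
  eGFR-lowering allele rarer in the elderly cohort vs p0 = 0.5,
  two-sided.

QQ diagnostics use expected quantiles i/(m+1).  The pooled dosage
screen fits, per variant, a logistic regression of study membership on
dosage and linear regressions of age on dosage with and without
membership adjustment, reporting Wald p-values for QQ inspection.

## Synthetic cohorts and calibration

The generator emulates two cohorts: general adults (n = 2,900, age
24-69, uniform) and elderly (n = 2,272, age 70-95, uniform), on a
634-variant creatinine panel or a 204-variant cystatin panel.  Preset
prevalences (diabetes 3.1%/20.9%, hypertension 32.0%/72.7%, CAD
1.7%/15.5%, high-ceiling diuretics 1.3%/12.8%), BMI moments, smoking
and education mirror the two study populations; comorbidity flags get a
logistic age dependence (0.08 log-odds/year) with the intercept solved
so the realized prevalence matches the preset.

**Panel.**  Effect-allele frequencies are Uniform(0.01, 0.99) — this
reproduces the observed unweighted-score SDs (~14.7 for 634 variants vs
the published 14.8/15.2) — and weights couple to frequency as
w_j ∝ v_j^(−γ)·exp(η_j), v_j = 2f_j(1−f_j), η ~ N(0, 0.25²).  Because
the weighted score is invariant to the overall weight scale, the
coupling exponent γ is the calibration knob: it is solved per panel so
the expected weighted-score SD equals the preset target (13.3/14.0
creatinine, 8.4/8.5 cystatin).  The expected variance uses the exact
censored-normal variance of the clipped noisy dosage, not the raw
Hardy-Weinberg value: with imputation noise, clipping to [0, 2] shrinks
the dosage variance appreciably at extreme frequencies, exactly where
the coupling puts large weights, and ignoring it biases the realized SD
(and hence the calibrated β) by several percent.  If a small panel
cannot reach the target SD, the minimum-variance coupling is used with
a warning; when `m_variants` is overridden the SD target rescales by
√(m ratio).

**Genotypes.**  Hard genotypes are Binomial(2, f_j) (Hardy-Weinberg);
dosages add Gaussian noise scaled so corr²(dosage, genotype) ≈ the
requested imputation r² (default 0.97), clipped to [0, 2]; r² = 1
yields exact integers.

**Phenotypes.**  Latent eGFR is linear: mean eGFR (95.3/67.7 crea,
99.2/60.9 cys) + age effect (−0.70 crea; −0.91/−0.96 cys — chosen so
the univariable age R² lands near the observed 34%/10% crea and
43%/17% cys) + a small sex effect + comorbidity effects (per-preset,
sized so the model-2-to-4 residual-variance decline mirrors the
published ladder) + PGS effect + noise.  The PGS coefficient is derived
from the explained-variance target, not from a rounded printed
coefficient:

    β_PGS = −sqrt(target_r2 · target_outcome_variance / Var(PGS)),

with Var(PGS) the realized variance of the weighted score in the
simulated dosages, and the noise variance closes the budget:

    σ_ε² = target_outcome_variance·(1 − target_r2) − v_c,

where v_c is the age-/sex-orthogonal variance contributed by the
comorbidity effects.  This makes the age-/sex-adjusted residual
variance, β and R² simultaneously recoverable within rounding (the
printed rounded values are mutually inconsistent at the second decimal,
so deriving β from R² is the consistent choice).  Targets: creatinine
R² 9.6%/4.6% with outcome variance 157.65/228.93; cystatin 4.7%/3.6%
with 186.38/234.68.  Latent draws ≤ 1 mL/min/1.73 m² are redrawn
(bounded retries).  Serum values come from the exact CKD-EPI inverses,
so the biomarker → equation → analysis round trip is exercised; the
off-trait biomarker is emitted from a noise-perturbed copy of the
latent eGFR for table completeness only and carries no calibrated
signal.  All randomness flows from one master seed through named
substreams (panel, genotypes, covariates, noise), so stages regenerate
independently and runs are fully deterministic.

**What the generator does not emulate:** linkage disequilibrium between
panel variants (the real panels are conditionally independent by
construction, but real dosage data still carry local LD), population
stratification with real PC effects, non-uniform age distributions,
biomarker assay error distinct from the eGFR noise term, and any true
gene-by-age interaction.  Passing tests therefore demonstrate that the
analysis machinery recovers known structure under the published
moments, not that the biological conclusions transfer to real cohorts.

## Pipeline

One panel per trait is simulated (SD target = mid-point of the two
cohort targets) and shared by both cohorts; each cohort's PGS effect is
calibrated from its own targets.  An APOE-like variant is planted with
effect-allele frequencies 0.87 (general adults) vs 0.89 (elderly) —
assigned to the panel variant whose drawn frequency is closest to the
gap so the override barely perturbs the calibration — and the
sensitivity rerun excludes it (plus any configured ids) and reports the
R² deltas.  The frequency comparison runs on the r² ≥ 0.8 subset; the
enrichment test uses the nominal count, the direction test the nominal
subset.  Reports are plain JSON/TSV and byte-identical under a fixed
seed (timings go to the log only).

## Problem sizes

Defaults: full cohort sizes (2,900/2,272) and panels (634/204)
throughout; the replicate studies in the test suite and the acceptance
script use 200 replicates, which puts a Monte-Carlo standard error of
roughly 0.06 percentage points on a mean R² near 5-10% and ~0.002 on a
mean β — adequate for the published one-decimal precision, though mean
values lying within ~0.05 pp of a rounding boundary can flip at this
replicate count.  The toy preset (200 individuals, 50 variants)
completes the full pipeline in well under 30 s on one CPU.

## Known limitations

- The 2021 race-free CKD-EPI refits and the combined
  creatinine-cystatin equation are out of scope (GWAS weights were
  estimated on the 2009/2012 equations).
- The two-sided direction binomial follows the stated R definition;
  printed literature values for such tests are not always reproducible
  from the reported counts.
- No LD pruning, PGS training (LDpred-style), liftover, or genotype
  imputation itself — variant lists and dosages are inputs.
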