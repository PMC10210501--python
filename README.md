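# egfr-pgs

Polygenic-score analysis of kidney function across adult and elderly
cohorts: score construction, CKD-EPI eGFR, explained-variance
decomposition, and cross-cohort allele-frequency screening.

## The problem

Polygenic scores (PGS) built from GWAS-significant variants for
creatinine-based eGFR explain markedly less phenotype variance in
elderly cohorts than in general-adult cohorts.  The explained variance
decomposes exactly as

    R² = β² · Var(PGS) / Var(Y)

where β is the coefficient of the simple regression of age-/sex-adjusted
eGFR residuals on the PGS, Var(PGS) the score variance, and Var(Y) the
adjusted outcome variance.  Whether the age gap in R² comes from a
smaller β (age-attenuated genetic effects), a larger outcome variance
(comorbidity burden), or a shifted PGS distribution (survival/selection
on protective alleles) are distinct hypotheses with distinct signatures
— this package implements the full analysis that separates them, for two
kidney biomarkers (serum creatinine and cystatin C), plus a calibrated
synthetic two-cohort generator so the whole pipeline is testable without
any cohort data.

Core pieces:

- **Scoring** (`scoring`, `harmonize`, `pgs`): PGS-catalog-style scoring
  files; allele harmonization with dosage flipping; weighted scores in
  "alleles of average effect" units (weighted dosage sum divided by the
  mean weight).
- **Biomarkers** (`ckdepi`, `phenotypes`): CKD-EPI 2009 creatinine and
  2012 cystatin C equations, their exact closed-form inverses, and
  study QC rules (cystatin validity categories, the <70-year cap for
  the general-adult cohort, CKD at eGFR < 60).
- **Association** (`association`): two-stage residualization + PGS
  regression across a four-model covariate ladder, univariable
  covariate screens, stepwise residual-variance profiles, Mann-Whitney
  comparison of PGS distributions.
- **Frequency comparison** (`freqcompare`): best-guess genotypes,
  per-variant Pearson chi-square allele-frequency tests with Bonferroni
  tiers, exact binomial enrichment and direction tests, QQ diagnostics,
  per-variant dosage-vs-cohort screens.
- **Synthetic cohorts** (`simulate`): Hardy-Weinberg genotypes with
  imputation-style dosage noise and presets calibrated so the published
  headline numbers (PGS SD, adjusted outcome variance, Model-1 R² and β)
  are recoverable end to end.
- **Pipeline** (`pipeline`, `cli`): the full two-cohort comparison
  behind a `egfr-pgs` command-line interface with YAML config and a
  deterministic JSON/TSV report bundle.

## Worked example

Simulate the calibrated elderly cohort (n = 2,272, 634-variant
creatinine panel), score it, and fit the adjustment-model ladder:

```python
from egfr_pgs import compute_pgs, phenotype_qc, run_model_ladder, summarize_pgs
from egfr_pgs.simulate import get_preset, simulate_panel, simulate_genotypes, simulate_cohort

preset = get_preset("elderly_crea")
panel  = simulate_panel(preset, seed=1)
geno   = simulate_genotypes(panel, preset.n, seed=1)
pgs    = compute_pgs(panel, geno)
print(summarize_pgs(pgs).round(1))

pheno  = simulate_cohort(preset, panel, geno, seed=1)
qc, _  = phenotype_qc(pheno, study_rules="elderly")
for fit in run_model_ladder(qc, pgs, "eGFRcrea", n_boot=200, seed=1):
    print(f"model {fit.model_id}: var(Y)={fit.outcome_variance:7.2f}  "
          f"beta={fit.beta1:+.3f} [{fit.ci95[0]:+.3f}, {fit.ci95[1]:+.3f}]  "
          f"R2={100*fit.r2:.1f}%")
```

prints

```
             mean    sd    min    max       n
weighted    603.3  14.0  548.4  647.8  2272.0
unweighted  609.5  14.4  550.0  652.9  2272.0
model 1: var(Y)= 225.60  beta=-0.218 [-0.262, -0.175]  R2=4.1%
model 2: var(Y)= 216.13  beta=-0.221 [-0.263, -0.179]  R2=4.4%
model 3: var(Y)= 210.37  beta=-0.220 [-0.262, -0.179]  R2=4.5%
model 4: var(Y)= 195.25  beta=-0.217 [-0.257, -0.177]  R2=4.7%
```

The weighted PGS has SD ≈ 14 alleles of average effect; one PGS unit
costs ≈ 0.22 mL/min/1.73 m² of eGFR; the PGS explains ≈ 4-5% of the
age-/sex-adjusted residual variance; adding BMI, diabetes/hypertension,
and CAD/diuretics shrinks the residual eGFR variance (comorbidity
burden) without moving β — the elderly pattern.

The full two-cohort comparison, including the Mann-Whitney distribution
test, the allele-frequency screen with binomial enrichment summaries,
and a sensitivity rerun excluding the planted APOE-like variant:

```sh
egfr-pgs run --seed 1 --out results/full      # full scale (~5 s)
egfr-pgs run --seed 1 --toy --out results/toy # 200 individuals, 50 variants
```

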