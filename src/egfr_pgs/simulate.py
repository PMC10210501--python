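"""Calibrated synthetic two-cohort genotype-phenotype generator.

The generator emulates the study conditions of a two-cohort PGS
comparison of kidney function: a general-adult cohort (n = 2,900, age
24-69) and an elderly cohort (n = 2,272, age 70-95), scored on a
634-variant creatinine panel or a 204-variant cystatin panel.  Every
preset is calibrated so that the published headline quantities are
recoverable by the downstream analysis:

* the weighted PGS standard deviation (13.3 / 14.0 PGS units for the
  creatinine panel in general adults / elderly; 8.4 / 8.5 for cystatin),
* the age-/sex-adjusted residual eGFR variance (157.65 / 228.93 and
  186.38 / 234.68 (mL/min/1.73 m²)²),
* the model-1 explained variance of the PGS (9.6% / 4.6% and
  4.7% / 3.6%).

The PGS effect is derived from the explained-variance target rather than
from a rounded printed coefficient:

    beta_PGS = -sqrt(target_r2 * target_outcome_variance / Var(PGS)),

with Var(PGS) the realized variance of the weighted score in the
simulated genotypes, and the noise scale set so the age-/sex-adjusted
residual variance matches its target:

    sigma_eps^2 = target_outcome_variance * (1 - target_r2) - v_c,

where v_c is the age-/sex-orthogonal variance contributed by the
comorbidity effects.  This makes both published ladder quantities
(beta and R^2) recoverable within rounding.

Genotypes are drawn from Hardy-Weinberg proportions per variant;
imputation is emulated by Gaussian dosage noise scaled so the squared
dosage-genotype correlation approximates the requested r².  Serum
creatinine and cystatin C are emitted by inverting the CKD-EPI
equations, so the biomarker -> equation -> analysis round trip is
exercised end to end.  All randomness flows from one master seed through
named substreams (panel, genotypes, covariates, noise).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import expit

from .ckdepi import invert_egfr
from .dosage import DosageMatrix
from .pgs import compute_pgs
from .scoring import ScoringFile, VariantWeight, TRAIT_CREA, TRAIT_CYS

_SUBSTREAMS = ("panel", "genotypes", "covariates", "noise")
_MIN_EGFR = 1.0          # latent eGFR floor; draws below are redrawn
_BASES = np.array(["A", "C", "G", "T"])


class SimulationError(ValueError):
    pass


def substreams(seed) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one master seed."""
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, children)}


@dataclass(frozen=True)
class SyntheticPreset:
    """Study conditions for one simulated cohort/trait combination."""

    name: str
    study: str                       # general_adults | elderly
    trait: str                       # eGFRcrea | eGFRcys
    n: int
    age_range: tuple[float, float]
    female_fraction: float
    m_variants: int
    mean_egfr: float                 # mL/min/1.73 m²
    age_beta: float                  # mL/min/1.73 m² per year
    target_pgs_sd: float             # PGS units (alleles of average effect)
    target_outcome_variance: float   # (mL/min/1.73 m²)²
    target_r2: float
    sex_beta: float = -1.0           # female vs male shift
    freq_range: tuple[float, float] = (0.01, 0.99)
    weight_jitter_sd: float = 0.25   # lognormal spread of the weights
    mean_weight: float = 0.005       # mL/min/1.73 m² per allele
    bmi_mean: float = 27.0
    bmi_sd: float = 4.6
    education_mean: float = 12.0
    education_sd: float = 3.0
    smoking_fractions: tuple[float, float, float] = (0.45, 0.35, 0.20)
    comorbidity_prevalence: dict = field(default_factory=dict)
    comorbidity_effects: dict = field(default_factory=dict)
    bmi_effect: float = 0.0          # mL/min/1.73 m² per kg/m²
    age_logodds_slope: float = 0.08  # comorbidity log-odds per year of age
    imputation_r2: float = 0.97
    cystatin_invalid_fraction: float = 0.0

    def replace(self, **overrides) -> "SyntheticPreset":
        return dataclasses.replace(self, **overrides)


def _general(trait, mean_egfr, age_beta, pgs_sd, var_out, r2, bmi_effect,
             effects):
    return SyntheticPreset(
        name=f"general_adults_{'crea' if trait == TRAIT_CREA else 'cys'}",
        study="general_adults", trait=trait, n=2900, age_range=(24.0, 69.0),
        female_fraction=0.528,
        m_variants=634 if trait == TRAIT_CREA else 204,
        mean_egfr=mean_egfr, age_beta=age_beta,
        target_pgs_sd=pgs_sd, target_outcome_variance=var_out, target_r2=r2,
        bmi_mean=26.8, bmi_sd=4.7, education_mean=11.79, education_sd=2.64,
        smoking_fractions=(0.411, 0.317, 0.272),
        comorbidity_prevalence={"diabetes": 0.031, "hypertension": 0.320,
                                "cad": 0.017, "high_ceiling_diuretics": 0.013},
        comorbidity_effects=effects, bmi_effect=bmi_effect)


def _elderly(trait, mean_egfr, age_beta, pgs_sd, var_out, r2, bmi_effect,
             effects):
    return SyntheticPreset(
        name=f"elderly_{'crea' if trait == TRAIT_CREA else 'cys'}",
        study="elderly", trait=trait, n=2272, age_range=(70.0, 95.0),
        female_fraction=0.515,
        m_variants=634 if trait == TRAIT_CREA else 204,
        mean_egfr=mean_egfr, age_beta=age_beta,
        target_pgs_sd=pgs_sd, target_outcome_variance=var_out, target_r2=r2,
        bmi_mean=27.7, bmi_sd=4.5, education_mean=12.3, education_sd=3.4,
        smoking_fractions=(0.555, 0.392, 0.053),
        comorbidity_prevalence={"diabetes": 0.209, "hypertension": 0.727,
                                "cad": 0.155, "high_ceiling_diuretics": 0.128},
        comorbidity_effects=effects, bmi_effect=bmi_effect)


#: calibrated study presets (cohort sizes, age ranges, prevalences and the
#: PGS / outcome-variance / R² targets the generator reproduces)
PRESETS: dict[str, SyntheticPreset] = {
    "general_adults_crea": _general(
        TRAIT_CREA, mean_egfr=95.3, age_beta=-0.70, pgs_sd=13.3,
        var_out=157.65, r2=0.096, bmi_effect=-0.15,
        effects={"diabetes": -2.0, "hypertension": -0.7, "cad": -2.0,
                 "high_ceiling_diuretics": -6.0}),
    "general_adults_cys": _general(
        TRAIT_CYS, mean_egfr=99.2, age_beta=-0.91, pgs_sd=8.4,
        var_out=186.38, r2=0.047, bmi_effect=-0.63,
        effects={"diabetes": -2.4, "hypertension": -0.7, "cad": -3.0,
                 "high_ceiling_diuretics": -10.0}),
    "elderly_crea": _elderly(
        TRAIT_CREA, mean_egfr=67.7, age_beta=-0.70, pgs_sd=14.0,
        var_out=228.93, r2=0.046, bmi_effect=-0.71,
        effects={"diabetes": -4.5, "hypertension": -3.2, "cad": -5.0,
                 "high_ceiling_diuretics": -10.0}),
    "elderly_cys": _elderly(
        TRAIT_CYS, mean_egfr=60.9, age_beta=-0.96, pgs_sd=8.5,
        var_out=234.68, r2=0.036, bmi_effect=-0.96,
        effects={"diabetes": -4.0, "hypertension": -2.7, "cad": -5.0,
                 "high_ceiling_diuretics": -12.0}),
}


def get_preset(name: str, **overrides) -> SyntheticPreset:
    """Fetch a preset, optionally overriding fields.

    When ``m_variants`` is overridden without an explicit
    ``target_pgs_sd``, the SD target is rescaled by sqrt(m_new / m_old):
    the score variance grows linearly with the number of independent
    variants, so down-scaled panels keep a proportionate target.
    """
    if name not in PRESETS:
        raise SimulationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[name]
    if "m_variants" in overrides and "target_pgs_sd" not in overrides:
        scale = np.sqrt(overrides["m_variants"] / preset.m_variants)
        overrides["target_pgs_sd"] = preset.target_pgs_sd * scale
    return preset.replace(**overrides) if overrides else preset


# ---------------------------------------------------------------- panel


def _dosage_variance(freqs: np.ndarray, r2) -> np.ndarray:
    """Exact per-variant variance of the clipped noisy dosage.

    The dosage is clip(g + sigma * Z, 0, 2) with g ~ Binomial(2, f) and
    sigma chosen so corr²(dosage, genotype) ~ r² before clipping.
    Clipping censors the Gaussian noise at the boundaries, which shrinks
    the variance noticeably for extreme frequencies; the censored-normal
    moments give the variance in closed form, so weight calibration can
    target the variance the analysis will actually see.
    """
    from scipy.stats import norm

    f = np.asarray(freqs, dtype=float)
    v = 2.0 * f * (1.0 - f)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), f.shape)
    sigma = np.sqrt(v * (1.0 - r2) / r2)
    exact = sigma == 0
    sigma_safe = np.where(exact, 1.0, sigma)

    probs = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])  # g = 0,1,2
    g = np.array([0.0, 1.0, 2.0])[:, None]
    alpha = (0.0 - g) / sigma_safe
    beta = (2.0 - g) / sigma_safe
    phi_a, phi_b = norm.pdf(alpha), norm.pdf(beta)
    cdf_a, cdf_b = norm.cdf(alpha), norm.cdf(beta)
    mid = cdf_b - cdf_a
    ez = phi_a - phi_b                       # E[Z; alpha < Z < beta]
    ez2 = mid + alpha * phi_a - beta * phi_b
    mean = (0.0 * cdf_a + 2.0 * (1.0 - cdf_b)
            + g * mid + sigma_safe * ez)
    second = (0.0 * cdf_a + 4.0 * (1.0 - cdf_b)
              + g ** 2 * mid + 2.0 * g * sigma_safe * ez
              + sigma_safe ** 2 * ez2)
    var = (probs * second).sum(axis=0) - ((probs * mean).sum(axis=0)) ** 2
    return np.where(exact, v, var)


def _calibrated_weights(freqs: np.ndarray, jitter: np.ndarray,
                        target_sd: float, mean_weight: float,
                        imputation_r2) -> np.ndarray:
    """Weights whose expected weighted-PGS variance hits the target.

    The weighted-score variance sum_j (w_j / w_bar)^2 * Var(d_j)
    is invariant to the overall weight scale, so the calibration knob is
    the coupling between effect size and allele frequency: weights are
    w_j ~ v_j^(-gamma) * exp(jitter_j) with v_j = 2 f_j (1 - f_j), and
    gamma is solved so the expected SD equals ``target_sd``.  gamma = 0
    gives frequency-independent weights; larger gamma concentrates
    weight on rare alleles, lowering the score variance.
    """
    v = 2.0 * freqs * (1.0 - freqs)
    if np.any(v <= 0):
        raise SimulationError("panel frequencies must lie strictly in (0,1)")
    var_d = _dosage_variance(freqs, imputation_r2)

    def expected_var(gamma: float) -> float:
        w = v ** (-gamma) * np.exp(jitter)
        return float(np.sum((w / w.mean()) ** 2 * var_d))

    target = target_sd ** 2
    # expected_var is U-shaped in gamma: solve on the decreasing branch
    # left of the minimizer
    opt = minimize_scalar(expected_var, bounds=(-2.0, 3.0),
                          method="bounded")
    lo, hi = -2.0, float(opt.x)
    if expected_var(lo) < target:
        raise SimulationError(
            f"target PGS SD {target_sd} too large for this panel "
            f"(attainable SD <= {np.sqrt(expected_var(lo)):.2f})")
    if expected_var(hi) > target:
        # small panels may not reach a low target: fall back to the
        # minimum-variance coupling
        warnings.warn(
            f"target PGS SD {target_sd:.2f} below the attainable minimum "
            f"{np.sqrt(expected_var(hi)):.2f} for this panel; using the "
            "minimum-variance frequency coupling", stacklevel=3)
        gamma = hi
    else:
        gamma = brentq(lambda g: expected_var(g) - target, lo, hi,
                       xtol=1e-10)
    w = v ** (-gamma) * np.exp(jitter)
    return w * (mean_weight / w.mean())


def simulate_panel(preset: SyntheticPreset, seed) -> ScoringFile:
    """Simulate a variant panel (scoring file) for one preset.

    Frequencies are Uniform over ``preset.freq_range``; weights are
    positive with a frequency coupling calibrated so the HWE-expected
    weighted PGS SD equals ``preset.target_pgs_sd``.  Deterministic under
    the seed.
    """
    if preset.m_variants < 1:
        raise SimulationError("m_variants must be >= 1")
    lo, hi = preset.freq_range
    if not (0.0 < lo < hi < 1.0):
        raise SimulationError(f"invalid freq_range {preset.freq_range}")
    rng = substreams(seed)["panel"]
    m = preset.m_variants
    freqs = rng.uniform(lo, hi, m)
    jitter = rng.normal(0.0, preset.weight_jitter_sd, m)
    weights = _calibrated_weights(freqs, jitter, preset.target_pgs_sd,
                                  preset.mean_weight, preset.imputation_r2)
    allele_idx = rng.integers(0, 4, m)
    other_offset = rng.integers(1, 4, m)
    effect = _BASES[allele_idx]
    other = _BASES[(allele_idx + other_offset) % 4]
    variants = [VariantWeight(
        variant_id=f"rs{1000001 + i}",
        chromosome=str(i % 22 + 1),
        position=1_000_000 + 1_000 * i,
        effect_allele=str(effect[i]),
        other_allele=str(other[i]),
        weight=float(weights[i]),
        effect_allele_freq=float(freqs[i]),
        imputation_r2=float(preset.imputation_r2),
    ) for i in range(m)]
    return ScoringFile(trait_label=preset.trait, variants=variants)


# ------------------------------------------------------------ genotypes


def simulate_genotypes(panel: ScoringFile, n: int,
                       imputation_r2: float | np.ndarray | None = None,
                       seed=0,
                       freq_overrides: dict[str, float] | None = None
                       ) -> DosageMatrix:
    """Hardy-Weinberg genotypes with imputation-style dosage noise.

    Hard genotypes are Binomial(2, f_j) per variant; dosages add Gaussian
    noise scaled so corr²(dosage, genotype) ~ ``imputation_r2`` and are
    clipped to [0, 2].  ``imputation_r2 = 1`` yields exact integers.
    ``freq_overrides`` replaces per-variant frequencies (e.g. to plant a
    cohort-specific frequency gap).
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    m = len(panel)
    freqs = np.array([v.effect_allele_freq for v in panel.variants],
                     dtype=float)
    if freq_overrides:
        ids = panel.variant_ids
        for vid, f in freq_overrides.items():
            if vid not in ids:
                raise SimulationError(f"freq override for unknown variant "
                                      f"{vid!r}")
            if not (0.0 <= f <= 1.0):
                raise SimulationError(f"frequency override outside [0,1]: {f}")
            freqs[ids.index(vid)] = f
    if imputation_r2 is None:
        imputation_r2 = np.array(
            [1.0 if v.imputation_r2 is None else v.imputation_r2
             for v in panel.variants])
    r2 = np.broadcast_to(np.asarray(imputation_r2, dtype=float), (m,)).copy()
    if np.any((r2 <= 0) | (r2 > 1)):
        raise SimulationError("imputation_r2 must lie in (0, 1]")

    rng = substreams(seed)["genotypes"]
    geno = rng.binomial(2, freqs, size=(n, m)).astype(float)
    noisy = r2 < 1.0
    if noisy.any():
        v = 2.0 * freqs * (1.0 - freqs)
        scale = np.zeros(m)
        scale[noisy] = np.sqrt(v[noisy] * (1.0 - r2[noisy]) / r2[noisy])
        geno = np.clip(geno + rng.standard_normal((n, m)) * scale, 0.0, 2.0)

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    dosages = pd.DataFrame(geno, index=pd.Index(sample_ids, name="sample_id"),
                           columns=panel.variant_ids)
    alleles = pd.DataFrame(
        {"counted": [v.effect_allele for v in panel.variants],
         "other": [v.other_allele for v in panel.variants]},
        index=pd.Index(panel.variant_ids, name="variant_id"))
    return DosageMatrix(dosages=dosages, alleles=alleles)


# -------------------------------------------------------------- cohort


def _solve_prevalence_intercept(age_centered: np.ndarray, slope: float,
                                prevalence: float) -> float:
    if prevalence <= 0.0:
        return -np.inf
    if prevalence >= 1.0:
        return np.inf
    def mean_prob(b0):
        return float(np.mean(expit(b0 + slope * age_centered))) - prevalence
    return brentq(mean_prob, -30.0, 30.0, xtol=1e-10)


def _residual_variance_on_age_sex(values, age, female) -> float:
    X = np.column_stack([np.ones(len(values)), age, female])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    return float(resid @ resid / (len(values) - 1))


def simulate_cohort(preset: SyntheticPreset, panel: ScoringFile,
                    genotypes: DosageMatrix, seed=0) -> pd.DataFrame:
    """Simulate the phenotype table for one cohort.

    The latent eGFR is a linear model in age, sex, comorbidities and the
    centred weighted PGS plus Gaussian noise; the PGS coefficient and the
    noise scale are calibrated from the preset targets (see module
    docstring).  The trait biomarker is obtained by closed-form inversion
    of the matching CKD-EPI equation; the other biomarker is emitted from
    a perturbed copy of the latent eGFR for table completeness only.
    """
    rngs = substreams(seed)
    rng_cov, rng_noise = rngs["covariates"], rngs["noise"]
    n = genotypes.shape[0]

    age = rng_cov.uniform(*preset.age_range, n)
    female = rng_cov.random(n) < preset.female_fraction
    bmi = rng_cov.normal(preset.bmi_mean, preset.bmi_sd, n)
    education = np.clip(
        rng_cov.normal(preset.education_mean, preset.education_sd, n), 4, None)
    smoking = rng_cov.choice(["never", "former", "current"], size=n,
                             p=np.asarray(preset.smoking_fractions)
                             / np.sum(preset.smoking_fractions))
    pcs = rng_cov.standard_normal((n, 10))

    age_centered = age - age.mean()
    flags: dict[str, np.ndarray] = {}
    for name, prevalence in preset.comorbidity_prevalence.items():
        b0 = _solve_prevalence_intercept(age_centered,
                                         preset.age_logodds_slope, prevalence)
        prob = expit(b0 + preset.age_logodds_slope * age_centered)
        flags[name] = (rng_cov.random(n) < prob).astype(int)

    pgs = compute_pgs(panel, genotypes)
    weighted = pgs.weighted.to_numpy()
    var_pgs = weighted.var(ddof=1)
    if preset.target_r2 > 0:
        beta_pgs = -np.sqrt(preset.target_r2 * preset.target_outcome_variance
                            / var_pgs)
    else:
        beta_pgs = 0.0

    comorbidity = np.zeros(n)
    for name, effect in preset.comorbidity_effects.items():
        if name in flags:
            comorbidity = comorbidity + effect * flags[name]
    comorbidity = comorbidity + preset.bmi_effect * (bmi - preset.bmi_mean)
    v_c = _residual_variance_on_age_sex(comorbidity, age,
                                        female.astype(float)) \
        if np.std(comorbidity) > 0 else 0.0

    sigma2 = preset.target_outcome_variance * (1.0 - preset.target_r2) - v_c
    if sigma2 <= 0:
        raise SimulationError(
            "comorbidity effects exceed the residual-variance budget; "
            f"sigma_eps^2 = {sigma2:.2f} <= 0")

    eps = rng_noise.normal(0.0, np.sqrt(sigma2), n)
    base = (preset.mean_egfr
            + preset.age_beta * age_centered
            + preset.sex_beta * (female - female.mean())
            + (comorbidity - comorbidity.mean())
            + beta_pgs * (weighted - weighted.mean()))
    latent = base + eps
    for _ in range(100):
        low = latent <= _MIN_EGFR
        if not low.any():
            break
        eps[low] = rng_noise.normal(0.0, np.sqrt(sigma2), int(low.sum()))
        latent = base + eps
    else:
        raise SimulationError("could not draw positive latent eGFR after "
                              "100 redraw rounds")

    sex = np.where(female, "F", "M")
    if preset.trait == TRAIT_CREA:
        creatinine = invert_egfr(latent, age, sex, equation="crea2009")
        other = np.clip(latent + rng_noise.normal(0.0, 6.0, n),
                        _MIN_EGFR, None)
        cystatin = invert_egfr(other, age, sex, equation="cys2012")
    else:
        cystatin = invert_egfr(latent, age, sex, equation="cys2012")
        other = np.clip(latent + rng_noise.normal(0.0, 6.0, n),
                        _MIN_EGFR, None)
        creatinine = invert_egfr(other, age, sex, equation="crea2009")

    validity = np.ones(n, dtype=int)
    if preset.cystatin_invalid_fraction > 0:
        bad = rng_noise.random(n) < preset.cystatin_invalid_fraction
        validity[bad] = rng_noise.integers(2, 5, int(bad.sum()))

    table = pd.DataFrame({
        "sample_id": genotypes.sample_ids,
        "age": age,
        "sex": sex,
        "creatinine": creatinine,
        "cystatin": cystatin,
        "cystatin_validity": validity,
        "bmi": bmi,
        "diabetes": flags.get("diabetes", np.zeros(n, dtype=int)),
        "hypertension": flags.get("hypertension", np.zeros(n, dtype=int)),
        "cad": flags.get("cad", np.zeros(n, dtype=int)),
        "high_ceiling_diuretics": flags.get("high_ceiling_diuretics",
                                            np.zeros(n, dtype=int)),
        "smoking": smoking,
        "education_years": education,
    })
    for i in range(10):
        table[f"pc{i + 1}"] = pcs[:, i]
    table["study"] = preset.study
    return table


# -------------------------------------------------------------- fixtures


def write_fixtures(panel: ScoringFile, genotypes: DosageMatrix,
                   phenotypes: pd.DataFrame, out_dir,
                   preset: SyntheticPreset | None = None,
                   seed=None) -> dict[str, str]:
    """Write the fixture bundle (scoring, dosage and phenotype TSVs plus
    a JSON manifest recording the preset and seed).  Re-reading the files
    reproduces the in-memory objects exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scoring": str(out / "scoring.tsv"),
        "dosages": str(out / "dosages.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    panel.write(paths["scoring"])
    genotypes.write_tsv(paths["dosages"])
    phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False,
                      na_rep="NA", float_format="%.17g")
    manifest = {
        "seed": seed,
        "preset": None if preset is None else dataclasses.asdict(preset),
        "n_samples": genotypes.shape[0],
        "m_variants": genotypes.shape[1],
        "files": {k: Path(v).name for k, v in paths.items()
                  if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
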