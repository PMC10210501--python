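"""Residualization, the PGS model, R² decomposition, screens, profiles,
and the Mann-Whitney comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from egfr_pgs.association import (AssociationError, compare_distributions,
                                  covariate_screen, decompose_r2,
                                  fit_pgs_model, residualize,
                                  run_model_ladder,
                                  stepwise_variance_profile)
from egfr_pgs.pgs import PgsVector
from egfr_pgs.phenotypes import phenotype_qc
from egfr_pgs.simulate import (get_preset, simulate_cohort,
                               simulate_genotypes, simulate_panel)
from egfr_pgs.pgs import compute_pgs


# ------------------------------------------------------------ residualize

def test_residualize_empty_design_centers():
    y = np.array([1.0, 2.0, 6.0])
    assert np.allclose(residualize(y, None), y - 3.0)


def test_residualize_exact_fit_gives_zero_residuals():
    age = np.array([30.0, 40.0, 50.0, 60.0, 70.0, 80.0])
    y = 3.0 * age + 1.0
    resid = residualize(y, pd.DataFrame({"age": age}))
    assert np.max(np.abs(resid)) < 1e-10


def test_residualize_matches_normal_equations_oracle(rng):
    """Six-point fixture checked against an explicit normal-equations
    solve, an independent route to the same least-squares problem."""
    X_cov = pd.DataFrame({"a": rng.normal(size=6), "b": rng.normal(size=6)})
    y = rng.normal(size=6)
    X = np.column_stack([np.ones(6), X_cov.to_numpy()])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(residualize(y, X_cov), y - X @ beta, atol=1e-10)


def test_residual_orthogonality(rng):
    n = 200
    cov = pd.DataFrame(rng.normal(size=(n, 4)),
                       columns=["age", "c1", "c2", "c3"])
    y = rng.normal(size=n)
    resid = residualize(y, cov)
    for col in cov.columns:
        assert abs(resid @ cov[col].to_numpy()) < 1e-8 * n
    assert abs(resid.sum()) < 1e-8 * n


def test_collinear_design_names_columns(rng):
    age = rng.normal(size=30)
    cov = pd.DataFrame({"age": age, "age_twice": 2 * age})
    with pytest.raises(AssociationError, match="age_twice"):
        residualize(rng.normal(size=30), cov)


# --------------------------------------------------------- fit_pgs_model

def test_fit_exact_linear_relation():
    x = np.linspace(600, 650, 20)
    y = 2.0 - 0.5 * x
    fit = fit_pgs_model(y, x, n_boot=0)
    assert fit.beta1 == pytest.approx(-0.5, rel=1e-10)
    assert fit.r2 == pytest.approx(1.0, rel=1e-10)
    assert fit.pvalue < 1e-100


def test_fit_hand_ols_oracle():
    # x = 0..4, y = (1,0,2,1,3): beta = Sxy/Sxx = 5/10, R2 = 2.5/5.2
    fit = fit_pgs_model(np.array([1.0, 0, 2, 1, 3]),
                        np.array([0.0, 1, 2, 3, 4]), n_boot=0)
    assert fit.beta1 == pytest.approx(0.5, rel=1e-12)
    assert fit.r2 == pytest.approx(2.5 / 5.2, rel=1e-12)


def test_decomposition_identity_on_random_fits(rng):
    """R² = beta1² s²(PGS) / s²(y) holds to 1e-10 on arbitrary fits."""
    for _ in range(20):
        n = int(rng.integers(10, 200))
        x = rng.normal(600, 13, n)
        y = rng.normal(0, 12, n) - 0.3 * x
        fit = fit_pgs_model(y, x, n_boot=0)
        lhs = fit.r2
        rhs = decompose_r2(fit.beta1, np.var(x, ddof=1), np.var(y, ddof=1))
        assert abs(lhs - rhs) < 1e-10


def test_constant_pgs_is_degenerate():
    with pytest.raises(AssociationError, match="constant"):
        fit_pgs_model(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]), n_boot=0)


def test_bootstrap_ci_brackets_r2(rng):
    n = 400
    x = rng.normal(0, 1, n)
    y = 0.5 * x + rng.normal(0, 1, n)
    fit = fit_pgs_model(y, x, n_boot=500, seed=1)
    lo, hi = fit.r2_ci95
    assert lo < fit.r2 < hi
    # same seed reproduces the interval
    again = fit_pgs_model(y, x, n_boot=500, seed=1)
    assert again.r2_ci95 == fit.r2_ci95


def test_ci_coverage_of_beta(rng):
    """Normal-theory 95% CI covers the simulation truth ~95% of the time."""
    beta_true, hits, reps = -0.3, 0, 500
    for _ in range(reps):
        x = rng.normal(600, 10, 120)
        y = beta_true * x + rng.normal(0, 8, 120)
        fit = fit_pgs_model(y, x, n_boot=0)
        hits += fit.ci95[0] <= beta_true <= fit.ci95[1]
    # binomial 99.9% band around 0.95 for 500 replicates
    assert 0.95 * reps - 3.3 * np.sqrt(reps * 0.95 * 0.05) <= hits \
        <= 0.95 * reps + 3.3 * np.sqrt(reps * 0.95 * 0.05)


def test_decompose_r2_edges():
    assert decompose_r2(0.0, 100.0, 50.0) == 0.0
    assert decompose_r2(1.0, 7.0, 7.0) == 1.0
    # printed-table arithmetic: beta -0.23, SD(PGS) 14.0, var 228.93
    assert decompose_r2(-0.23, 14.0 ** 2, 228.93) == pytest.approx(
        0.0453, abs=5e-4)
    with pytest.raises(AssociationError):
        decompose_r2(1.0, 1.0, 0.0)


# ------------------------------------------------------------- the ladder

def _cohort(preset_name, study, seed=3, **overrides):
    preset = get_preset(preset_name, **overrides)
    panel = simulate_panel(preset, seed)
    geno = simulate_genotypes(panel, preset.n, seed=seed)
    pgs = compute_pgs(panel, geno)
    pheno = simulate_cohort(preset, panel, geno, seed=seed)
    qc, _ = phenotype_qc(pheno, study_rules=study)
    return preset, qc, pgs


def test_ladder_structure_and_null_covariates():
    preset, qc, pgs = _cohort("general_adults_crea", "general_adults",
                              n=600, m_variants=60,
                              comorbidity_effects={}, bmi_effect=0.0)
    fits = run_model_ladder(qc, pgs, "eGFRcrea", n_boot=0)
    assert [f.model_id for f in fits] == [1, 2, 3, 4]
    # with zero comorbidity effects the outcome variance is stable and
    # beta barely moves across models
    variances = [f.outcome_variance for f in fits]
    assert max(variances) - min(variances) < 0.02 * variances[0]
    betas = [f.beta1 for f in fits]
    assert max(betas) - min(betas) < 0.02


def test_ladder_bmi_effect_reduces_model2_variance():
    preset, qc, pgs = _cohort("elderly_crea", "elderly", n=1500,
                              m_variants=60)
    fits = run_model_ladder(qc, pgs, "eGFRcrea", n_boot=0)
    assert fits[1].outcome_variance < fits[0].outcome_variance
    assert fits[3].outcome_variance < fits[1].outcome_variance


def test_missing_covariate_is_named():
    _, qc, pgs = _cohort("general_adults_crea", "general_adults",
                         n=200, m_variants=20)
    with pytest.raises(AssociationError, match="bmi"):
        run_model_ladder(qc.drop(columns=["bmi"]), pgs, "eGFRcrea",
                         n_boot=0)


# ------------------------------------------------------ screen & profile

def test_covariate_screen_analytic_r2(rng):
    """eGFR = 5*BMI + noise: R² ~ 25 Var(BMI) / Var(eGFR)."""
    n = 4000
    bmi = rng.normal(27, 4.5, n)
    noise = rng.normal(0, 40, n)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "age": rng.uniform(24, 69, n), "sex": rng.choice(["F", "M"], n),
        "bmi": bmi, "diabetes": 0, "hypertension": 0, "cad": 0,
        "high_ceiling_diuretics": 0,
        "smoking": rng.choice(["never", "former", "current"], n),
        "education_years": rng.normal(12, 3, n),
        "egfr_crea": 5 * bmi + noise + 60.0})
    with pytest.warns(UserWarning):        # constant flags are skipped
        screen = covariate_screen(df, "eGFRcrea")
    row = screen.set_index("covariable").loc["bmi"]
    y = df["egfr_crea"]
    expected = 25 * bmi.var(ddof=1) / y.var(ddof=1)
    assert row["r2"] == pytest.approx(expected, rel=0.05)
    assert row["beta"] == pytest.approx(5.0, abs=0.5)


def test_screen_age_dominates_in_general_adult_preset():
    _, qc, _ = _cohort("general_adults_crea", "general_adults",
                       n=1500, m_variants=40)
    screen = covariate_screen(qc, "eGFRcrea").set_index("covariable")
    assert screen.loc["age", "r2"] > screen.loc["education_years", "r2"]
    assert screen.loc["age", "r2"] > 0.2          # ~34% in the calibration


def test_variance_profile_monotone_and_pgs_last():
    _, qc, pgs = _cohort("elderly_crea", "elderly", n=1000, m_variants=50)
    profile = stepwise_variance_profile(qc, pgs, "eGFRcrea")
    values = profile["residual_variance"].to_numpy()
    assert np.all(np.diff(values) <= 1e-9)
    assert profile["added_covariate"].iloc[-1] == "pgs"
    # the PGS step removes ~R2 of the preceding residual variance
    drop = values[-2] - values[-1]
    assert drop > 0


# ----------------------------------------------------------- Mann-Whitney

def _mw_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all arrangements."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_stat(x, y)
    n_extreme = 0
    combos = list(itertools.combinations(range(len(pooled)), n1))
    us = []
    for idx in combos:
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        us.append(_u_stat(pooled[mask], pooled[~mask]))
    us = np.array(us)
    mean_u = n1 * (len(pooled) - n1) / 2
    n_extreme = np.sum(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return n_extreme / len(combos)


def _u_stat(x, y):
    return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)


def test_mw_textbook_example():
    u, p = compare_distributions([1.0, 2.0], [3.0, 4.0])
    assert u == 0.0
    assert p == pytest.approx(1 / 3, rel=1e-12)


def test_mw_identical_samples():
    x = np.arange(30, dtype=float)
    _, p = compare_distributions(x, x)
    assert p == pytest.approx(1.0)


def test_mw_matches_enumeration_small_layouts(rng):
    """The implemented test equals full enumeration for every two-sample
    layout with n1 + n2 <= 8 (distinct values)."""
    for n1, n2 in [(2, 2), (2, 3), (3, 3), (2, 6), (3, 5), (4, 4)]:
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            _, p_impl = compare_distributions(x, y)
            assert p_impl == pytest.approx(_mw_enumeration(x, y), rel=1e-9)


def test_mw_exact_close_to_normal_at_moderate_n(rng):
    x = rng.uniform(size=50)
    y = rng.uniform(size=50)
    from scipy.stats import mannwhitneyu
    p_asym = mannwhitneyu(x, y, alternative="two-sided",
                          method="asymptotic").pvalue
    p_exact = mannwhitneyu(x, y, alternative="two-sided",
                           method="exact").pvalue
    assert abs(p_asym - p_exact) < 0.02


def test_mw_empty_sample_errors():
    with pytest.raises(AssociationError):
        compare_distributions([], [1.0])
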