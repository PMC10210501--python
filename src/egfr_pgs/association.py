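"""PGS-eGFR association: residualization, the adjustment-model ladder,
and explained-variance decomposition.

The analysis is two-stage.  Stage 1 residualizes eGFR on covariates by
ordinary least squares (age + sex + 10 genetic PCs for model 1; models
2-4 cumulatively add BMI, then diabetes + hypertension, then CAD +
high-ceiling diuretics).  Stage 2 is the simple regression

    Y_i = b0 + b1 * PGS_i + e_i,

with Y the stage-1 residuals.  For a single predictor the explained
variance decomposes exactly as

    R^2 = b1^2 * Var(PGS) / Var(Y),

with the same n-1 variance convention throughout; the reported R^2 is
computed through this identity (it coincides with the OLS coefficient of
determination), so the decomposition holds to machine precision for
every fit.

The R^2 confidence interval is a seeded nonparametric pairs bootstrap
(percentile method), so it carries no distributional assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pgs import PgsVector


class AssociationError(ValueError):
    pass


#: cumulative covariate ladder (10 PCs are always added on top)
MODEL_COVARIATES = {
    1: ["age", "female"],
    2: ["age", "female", "bmi"],
    3: ["age", "female", "bmi", "diabetes", "hypertension"],
    4: ["age", "female", "bmi", "diabetes", "hypertension", "cad",
        "high_ceiling_diuretics"],
}

PC_COLUMNS = [f"pc{i}" for i in range(1, 11)]

#: covariables of the univariable screen
SCREEN_COVARIATES = ["age", "female", "bmi", "diabetes", "hypertension",
                     "cad", "high_ceiling_diuretics", "smoking",
                     "education_years"]


@dataclass
class ModelFit:
    """One row of the adjustment-model ladder output."""

    model_id: int
    trait: str
    n: int
    outcome_variance: float       # (mL/min/1.73 m²)², n-1 denominator
    beta0: float
    beta1: float                  # mL/min/1.73 m² per PGS unit
    se: float
    ci95: tuple[float, float]
    pvalue: float
    r2: float
    pgs_variance: float = float("nan")   # Var of the PGS in the fit sample
    r2_ci95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model_id, "trait": self.trait, "n": self.n,
            "outcome_variance": self.outcome_variance,
            "beta0": self.beta0, "beta": self.beta1, "se": self.se,
            "ci_low": self.ci95[0], "ci_high": self.ci95[1],
            "pvalue": self.pvalue, "pvalue_str": format_pvalue(self.pvalue),
            "r2": self.r2, "pgs_variance": self.pgs_variance,
        }
        if self.r2_ci95 is not None:
            d["r2_ci_low"], d["r2_ci_high"] = self.r2_ci95
        return d


def format_pvalue(p: float) -> str:
    """p-values below float underflow are reported as '< 1e-300'."""
    if p < 1e-300:
        return "< 1e-300"
    return f"{p:.3g}"


def _design_frame(pheno: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design columns; sex is coded as a 0/1 female indicator."""
    out = {}
    for col in columns:
        if col == "female":
            out[col] = (pheno["sex"].isin(["F", "female"])).astype(float)
        else:
            if col not in pheno.columns:
                raise AssociationError(f"missing covariate column: {col!r}")
            out[col] = pheno[col].astype(float)
    return pd.DataFrame(out, index=pheno.index)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, X.shape[1]):
        prev = X[:, :j]
        resid = X[:, j] - prev @ np.linalg.lstsq(prev, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j - 1] if j >= 1 else "intercept")
    return bad


def residualize(y, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of ``y`` on the design columns (intercept always
    included).  Residuals are orthogonal to every design column."""
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    X = np.column_stack([np.ones(len(y)), covariates.to_numpy(dtype=float)])
    if len(y) <= X.shape[1] + 1:
        raise AssociationError(
            f"n = {len(y)} too small for {X.shape[1] - 1} covariates")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, list(covariates.columns))
        raise AssociationError(f"rank-deficient design; collinear "
                               f"column(s): {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _bootstrap_r2_ci(x: np.ndarray, y: np.ndarray, n_boot: int,
                     seed) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1) ** 2
    den = (xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = num / den
    lo, hi = np.nanpercentile(r2, [2.5, 97.5])
    return float(lo), float(hi)


def fit_pgs_model(residuals, pgs, *, trait: str = "eGFRcrea",
                  model_id: int = 1, n_boot: int = 1000,
                  seed=None) -> ModelFit:
    """Stage-2 simple OLS of the adjusted residuals on the weighted PGS.

    ``pgs`` may be a :class:`~egfr_pgs.pgs.PgsVector` (its weighted score
    is used) or any 1-d array aligned with ``residuals``.  ``n_boot = 0``
    skips the bootstrap R² interval.
    """
    x = pgs.weighted.to_numpy() if isinstance(pgs, PgsVector) else \
        np.asarray(pgs, dtype=float)
    y = np.asarray(residuals, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(y)
    if n < 3:
        raise AssociationError(f"need >= 3 paired observations, got {n}")
    if np.std(x) == 0:
        raise AssociationError("degenerate predictor: PGS is constant")

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    beta0, beta1 = fit.params
    se = fit.bse[1]
    ci = fit.conf_int(alpha=0.05)[1]
    var_x = x.var(ddof=1)
    var_y = y.var(ddof=1)
    r2 = beta1 ** 2 * var_x / var_y      # single-predictor identity
    r2_ci = None
    if n_boot:
        r2_ci = _bootstrap_r2_ci(x, y, n_boot, seed)
    return ModelFit(
        model_id=model_id, trait=trait, n=n,
        outcome_variance=float(var_y), beta0=float(beta0),
        beta1=float(beta1), se=float(se),
        ci95=(float(ci[0]), float(ci[1])),
        pvalue=float(fit.pvalues[1]), r2=float(r2),
        pgs_variance=float(var_x), r2_ci95=r2_ci)


def decompose_r2(beta1: float, var_pgs: float, var_outcome: float) -> float:
    """R² = beta1² * Var(PGS) / Var(outcome)."""
    if var_outcome <= 0:
        raise AssociationError("var_outcome must be > 0")
    if var_pgs < 0:
        raise AssociationError("var_pgs must be >= 0")
    return beta1 ** 2 * var_pgs / var_outcome


def _outcome_column(trait: str) -> str:
    if trait == "eGFRcrea":
        return "egfr_crea"
    if trait == "eGFRcys":
        return "egfr_cys"
    raise AssociationError(f"unknown trait {trait!r}")


def _aligned(pheno: pd.DataFrame, pgs: PgsVector) -> pd.Series:
    s = pgs.weighted.reindex(pheno["sample_id"])
    if s.isna().all():
        raise AssociationError("no PGS values align with phenotype samples")
    return pd.Series(s.to_numpy(), index=pheno.index)


def _trait_table(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    df = pheno
    if trait == "eGFRcys" and "cys_valid" in df.columns:
        df = df[df["cys_valid"]]
    y_col = _outcome_column(trait)
    if y_col not in df.columns:
        raise AssociationError(
            f"phenotype table lacks {y_col!r}; run phenotype QC first")
    return df.dropna(subset=[y_col])


def run_model_ladder(pheno: pd.DataFrame, pgs: PgsVector, trait: str,
                     n_boot: int = 1000, seed=None) -> list[ModelFit]:
    """Fit the four-model adjustment ladder for one trait.

    Stage-1 residualization always includes the 10 genetic PCs alongside
    the model covariates; stage 2 is the simple PGS regression.
    """
    df = _trait_table(pheno, trait)
    y = df[_outcome_column(trait)].to_numpy(dtype=float)
    x = _aligned(df, pgs).to_numpy()
    fits = []
    for model_id, covs in MODEL_COVARIATES.items():
        design = _design_frame(df, covs + PC_COLUMNS)
        resid = residualize(y, design)
        fits.append(fit_pgs_model(
            resid, x, trait=trait, model_id=model_id,
            n_boot=n_boot, seed=None if seed is None else seed + model_id))
    return fits


def covariate_screen(pheno: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Univariable screen: one simple regression of raw eGFR per
    covariable.

    Smoking enters as two dummies (former, current) fitted jointly; the
    two rows share the joint model's R².  Constant covariables are
    skipped with a warning.
    """
    df = _trait_table(pheno, trait)
    y = df[_outcome_column(trait)].to_numpy(dtype=float)
    records = []
    for cov in SCREEN_COVARIATES:
        if cov == "smoking":
            dummies = pd.DataFrame({
                "smoking_former": (df["smoking"] == "former").astype(float),
                "smoking_current": (df["smoking"] == "current").astype(float),
            }, index=df.index)
            if (dummies.std() == 0).all():
                warnings.warn("covariate_screen: smoking constant; skipped",
                              stacklevel=2)
                continue
            X = sm.add_constant(dummies.to_numpy())
            fit = sm.OLS(y, X).fit()
            ci = fit.conf_int(alpha=0.05)
            for j, name in enumerate(dummies.columns, start=1):
                records.append({
                    "covariable": name, "beta": float(fit.params[j]),
                    "ci_low": float(ci[j][0]), "ci_high": float(ci[j][1]),
                    "r2": float(fit.rsquared)})
            continue
        xcol = _design_frame(df, [cov])[cov].to_numpy()
        if np.std(xcol) == 0:
            warnings.warn(f"covariate_screen: {cov!r} constant; skipped",
                          stacklevel=2)
            continue
        fit = sm.OLS(y, sm.add_constant(xcol)).fit()
        ci = fit.conf_int(alpha=0.05)[1]
        records.append({
            "covariable": cov, "beta": float(fit.params[1]),
            "ci_low": float(ci[0]), "ci_high": float(ci[1]),
            "r2": float(fit.rsquared)})
    return pd.DataFrame(records,
                        columns=["covariable", "beta", "ci_low", "ci_high",
                                 "r2"])


DEFAULT_STEPWISE_ORDER = ["age", "female", "bmi", "diabetes",
                          "hypertension", "cad", "high_ceiling_diuretics"]


def stepwise_variance_profile(pheno: pd.DataFrame, pgs: PgsVector,
                              trait: str,
                              order: list[str] | None = None) -> pd.DataFrame:
    """Residual eGFR variance after cumulatively adding each covariate,
    with the PGS added last.

    All variances use the fixed n-1 denominator, so the profile is
    non-increasing for any ordering (nested least squares).
    """
    df = _trait_table(pheno, trait)
    y = df[_outcome_column(trait)].to_numpy(dtype=float)
    x = _aligned(df, pgs).to_numpy()
    order = list(order) if order is not None else list(DEFAULT_STEPWISE_ORDER)
    n = len(y)
    steps = [("none", np.var(y, ddof=1))]
    design = pd.DataFrame(index=df.index)
    for cov in order:
        design[cov] = _design_frame(df, [cov])[cov]
        resid = residualize(y, design)
        steps.append((cov, resid @ resid / (n - 1)))
    design["pgs"] = x
    resid = residualize(y, design)
    steps.append(("pgs", resid @ resid / (n - 1)))
    return pd.DataFrame(steps, columns=["added_covariate",
                                        "residual_variance"])


def compare_distributions(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two PGS samples.

    Exact enumeration when the smaller sample has <= 8 values and there
    are no ties; tie-corrected normal approximation otherwise.  Returns
    (U of the first sample, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise AssociationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
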