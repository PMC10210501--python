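"""Cross-cohort allele-frequency comparison and enrichment tests.

Per-variant effect-allele frequencies are compared between two cohorts
on best-guess genotypes (dosages rounded half-up to {0, 1, 2}) via the
Pearson chi-square test on the 2x2 allele-count table (2N alleles per
cohort, no continuity correction by default — a documented switch turns
the Yates correction on).  Multiple testing uses Bonferroni tiers.

Two exact binomial summaries screen for systematic frequency shifts,
e.g. survival/selection effects in an elderly cohort:

* enrichment — is the number of nominally significant variants larger
  than the 5% expected under "no frequency differences"?  One-sided,
  P(X >= k) under Binomial(n, 0.05).
* direction — among the nominally significant variants, is the
  eGFR-lowering allele preferentially rarer (or more common) in one
  cohort?  Two-sided minimum-likelihood test at p0 = 0.5, matching the
  behaviour of R's ``binom.test``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dosage import DosageMatrix


class FreqCompareError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact binomial test summary."""

    k: int
    n: int
    p0: float
    alternative: str
    p_bin: float

    def to_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "p0": self.p0,
                "alternative": self.alternative, "p_bin": self.p_bin}


def best_guess_genotypes(d) -> pd.DataFrame:
    """Round dosages to hard genotypes {0, 1, 2}; halves round up.

    Missing dosages stay missing.  Accepts a :class:`DosageMatrix` or a
    plain DataFrame.
    """
    df = d.dosages if isinstance(d, DosageMatrix) else d
    values = df.to_numpy(dtype=float)
    rounded = np.floor(values + 0.5)          # half-up
    rounded = np.clip(rounded, 0.0, 2.0)
    rounded[np.isnan(values)] = np.nan
    return pd.DataFrame(rounded, index=df.index, columns=df.columns)


def _allele_counts(genos: pd.DataFrame) -> pd.DataFrame:
    """Effect-allele count and total allele count (2N) per variant."""
    k = genos.sum(axis=0, skipna=True)
    n = 2.0 * genos.notna().sum(axis=0)
    return pd.DataFrame({"k": k, "n2": n})


def pearson_chi2_2x2(table: np.ndarray, correction: bool = False
                     ) -> tuple[float, float, float]:
    """Pearson chi-square on a 2x2 table; returns (chi2, p, min expected)."""
    obs = np.asarray(table, dtype=float)
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), float(p), float(expected.min())


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise FreqCompareError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def freq_diff_test(genos_study1: pd.DataFrame, genos_study2: pd.DataFrame,
                   alpha: float = 0.05, bonferroni_m: int | None = None,
                   correction: bool = False) -> pd.DataFrame:
    """Per-variant allele-frequency difference test between two cohorts.

    ``genos_study*`` are best-guess genotype frames sharing columns.
    Returns one row per shared variant: frequencies, 2x2 chi-square
    (1 df), p_diff, a low-expected-count flag, and the significance tier
    (none / nominal / bonferroni).  Monomorphic variants (one allele
    absent in both cohorts combined) are skipped with a warning and
    reported with missing statistics.
    """
    shared = [v for v in genos_study1.columns if v in set(genos_study2.columns)]
    if not shared:
        raise FreqCompareError("no shared variants between the two cohorts")
    m = bonferroni_m if bonferroni_m is not None else len(shared)
    bonf = bonferroni_threshold(m, alpha)

    c1 = _allele_counts(genos_study1[shared])
    c2 = _allele_counts(genos_study2[shared])
    rows = []
    n_skipped = 0
    for vid in shared:
        k1, n1 = c1.loc[vid, "k"], c1.loc[vid, "n2"]
        k2, n2 = c2.loc[vid, "k"], c2.loc[vid, "n2"]
        if n1 == 0 or n2 == 0:
            raise FreqCompareError(f"{vid}: zero genotyped individuals")
        eaf1, eaf2 = k1 / n1, k2 / n2
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        if table.sum(axis=0).min() == 0:      # monomorphic overall
            n_skipped += 1
            rows.append({"variant_id": vid, "eaf_study1": eaf1,
                         "eaf_study2": eaf2, "count1": k1, "total1": n1,
                         "count2": k2, "total2": n2, "chi2": np.nan,
                         "p_diff": np.nan, "low_expected": False,
                         "tier": "none"})
            continue
        chi2, p, min_exp = pearson_chi2_2x2(table, correction=correction)
        tier = "bonferroni" if p < bonf else ("nominal" if p < alpha
                                              else "none")
        rows.append({"variant_id": vid, "eaf_study1": eaf1,
                     "eaf_study2": eaf2, "count1": k1, "total1": n1,
                     "count2": k2, "total2": n2, "chi2": chi2, "p_diff": p,
                     "low_expected": min_exp < 1.0, "tier": tier})
    if n_skipped:
        warnings.warn(f"freq_diff_test: {n_skipped} monomorphic variant(s) "
                      "skipped", stacklevel=2)
    return pd.DataFrame(rows)


def binom_enrichment(k: int, n: int, p0: float,
                     alternative: str = "greater") -> EnrichmentResult:
    """Exact binomial test.

    ``greater`` gives the upper tail P(X >= k); ``two_sided`` sums all
    outcome probabilities not exceeding the observed point probability
    (with the customary small relative tolerance on the comparison).
    """
    if not (0 <= k <= n):
        raise FreqCompareError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise FreqCompareError(f"p0 must be in (0,1), got {p0}")
    alt = {"greater": "greater", "two_sided": "two-sided",
           "two-sided": "two-sided", "less": "less"}.get(alternative)
    if alt is None:
        raise FreqCompareError(f"unknown alternative {alternative!r}")
    p = stats.binomtest(k, n, p0, alternative=alt).pvalue
    return EnrichmentResult(k=k, n=n, p0=p0, alternative=alternative,
                            p_bin=float(p))


def qq_points(pvalues) -> tuple[pd.DataFrame, int]:
    """Expected vs observed -log10(p) quantiles for a QQ plot.

    Expected quantiles are i/(m+1).  Also returns the count of p < 0.05.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise FreqCompareError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise FreqCompareError("p-values must lie in (0, 1]")
    observed = np.sort(p)
    m = p.size
    expected = np.arange(1, m + 1) / (m + 1)
    df = pd.DataFrame({
        "expected_p": expected,
        "observed_p": observed,
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(observed),
    })
    return df, int((p < 0.05).sum())


def per_variant_assoc(d: DosageMatrix | pd.DataFrame, labels,
                      age) -> pd.DataFrame:
    """Per-variant dosage association in pooled two-cohort data.

    For each variant: (a) logistic regression of study membership on the
    dosage, (b) linear regression of age on the dosage, and (c) the same
    adjusting for membership.  Wald p-values are reported for QQ
    inspection; constant-dosage variants are flagged and left missing.
    """
    df = d.dosages if isinstance(d, DosageMatrix) else d
    labels = np.asarray(labels, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(labels) != len(df) or len(age) != len(df):
        raise FreqCompareError("labels/age length must match sample count")
    if len(np.unique(labels)) < 2:
        raise FreqCompareError("both study labels must be present")

    rows = []
    for vid in df.columns:
        x = df[vid].to_numpy(dtype=float)
        mask = ~np.isnan(x)
        xv, lv, av = x[mask], labels[mask], age[mask]
        if np.std(xv) == 0:
            rows.append({"variant_id": vid, "constant": True,
                         "beta_membership": np.nan, "p_membership": np.nan,
                         "beta_age": np.nan, "p_age": np.nan,
                         "beta_age_adj": np.nan, "p_age_adj": np.nan})
            continue
        try:
            logit = sm.Logit(lv, sm.add_constant(xv)).fit(disp=False)
            beta_m, p_m = float(logit.params[1]), float(logit.pvalues[1])
        except Exception:       # separation / non-convergence
            beta_m, p_m = np.nan, np.nan
        ols_age = sm.OLS(av, sm.add_constant(xv)).fit()
        X_adj = sm.add_constant(np.column_stack([xv, lv]))
        ols_adj = sm.OLS(av, X_adj).fit()
        rows.append({
            "variant_id": vid, "constant": False,
            "beta_membership": beta_m, "p_membership": p_m,
            "beta_age": float(ols_age.params[1]),
            "p_age": float(ols_age.pvalues[1]),
            "beta_age_adj": float(ols_adj.params[1]),
            "p_age_adj": float(ols_adj.pvalues[1])})
    return pd.DataFrame(rows)
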