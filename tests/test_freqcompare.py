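"""Frequency comparison: best-guess rounding, Pearson chi-square vs a
brute-force oracle, exact binomial vs enumeration, QQ, dosage screens."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from egfr_pgs.dosage import DosageMatrix
from egfr_pgs.freqcompare import (FreqCompareError, best_guess_genotypes,
                                  binom_enrichment, bonferroni_threshold,
                                  freq_diff_test, pearson_chi2_2x2,
                                  per_variant_assoc, qq_points)


# ------------------------------------------------------------ best guess

def test_best_guess_rounding_half_up():
    df = pd.DataFrame({"v": [0.49, 0.5, 1.49, 1.5, 1.51, 2.0, np.nan]})
    bg = best_guess_genotypes(df)
    assert bg["v"].tolist()[:6] == [0.0, 1.0, 1.0, 2.0, 2.0, 2.0]
    assert np.isnan(bg["v"].iloc[6])


def test_best_guess_integers_unchanged():
    df = pd.DataFrame({"v": [0.0, 1.0, 2.0]})
    assert best_guess_genotypes(df)["v"].tolist() == [0.0, 1.0, 2.0]


# ------------------------------------------------------------ chi-square

def _chi2_oracle(table):
    """Textbook Pearson statistic sum (O - E)^2 / E."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def test_chi2_identical_tables_give_zero():
    chi2, p, _ = pearson_chi2_2x2([[30, 70], [30, 70]])
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_hand_example():
    chi2, p, _ = pearson_chi2_2x2([[30, 70], [50, 50]])
    assert chi2 == pytest.approx(25 / 3, rel=1e-9)
    assert p == pytest.approx(0.003892, abs=2e-5)


def test_chi2_doubling_counts_doubles_statistic():
    chi2_1, p1, _ = pearson_chi2_2x2([[30, 70], [50, 50]])
    chi2_2, p2, _ = pearson_chi2_2x2([[60, 140], [100, 100]])
    assert chi2_2 == pytest.approx(2 * chi2_1, rel=1e-9)
    assert p2 < p1


def test_chi2_matches_bruteforce_on_random_tables(rng):
    """Implementation equals sum (O-E)^2/E on 1,000 random 2x2 tables."""
    for _ in range(1000):
        table = rng.integers(1, 500, size=(2, 2))
        chi2, _, _ = pearson_chi2_2x2(table)
        assert chi2 == pytest.approx(_chi2_oracle(table), rel=1e-10)


def test_yates_switch_changes_statistic():
    plain, _, _ = pearson_chi2_2x2([[12, 8], [5, 15]], correction=False)
    yates, _, _ = pearson_chi2_2x2([[12, 8], [5, 15]], correction=True)
    assert yates < plain


# ------------------------------------------------------------ Bonferroni

def test_bonferroni_thresholds():
    assert bonferroni_threshold(534) == pytest.approx(9.36e-5, rel=5e-3)
    assert bonferroni_threshold(186) == pytest.approx(2.69e-4, rel=5e-3)
    assert bonferroni_threshold(1) == 0.05
    with pytest.raises(FreqCompareError):
        bonferroni_threshold(0)


# ---------------------------------------------------------- exact binomial

def _binom_enumeration(k, n, p0, alternative):
    probs = np.array([stats.binom.pmf(i, n, p0) for i in range(n + 1)])
    if alternative == "greater":
        return probs[k:].sum()
    point = probs[k]
    return probs[probs <= point * (1 + 1e-7)].sum()


def test_binom_two_sided_enumeration_value():
    res = binom_enrichment(2, 10, 0.5, "two_sided")
    assert res.p_bin == pytest.approx(112 / 1024, rel=1e-12)


def test_binom_whole_sample_space():
    assert binom_enrichment(0, 10, 0.05, "greater").p_bin == 1.0


@pytest.mark.parametrize("alternative", ["greater", "two_sided"])
def test_binom_matches_enumeration_all_small_n(alternative):
    """Exact binomial equals full enumeration for all n <= 25."""
    for n in range(1, 26):
        for k in range(0, n + 1):
            for p0 in (0.05, 0.3, 0.5):
                res = binom_enrichment(k, n, p0, alternative)
                assert res.p_bin == pytest.approx(
                    _binom_enumeration(k, n, p0, alternative), rel=1e-9), \
                    (k, n, p0, alternative)


def test_binom_invalid_inputs():
    with pytest.raises(FreqCompareError):
        binom_enrichment(5, 3, 0.5)
    with pytest.raises(FreqCompareError):
        binom_enrichment(1, 3, 0.0)
    with pytest.raises(FreqCompareError):
        binom_enrichment(1, 3, 0.5, "weird")


# -------------------------------------------------------------- QQ points

def test_qq_uniform_quantiles_on_diagonal():
    df, n_nominal = qq_points([0.25, 0.5, 0.75])
    assert df["expected_p"].tolist() == [0.25, 0.5, 0.75]
    assert df["observed_p"].tolist() == [0.25, 0.5, 0.75]
    assert n_nominal == 0


def test_qq_inflated_pvalues_sit_above_diagonal():
    df, n_nominal = qq_points([1e-6] * 5)
    assert (df["observed_neglog10"] > df["expected_neglog10"]).all()
    assert n_nominal == 5


def test_qq_null_uniform_nominal_count(rng):
    p = rng.uniform(size=534)
    _, n_nominal = qq_points(p)
    # binomial 99% band around 534 * 0.05 = 26.7
    sd = np.sqrt(534 * 0.05 * 0.95)
    assert 26.7 - 2.58 * sd <= n_nominal <= 26.7 + 2.58 * sd


def test_qq_rejects_out_of_range():
    with pytest.raises(FreqCompareError):
        qq_points([0.5, 0.0])


# ------------------------------------------------------------ freq tests

def _two_cohort_genotypes(rng, n1, n2, m, f1, f2):
    g1 = pd.DataFrame(rng.binomial(2, f1, size=(n1, m)).astype(float),
                      columns=[f"v{i}" for i in range(m)])
    g2 = pd.DataFrame(rng.binomial(2, f2, size=(n2, m)).astype(float),
                      columns=[f"v{i}" for i in range(m)])
    return g1, g2


def test_freq_diff_null_nominal_fraction(rng):
    """Equal frequencies: the nominal tier hits ~5% of 500 variants."""
    f = rng.uniform(0.1, 0.9, 500)
    g1, g2 = _two_cohort_genotypes(rng, 800, 700, 500, f, f)
    table = freq_diff_test(g1, g2)
    n_nominal = (table["tier"] != "none").sum()
    sd = np.sqrt(500 * 0.05 * 0.95)
    assert 25 - 2.58 * sd <= n_nominal <= 25 + 2.58 * sd
    assert (table["tier"] == "bonferroni").sum() == 0


def test_freq_diff_detects_planted_gap(rng):
    f = np.full(20, 0.5)
    f2 = f.copy()
    f2[0] = 0.8
    g1, g2 = _two_cohort_genotypes(rng, 1000, 1000, 20, f, f2)
    table = freq_diff_test(g1, g2).set_index("variant_id")
    assert table.loc["v0", "tier"] == "bonferroni"
    assert table.loc["v0", "eaf_study2"] > table.loc["v0", "eaf_study1"]


def test_freq_diff_tier_consistency(rng):
    f = rng.uniform(0.2, 0.8, 100)
    g1, g2 = _two_cohort_genotypes(rng, 300, 400, 100, f, f)
    table = freq_diff_test(g1, g2)
    bonf = bonferroni_threshold(100)
    for _, row in table.dropna(subset=["p_diff"]).iterrows():
        if row["tier"] == "bonferroni":
            assert row["p_diff"] < bonf
        elif row["tier"] == "nominal":
            assert bonf <= row["p_diff"] < 0.05
        else:
            assert row["p_diff"] >= 0.05


def test_freq_diff_monomorphic_skipped(rng):
    g1 = pd.DataFrame({"v0": np.zeros(50)})
    g2 = pd.DataFrame({"v0": np.zeros(60)})
    with pytest.warns(UserWarning, match="monomorphic"):
        table = freq_diff_test(g1, g2)
    assert np.isnan(table["p_diff"].iloc[0])


# ------------------------------------------------------- dosage screens

def test_per_variant_assoc_null_uniform(rng):
    m, n = 200, 400
    f = rng.uniform(0.2, 0.8, m)
    d = pd.DataFrame(rng.binomial(2, f, size=(n, m)).astype(float),
                     columns=[f"v{i}" for i in range(m)])
    labels = (np.arange(n) < n // 2).astype(float)
    age = rng.uniform(20, 90, n)
    res = per_variant_assoc(d, labels, age)
    ks = stats.kstest(res["p_membership"].dropna(), "uniform")
    assert ks.pvalue > 0.01


def test_per_variant_assoc_detects_separation(rng):
    n = 1000
    labels = (np.arange(n) < n // 2).astype(float)
    dos = np.where(labels == 0, rng.binomial(2, 0.3, n),
                   rng.binomial(2, 0.7, n)).astype(float)
    d = pd.DataFrame({"v0": dos})
    res = per_variant_assoc(d, labels, rng.uniform(20, 90, n))
    assert res["beta_membership"].iloc[0] > 0
    assert res["p_membership"].iloc[0] < 1e-6


def test_per_variant_assoc_constant_flagged(rng):
    d = pd.DataFrame({"v0": np.ones(40)})
    labels = (np.arange(40) < 20).astype(float)
    res = per_variant_assoc(d, labels, rng.uniform(20, 90, 40))
    assert bool(res["constant"].iloc[0])
    assert np.isnan(res["p_membership"].iloc[0])
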