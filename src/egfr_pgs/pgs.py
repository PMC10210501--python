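"""Polygenic-score computation in "alleles of average effect" units.

The unweighted score of individual *i* is the plain sum of effect-allele
dosages, sum_j d_ij.  The weighted score is

    (sum_j d_ij * w_j) / w_bar,   w_bar = mean of the weights,

so that one unit of the weighted score corresponds to one allele of
average effect on eGFR.  Division by the *mean* weight (rather than the
raw weighted sum) puts the weighted score on the same allele-count scale
as the unweighted one: with M ~ 634 variants both land near 2*M*f_bar.

Missing dosages are handled by per-individual renormalization: each
individual's w_bar is taken over that individual's non-missing variants,
and the number of variants used is reported per individual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import DosageMatrix
from .scoring import ScoringFile


class PgsError(ValueError):
    pass


@dataclass
class PgsVector:
    """Per-individual weighted and unweighted polygenic scores."""

    sample_ids: list[str]
    weighted: pd.Series
    unweighted: pd.Series
    n_variants_used: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "weighted": self.weighted,
            "unweighted": self.unweighted,
            "n_variants_used": self.n_variants_used,
        })


def compute_pgs(score: ScoringFile, geno: DosageMatrix) -> PgsVector:
    """Compute weighted and unweighted PGS for harmonized inputs.

    Every scoring-file variant must be a column of ``geno`` (run
    harmonization first).  Individuals with no non-missing dosage get a
    missing (NaN) score and a warning, never a silent zero.
    """
    missing_cols = [v for v in score.variant_ids if v not in geno.dosages.columns]
    if missing_cols:
        raise PgsError(
            f"dosage matrix lacks scored variants (harmonize first): "
            f"{missing_cols[:5]}")

    D = geno.dosages[score.variant_ids].to_numpy(dtype=float)
    w = score.weights
    observed = ~np.isnan(D)
    n_used = observed.sum(axis=1)

    unweighted = np.nansum(np.where(observed, D, 0.0), axis=1)
    sum_dw = np.nansum(np.where(observed, D, 0.0) * w, axis=1)
    sum_w = observed @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_w = np.where(n_used > 0, sum_w / np.maximum(n_used, 1), np.nan)
        weighted = sum_dw / mean_w

    none_used = n_used == 0
    if none_used.any():
        warnings.warn(
            f"{int(none_used.sum())} individual(s) have all dosages missing; "
            "their scores are reported as missing", stacklevel=2)
        unweighted = unweighted.astype(float)
        unweighted[none_used] = np.nan
        weighted[none_used] = np.nan

    idx = pd.Index(geno.sample_ids, name="sample_id")
    return PgsVector(
        sample_ids=list(idx),
        weighted=pd.Series(weighted, index=idx, name="weighted"),
        unweighted=pd.Series(unweighted, index=idx, name="unweighted"),
        n_variants_used=pd.Series(n_used, index=idx, name="n_variants_used"),
    )


def summarize_pgs(pgs: PgsVector) -> pd.DataFrame:
    """Mean, SD (n-1 denominator), min and max per score type."""
    rows = {}
    for name, series in (("weighted", pgs.weighted),
                         ("unweighted", pgs.unweighted)):
        values = series.dropna()
        if len(values) < 2:
            raise PgsError(
                f"summarize_pgs needs >= 2 non-missing {name} scores, "
                f"got {len(values)}")
        rows[name] = {"mean": values.mean(), "sd": values.std(ddof=1),
                      "min": values.min(), "max": values.max(),
                      "n": len(values)}
    return pd.DataFrame(rows).T[["mean", "sd", "min", "max", "n"]]
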