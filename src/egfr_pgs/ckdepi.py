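"""CKD-EPI equations for estimated glomerular filtration rate.

Implements the 2009 creatinine equation and the 2012 cystatin C equation,

    eGFR = intercept * min(B/kappa, 1)^a * max(B/kappa, 1)^b
           * age_base^age * female_factor[f] * race_factor[black],

where B is the serum biomarker (creatinine in mg/dL, cystatin C in mg/L),
kappa the sex-specific knot, a the below-knot and b the above-knot
exponent.  Both equations are strictly decreasing in the biomarker and in
age, and continuous at the knot.

The race coefficient of the 2009 equation is implemented for fidelity to
the published form but defaults to off; the race-free 2021 refits are out
of scope here because published GWAS effect sizes for eGFR were estimated
on these equations.

A closed-form piecewise inverse is provided so simulated cohorts can emit
serum concentrations that round-trip exactly through the published
equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class EgfrDomainError(ValueError):
    """Non-positive biomarker, age, or eGFR."""


@dataclass(frozen=True)
class CkdEpiParams:
    """Constants of one CKD-EPI equation."""

    equation: str
    intercept: float
    age_base: float
    female_factor: float
    race_factor: float
    knot_female: float
    knot_male: float
    alpha_female: float          # below-knot exponent
    alpha_male: float
    beta: float                  # above-knot exponent (both sexes)

    def knot(self, female) -> np.ndarray:
        return np.where(female, self.knot_female, self.knot_male)

    def alpha(self, female) -> np.ndarray:
        return np.where(female, self.alpha_female, self.alpha_male)


CREA_2009 = CkdEpiParams(
    equation="crea2009", intercept=141.0, age_base=0.993,
    female_factor=1.018, race_factor=1.159,
    knot_female=0.7, knot_male=0.9,
    alpha_female=-0.329, alpha_male=-0.411, beta=-1.209)

CYS_2012 = CkdEpiParams(
    equation="cys2012", intercept=133.0, age_base=0.996,
    female_factor=0.932, race_factor=1.0,
    knot_female=0.8, knot_male=0.8,
    alpha_female=-0.499, alpha_male=-0.499, beta=-1.328)

PARAMS = {"crea2009": CREA_2009, "cys2012": CYS_2012}


def _female_mask(sex) -> np.ndarray:
    if isinstance(sex, str):
        return np.asarray(sex in ("F", "female"))
    s = np.asarray(sex)
    if s.dtype.kind in "OUS":
        return np.isin(s, ("F", "female"))
    return s.astype(bool)


def _as_arrays(biomarker, age, sex):
    b = np.asarray(biomarker, dtype=float)
    a = np.asarray(age, dtype=float)
    female = _female_mask(sex)
    if np.any(~(b > 0)):
        raise EgfrDomainError("biomarker concentration must be > 0")
    if np.any(~(a > 0)):
        raise EgfrDomainError("age must be > 0")
    return b, a, female


def _forward(params: CkdEpiParams, biomarker, age, sex, black=False):
    b, a, female = _as_arrays(biomarker, age, sex)
    ratio = b / params.knot(female)
    egfr = (params.intercept
            * np.minimum(ratio, 1.0) ** params.alpha(female)
            * np.maximum(ratio, 1.0) ** params.beta
            * params.age_base ** a
            * np.where(female, params.female_factor, 1.0)
            * np.where(np.asarray(black, dtype=bool), params.race_factor, 1.0))
    return egfr if egfr.ndim else float(egfr)


def egfr_crea_2009(scr, age, sex, black=False):
    """eGFR (mL/min/1.73 m²) from serum creatinine (mg/dL), CKD-EPI 2009.

    ``sex`` may be "F"/"M" (or "female"/"male"), a boolean female flag, or
    an array of either.
    """
    return _forward(CREA_2009, scr, age, sex, black)


def egfr_cys_2012(scys, age, sex):
    """eGFR (mL/min/1.73 m²) from serum cystatin C (mg/L), CKD-EPI 2012."""
    return _forward(CYS_2012, scys, age, sex, black=False)


def invert_egfr(egfr, age, sex, equation="crea2009", black=False):
    """Serum concentration that yields ``egfr`` under the chosen equation.

    Closed-form piecewise inversion: with the sex/age/race prefactor
    P = intercept * age_base^age * female_factor * race_factor, the eGFR
    at the knot equals P, so egfr <= P is solved on the above-knot branch
    and egfr > P on the below-knot branch.  Exact to floating precision.
    """
    params = PARAMS[equation]
    e = np.asarray(egfr, dtype=float)
    if np.any(~(e > 0)):
        raise EgfrDomainError("eGFR must be > 0")
    # reuse validation/coding of age and sex with a dummy biomarker
    _, a, female = _as_arrays(np.ones_like(e, dtype=float), age, sex)
    prefactor = (params.intercept * params.age_base ** a
                 * np.where(female, params.female_factor, 1.0)
                 * np.where(np.asarray(black, dtype=bool),
                            params.race_factor, 1.0))
    ratio_to = e / prefactor
    exponent = np.where(ratio_to <= 1.0, 1.0 / params.beta,
                        1.0 / params.alpha(female))
    biomarker = params.knot(female) * ratio_to ** exponent
    return biomarker if biomarker.ndim else float(biomarker)
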