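"""Phenotype tables and study-specific quality control.

The phenotype table carries, per individual: demographics (age, sex),
serum creatinine and cystatin C, the cystatin validity category (1 =
within assay range; 2-4 = outside/imputed detection limits), BMI,
comorbidity and medication flags, smoking, education, ten genetic
principal components and the study label.

QC rules mirror the two-cohort comparison design:

* cystatin validity categories 2-4 are excluded from cystatin-based
  analyses (the record stays usable for creatinine),
* the general-adult cohort is restricted to age < 70 years so the two
  cohorts cover fully disjoint age ranges,
* chronic kidney disease is flagged as eGFR_crea < 60 (strict).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .ckdepi import egfr_crea_2009, egfr_cys_2012

#: column order of the tab-separated phenotype dialect
PHENOTYPE_COLUMNS = [
    "sample_id", "age", "sex", "creatinine", "cystatin",
    "cystatin_validity", "bmi", "diabetes", "hypertension", "cad",
    "high_ceiling_diuretics", "smoking", "education_years",
] + [f"pc{i}" for i in range(1, 11)] + ["study"]

GENERAL_ADULT_AGE_CAP = 70.0
CKD_EGFR_THRESHOLD = 60.0


class PhenotypeError(ValueError):
    pass


def read_phenotype_table(path) -> pd.DataFrame:
    """Read the tab-separated phenotype table (sex "F"/"M", flags 0/1,
    missing "NA")."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     float_precision="round_trip")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"phenotype table missing column(s): {missing}")
    bad_validity = ~df["cystatin_validity"].dropna().isin([1, 2, 3, 4])
    if bad_validity.any():
        raise PhenotypeError("cystatin_validity outside {1,2,3,4}")
    return df


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.17g")


def add_egfr_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Annotate eGFR_crea, eGFR_cys, and the CKD flag."""
    out = df.copy()
    out["egfr_crea"] = egfr_crea_2009(out["creatinine"].to_numpy(),
                                      out["age"].to_numpy(),
                                      out["sex"].to_numpy())
    out["egfr_cys"] = egfr_cys_2012(out["cystatin"].to_numpy(),
                                    out["age"].to_numpy(),
                                    out["sex"].to_numpy())
    out["ckd"] = out["egfr_crea"] < CKD_EGFR_THRESHOLD
    return out


def phenotype_qc(records: pd.DataFrame,
                 study_rules: str = "elderly") -> tuple[pd.DataFrame, dict]:
    """Apply study-specific QC and annotate derived kidney measures.

    Parameters
    ----------
    records
        Phenotype table (see :data:`PHENOTYPE_COLUMNS`).
    study_rules
        ``"general_adults"`` applies the age-< 70 restriction;
        ``"elderly"`` applies no age cap.

    Returns
    -------
    (table, report)
        The QC'd table with ``egfr_crea``, ``egfr_cys``, ``ckd`` and a
        boolean ``cys_valid`` column (False rows are to be excluded from
        cystatin analyses but retained for creatinine), and a report
        counting exclusions by reason.
    """
    if study_rules not in ("general_adults", "elderly"):
        raise PhenotypeError(f"unknown study_rules preset {study_rules!r}")
    df = records.copy()
    n_input = len(df)

    n_age_excluded = 0
    if study_rules == "general_adults":
        keep = df["age"] < GENERAL_ADULT_AGE_CAP
        n_age_excluded = int((~keep).sum())
        df = df[keep].copy()

    df = add_egfr_columns(df)
    df["cys_valid"] = df["cystatin_validity"] == 1
    n_cys_invalid = int((~df["cys_valid"]).sum())

    if df.empty:
        warnings.warn("phenotype_qc: no records remain after QC",
                      stacklevel=2)
    report = {
        "n_input": n_input,
        "excluded_age_cap": n_age_excluded,
        "flagged_cystatin_validity": n_cys_invalid,
        "n_retained": len(df),
    }
    return df, report
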