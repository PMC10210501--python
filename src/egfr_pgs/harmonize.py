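"""Harmonize a scoring file against a dosage matrix.

Keeps the variants present in both inputs whose alleles are compatible.
Swapped orientations (scoring effect/other equals dosage other/counted)
are resolved by complementing the dosage, d -> 2 - d.  Strand-ambiguous
(A/T, C/G) pairs are matched by id and allele pair only and flagged in
the report; no frequency-based strand inference is attempted, which is
appropriate when both cohorts share one imputation panel.

An optional imputation-quality threshold drops variants whose stored
r² falls below it (the frequency-comparison analyses use 0.8).
"""

from __future__ import annotations

import pandas as pd

from .dosage import DosageMatrix
from .scoring import ScoringFile, VariantWeight


class HarmonizationError(ValueError):
    """No variants survive harmonization."""


def harmonize_and_filter(
    score: ScoringFile,
    geno: DosageMatrix,
    r2_threshold: float | None = None,
) -> tuple[ScoringFile, DosageMatrix, pd.DataFrame]:
    """Intersect and orient ``score`` and ``geno``.

    Returns the filtered scoring file, the matching dosage matrix (columns
    ordered as the scoring file, swapped variants flipped), and a report
    with one row per scoring-file variant: ``variant_id``, ``action``
    (kept / flipped / dropped) and ``reason``.
    """
    report_rows: list[dict] = []
    kept_variants: list[VariantWeight] = []
    flip: dict[str, bool] = {}

    geno_cols = set(geno.variant_ids)
    alleles = geno.alleles

    for vw in score.variants:
        vid = vw.variant_id
        if vid not in geno_cols:
            report_rows.append({"variant_id": vid, "action": "dropped",
                                "reason": "absent from genotypes"})
            continue
        if (r2_threshold is not None and vw.imputation_r2 is not None
                and vw.imputation_r2 < r2_threshold):
            report_rows.append({"variant_id": vid, "action": "dropped",
                                "reason": "low imputation quality"})
            continue

        action, reason = "kept", "match"
        if alleles is not None:
            counted = str(alleles.loc[vid, "counted"])
            other = str(alleles.loc[vid, "other"])
            if counted == vw.effect_allele and other == vw.other_allele:
                pass
            elif counted == vw.other_allele and other == vw.effect_allele:
                action, reason = "flipped", "alleles swapped"
                flip[vid] = True
            else:
                report_rows.append({"variant_id": vid, "action": "dropped",
                                    "reason": "allele mismatch"})
                continue
        if vw.is_strand_ambiguous:
            reason += "; strand-ambiguous pair"
        report_rows.append({"variant_id": vid, "action": action,
                            "reason": reason})
        kept_variants.append(vw)

    if not kept_variants:
        raise HarmonizationError(
            "zero variants survive harmonization between scoring file "
            "and dosage matrix")

    kept_ids = [v.variant_id for v in kept_variants]
    dosages = geno.dosages[kept_ids].copy()
    for vid in flip:
        dosages[vid] = 2.0 - dosages[vid]

    out_alleles = None
    if alleles is not None:
        out_alleles = pd.DataFrame(
            {"counted": [v.effect_allele for v in kept_variants],
             "other": [v.other_allele for v in kept_variants]},
            index=pd.Index(kept_ids, name="variant_id"))

    harmonized_score = ScoringFile(trait_label=score.trait_label,
                                   variants=kept_variants)
    harmonized_geno = DosageMatrix(dosages=dosages, alleles=out_alleles)
    report = pd.DataFrame(report_rows,
                          columns=["variant_id", "action", "reason"])
    return harmonized_score, harmonized_geno, report
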