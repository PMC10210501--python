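"""Scoring files for eGFR polygenic scores.

A scoring file lists the variants that make up a polygenic score: one row
per variant with the effect allele (oriented to the eGFR-*lowering* allele),
the other allele, and a positive effect weight in mL/min/1.73 m² of eGFR
change per effect-allele copy.  The creatinine-based score nominally carries
634 variants and the cystatin-based score 204, but any non-empty panel is
accepted.

Weights are always stored as positive magnitudes.  A source row with a
negative effect weight is re-oriented at load time: the allele pair is
swapped, the stored weight is the magnitude, and the flip is recorded on the
variant so downstream harmonization can audit it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRAIT_CREA = "eGFRcrea"
TRAIT_CYS = "eGFRcys"

#: mandatory columns of the tab-separated scoring-file dialect
REQUIRED_COLUMNS = ("variant_id", "chr", "pos", "effect_allele",
                    "other_allele", "effect_weight")
OPTIONAL_COLUMNS = ("effect_allele_freq", "imputation_r2")


class ScoringFileError(ValueError):
    """Malformed scoring file or invalid variant record."""


@dataclass(frozen=True)
class VariantWeight:
    """One scored variant: the eGFR-lowering allele and its weight."""

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    weight: float
    effect_allele_freq: float | None = None
    imputation_r2: float | None = None
    #: True when the source row carried a negative effect and the allele
    #: pair was swapped at load time to keep the weight positive.
    source_sign_flipped: bool = False

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ScoringFileError("variant_id must be non-empty")
        if self.position < 1:
            raise ScoringFileError(
                f"{self.variant_id}: position must be >= 1, got {self.position}")
        if self.effect_allele == self.other_allele:
            raise ScoringFileError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})")
        if not (self.weight > 0):
            raise ScoringFileError(
                f"{self.variant_id}: non-positive weight after orientation "
                f"({self.weight})")
        if self.effect_allele_freq is not None and not (
                0.0 <= self.effect_allele_freq <= 1.0):
            raise ScoringFileError(
                f"{self.variant_id}: effect_allele_freq outside [0,1]")
        if self.imputation_r2 is not None and not (
                0.0 <= self.imputation_r2 <= 1.0):
            raise ScoringFileError(
                f"{self.variant_id}: imputation_r2 outside [0,1]")

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T or C/G pairs cannot be resolved by allele identity alone."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class ScoringFile:
    """An ordered panel of :class:`VariantWeight` records defining one PGS."""

    trait_label: str
    variants: list[VariantWeight]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ScoringFileError("scoring file contains no variants")
        ids = [v.variant_id for v in self.variants]
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        if dups:
            raise ScoringFileError(f"duplicate variant_id entries: {dups}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)

    def get(self, variant_id: str) -> VariantWeight:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise KeyError(variant_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "variant_id": v.variant_id,
            "chr": v.chromosome,
            "pos": v.position,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "effect_weight": v.weight,
            "effect_allele_freq": v.effect_allele_freq,
            "imputation_r2": v.imputation_r2,
        } for v in self.variants]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format="%.17g")


def _maybe_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_scoring_file(path, trait_label: str = TRAIT_CREA) -> ScoringFile:
    """Read a tab-separated scoring file.

    ``#`` lines are comments.  Rows with a negative effect weight are
    re-oriented (alleles swapped, weight stored as magnitude, frequency
    complemented) and flagged via ``source_sign_flipped``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chr": str},
                     na_values=["NA"], float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScoringFileError(
            f"scoring file {path} is missing mandatory column(s): {missing}")

    dup = df["variant_id"][df["variant_id"].duplicated()].unique().tolist()
    if dup:
        raise ScoringFileError(f"duplicate variant_id entries: {sorted(dup)}")

    variants: list[VariantWeight] = []
    for row in df.itertuples(index=False):
        weight = float(row.effect_weight)
        effect, other = str(row.effect_allele), str(row.other_allele)
        freq = _maybe_float(getattr(row, "effect_allele_freq", None))
        flipped = False
        if weight < 0:
            effect, other = other, effect
            weight = -weight
            freq = None if freq is None else 1.0 - freq
            flipped = True
        variants.append(VariantWeight(
            variant_id=str(row.variant_id),
            chromosome=str(row.chr),
            position=int(row.pos),
            effect_allele=effect,
            other_allele=other,
            weight=weight,
            effect_allele_freq=freq,
            imputation_r2=_maybe_float(getattr(row, "imputation_r2", None)),
            source_sign_flipped=flipped,
        ))
    return ScoringFile(trait_label=trait_label, variants=variants)


def exclude_variants(score: ScoringFile, ids: Iterable[str]) -> ScoringFile:
    """Return a copy of ``score`` without the listed variants.

    Unknown ids raise a warning, not an error; emptying the panel is an
    error.  Downstream scoring renormalizes by the new mean weight.
    """
    ids = set(ids)
    unknown = ids - set(score.variant_ids)
    if unknown:
        warnings.warn(f"exclude_variants: ids not in scoring file ignored: "
                      f"{sorted(unknown)}", stacklevel=2)
    kept = [v for v in score.variants if v.variant_id not in ids]
    if not kept:
        raise ScoringFileError("excluding these variants empties the score")
    return ScoringFile(trait_label=score.trait_label, variants=kept)
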