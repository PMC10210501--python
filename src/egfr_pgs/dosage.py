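"""Effect-allele dosage matrices.

Dosages are expected allele counts in [0, 2] per individual and variant,
as produced by genotype imputation.  Two on-disk dialects are supported:

* a tab-separated matrix with samples in rows and variant ids in the
  header (missing values coded ``NA``), and
* a VCF with a per-genotype ``DS`` FORMAT field (read via cyvcf2), where
  the counted allele is the ALT allele.

The matrix optionally carries per-variant allele metadata (which allele
the dosage counts) so that harmonization against a scoring file can flip
swapped orientations; a bare TSV without metadata is taken to be already
oriented to the scoring file's effect alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_RANGE_TOL = 1e-6


class DosageError(ValueError):
    """Invalid dosage value or malformed dosage input."""


@dataclass
class DosageMatrix:
    """Individuals × variants effect-allele dosages in [0, 2].

    Parameters
    ----------
    dosages
        Float DataFrame, index = sample ids, columns = variant ids.
        ``NaN`` encodes missing.
    alleles
        Optional DataFrame indexed by variant id with columns
        ``counted`` and ``other`` naming the allele the dosage counts
        and its partner.
    """

    dosages: pd.DataFrame
    alleles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.dosages.astype(float)
        values = df.to_numpy()
        bad = (values < -_RANGE_TOL) | (values > 2.0 + _RANGE_TOL)
        bad &= ~np.isnan(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DosageError(
                f"dosage outside [0,2] at sample {df.index[i]!r}, "
                f"variant {df.columns[j]!r}: {values[i, j]}")
        # values within numerical tolerance of the bounds are clamped
        self.dosages = df.clip(lower=0.0, upper=2.0)
        if self.alleles is not None:
            missing = [v for v in df.columns if v not in self.alleles.index]
            if missing:
                raise DosageError(
                    f"allele metadata missing for variants: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    def write_tsv(self, path) -> None:
        self.dosages.to_csv(path, sep="\t", na_rep="NA",
                            index_label="sample_id", float_format="%.17g")


def _read_dosage_tsv(path) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     float_precision="round_trip")
    return DosageMatrix(dosages=df)


def _read_dosage_vcf(path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    allele_rows: list[dict] = []
    for record in vcf:
        ds = record.format("DS")
        if ds is None:
            raise DosageError(
                f"variant {record.ID or record.POS}: no DS field in FORMAT")
        vid = record.ID or f"{record.CHROM}:{record.POS}"
        columns[vid] = np.asarray(ds, dtype=float).reshape(-1)
        allele_rows.append({"variant_id": vid,
                            "counted": record.ALT[0],
                            "other": record.REF})
    if not columns:
        raise DosageError(f"no variant records in VCF {path}")
    df = pd.DataFrame(columns, index=samples)
    alleles = pd.DataFrame(allele_rows).set_index("variant_id")
    return DosageMatrix(dosages=df, alleles=alleles)


def read_dosage_matrix(path, format: str = "tsv") -> DosageMatrix:
    """Read a dosage matrix from ``tsv`` or ``vcf_ds`` input."""
    if format == "tsv":
        return _read_dosage_tsv(path)
    if format == "vcf_ds":
        return _read_dosage_vcf(path)
    raise ValueError(f"unknown dosage format {format!r}; "
                     "expected 'tsv' or 'vcf_ds'")
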