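"""Shared fixtures: tiny hand-written scoring/dosage/phenotype inputs."""

import textwrap

import numpy as np
import pandas as pd
import pytest

from egfr_pgs.dosage import DosageMatrix
from egfr_pgs.scoring import ScoringFile, VariantWeight


SCORING_3VAR = textwrap.dedent("""\
    # three-variant toy panel
    variant_id\tchr\tpos\teffect_allele\tother_allele\teffect_weight\teffect_allele_freq\timputation_r2
    rs1\t1\t1000\tA\tG\t0.001\t0.30\t0.95
    rs2\t2\t2000\tC\tT\t0.002\t0.50\t0.85
    rs3\t3\t3000\tG\tA\t0.003\t0.70\t0.99
    """)


@pytest.fixture
def scoring_file_path(tmp_path):
    path = tmp_path / "scoring.tsv"
    path.write_text(SCORING_3VAR)
    return path


@pytest.fixture
def toy_score():
    return ScoringFile(trait_label="eGFRcrea", variants=[
        VariantWeight("rs1", "1", 1000, "A", "G", 0.001,
                      effect_allele_freq=0.3, imputation_r2=0.95),
        VariantWeight("rs2", "2", 2000, "C", "T", 0.002,
                      effect_allele_freq=0.5, imputation_r2=0.85),
        VariantWeight("rs3", "3", 3000, "G", "A", 0.003,
                      effect_allele_freq=0.7, imputation_r2=0.99),
    ])


@pytest.fixture
def toy_dosages():
    df = pd.DataFrame(
        [[2.0, 1.0, 0.0],
         [0.0, 1.0, 2.0]],
        index=pd.Index(["s1", "s2"], name="sample_id"),
        columns=["rs1", "rs2", "rs3"])
    alleles = pd.DataFrame(
        {"counted": ["A", "C", "G"], "other": ["G", "T", "A"]},
        index=pd.Index(["rs1", "rs2", "rs3"], name="variant_id"))
    return DosageMatrix(dosages=df, alleles=alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(20230525)
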