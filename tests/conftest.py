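import numpy as np
import pandas as pd
import pytest

from mpdicho import ClinicalTable, ExpressionMatrix, GeneSet
from mpdicho.preprocess import NormalizedMatrix


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples, hand-set values."""
    return ExpressionMatrix(
        ["TP53", "ZEB1", "MKI67"], ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.5], [0.25, 0.5]]),
    )


@pytest.fixture
def tiny_tsv(tmp_path, tiny_matrix):
    from mpdicho import write_expression_table
    path = tmp_path / "expr.tsv"
    write_expression_table(tiny_matrix, path)
    return path


@pytest.fixture
def hand_normalized():
    """2 proliferation + 2 migration genes over 3 samples with hand-set values.

    Proliferation decreases s1 > s2 > s3 while migration increases, so the
    fractional ranks and DI are known in closed form.
    """
    values = np.array([
        [1.0, 0.5, 0.0],   # P1
        [1.0, 0.5, 0.0],   # P2
        [0.0, 0.5, 1.0],   # M1
        [0.0, 0.5, 1.0],   # M2
    ])
    return NormalizedMatrix(["P1", "P2", "M1", "M2"], ["s1", "s2", "s3"], values)


@pytest.fixture
def hand_clinical():
    return ClinicalTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "stage_group": ["early", "early", "late"],
    }))


@pytest.fixture
def prolif_set():
    return GeneSet("PROLIF", ("P1", "P2"))


@pytest.fixture
def migr_set():
    return GeneSet("MIGR", ("M1", "M2"))
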