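import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mpdicho import (ExpressionMatrix, GeneSet, compute_signature_table,
                     dichotomize_di, geometric_mean_index, zero_one_normalize)
from mpdicho.io_formats import ValidationError
from mpdicho.preprocess import NormalizedMatrix
from mpdicho.signatures import CoverageError, SignatureScorer


class TestGeometricMeanIndex:
    def test_equal_values_return_that_value(self):
        mat = NormalizedMatrix(["a", "b", "c"], ["s1", "s2"],
                               [[0.3, 0.8]] * 3)
        score = geometric_mean_index(mat, GeneSet("S", ("a", "b", "c")))
        np.testing.assert_allclose(score.values, [0.3, 0.8], atol=1e-9)

    def test_cube_root_of_product(self):
        # geometric mean of (1, 2, 4) is 2; scorer applied on raw values
        X = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [4.0], "m": [1.0]})
        scorer = SignatureScorer(prolif_genes=("a", "b", "c"),
                                 migr_genes=("m",), pseudocount=1e-12).fit(X)
        out = scorer.transform(X)
        assert out["prolif_index"].iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_pseudocount_on_zero_value(self):
        # k=2, values (0, 1), eps=1e-6: sqrt(eps(1+eps)) - eps ~= 0.000999
        mat = NormalizedMatrix(["a", "b"], ["s1", "s2"],
                               [[0.0, 1.0], [1.0, 0.0]])
        score = geometric_mean_index(mat, GeneSet("S", ("a", "b")), pseudocount=1e-6)
        expected = np.sqrt(1e-6 * (1 + 1e-6)) - 1e-6
        assert score["s1"] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.000999, abs=1e-6)

    def test_coverage_error_lists_missing(self):
        mat = NormalizedMatrix(["a"], ["s1", "s2"], [[0.0, 1.0]])
        with pytest.raises(CoverageError, match="missing"):
            geometric_mean_index(mat, GeneSet("S", ("a", "x", "y")))

    def test_constant_genes_excluded(self):
        mat = zero_one_normalize(ExpressionMatrix(
            ["a", "b"], ["s1", "s2"], [[1.0, 3.0], [5.0, 5.0]]))
        score = geometric_mean_index(mat, GeneSet("S", ("a", "b")))
        # only gene "a" contributes: scores equal its normalized values
        np.testing.assert_allclose(score.values, [0.0, 1.0], atol=1e-9)

    def test_alias_and_case_matching(self):
        mat = NormalizedMatrix(["SNAI1", "ZEB1"], ["s1", "s2"],
                               [[0.2, 0.4], [0.2, 0.4]])
        score = geometric_mean_index(mat, GeneSet("EMT", ("SNAIL", "zeb1")))
        np.testing.assert_allclose(score.values, [0.2, 0.4], atol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 3), st.floats(0.0, 0.5))
    def test_monotone_in_any_component(self, gene_idx, bump):
        """Raising one component gene's value never lowers the score."""
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 0.5, size=(4, 3))
        mat = NormalizedMatrix([f"g{i}" for i in range(4)],
                               ["s1", "s2", "s3"], values)
        gs = GeneSet("S", tuple(f"g{i}" for i in range(4)))
        before = geometric_mean_index(mat, gs)
        bumped = values.copy()
        bumped[gene_idx, 0] += bump
        mat2 = NormalizedMatrix(mat.gene_ids, mat.sample_ids, bumped)
        after = geometric_mean_index(mat2, gs)
        assert after["s1"] >= before["s1"] - 1e-12


class TestSignatureTable:
    def test_hand_ranked_fixture(self, hand_normalized, hand_clinical,
                                 prolif_set, migr_set):
        table = compute_signature_table(hand_normalized, hand_clinical,
                                        prolif_set, migr_set)
        np.testing.assert_allclose(table["prolif_rank"], [1.0, 2 / 3, 1 / 3])
        np.testing.assert_allclose(table["migr_rank"], [1 / 3, 2 / 3, 1.0])
        np.testing.assert_allclose(table["di"], [3.0, 1.0, 1 / 3])

    def test_row_count_is_sample_intersection(self, hand_normalized, prolif_set,
                                              migr_set):
        from mpdicho import ClinicalTable
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": ["s1", "s3", "sX"],
            "stage_group": ["early", "late", "late"],
        }))
        table = compute_signature_table(hand_normalized, clin, prolif_set, migr_set)
        assert table["sample_id"].tolist() == ["s1", "s3"]

    def test_empty_overlap_rejected(self, hand_normalized, prolif_set, migr_set):
        from mpdicho import ClinicalTable
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": ["x1"], "stage_group": ["early"]}))
        with pytest.raises(ValidationError, match="no samples shared"):
            compute_signature_table(hand_normalized, clin, prolif_set, migr_set)

    def test_di_scale_free(self, hand_clinical, prolif_set, migr_set):
        """Multiplying raw expression by a constant leaves ranks and DI fixed."""
        rng = np.random.default_rng(1)
        raw = rng.uniform(0.5, 10, size=(4, 3))
        base = ExpressionMatrix(["P1", "P2", "M1", "M2"], ["s1", "s2", "s3"], raw)
        scaled = ExpressionMatrix(base.gene_ids, base.sample_ids, raw * 37.5)
        t1 = compute_signature_table(zero_one_normalize(base), hand_clinical,
                                     prolif_set, migr_set)
        t2 = compute_signature_table(zero_one_normalize(scaled), hand_clinical,
                                     prolif_set, migr_set)
        np.testing.assert_allclose(t1["di"], t2["di"], rtol=1e-9)


class TestDichotomizeDi:
    def test_median_split(self):
        table = pd.DataFrame({"sample_id": list("abcd"),
                              "di": [0.5, 1.0, 2.0, 4.0]})
        out = dichotomize_di(table)
        assert out["di_category"].tolist() == ["low", "low", "high", "high"]
        assert out.attrs["di_threshold"] == pytest.approx(1.5)

    def test_two_samples(self):
        table = pd.DataFrame({"sample_id": ["a", "b"], "di": [1.0, 3.0]})
        assert dichotomize_di(table)["di_category"].tolist() == ["low", "high"]

    def test_degenerate_all_equal(self):
        table = pd.DataFrame({"sample_id": list("abc"), "di": [1.0, 1.0, 1.0]})
        with pytest.warns(UserWarning, match="identical"):
            out = dichotomize_di(table)
        assert set(out["di_category"]) == {"low"}

    def test_extreme_di_equals_n_over_one(self):
        # top proliferation rank (1.0) with bottom migration rank (1/n) -> di = n
        table = pd.DataFrame({"sample_id": ["a"], "prolif_rank": [1.0],
                              "migr_rank": [1 / 5]})
        assert table["prolif_rank"][0] / table["migr_rank"][0] == pytest.approx(5.0)
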