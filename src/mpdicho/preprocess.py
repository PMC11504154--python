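"""Cohort-level normalisations applied before and after signature scoring.

Two normalisations are used: a per-gene zero-to-one (min-max) rescaling of
the expression matrix across the samples of one cohort, and a fractional
rank transform applied to the per-sample signature scores.  Both are
deliberately unit-agnostic so that RSEM, TPM and microarray cohorts can be
treated identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io_formats import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """Expression matrix rescaled so each non-constant gene spans [0, 1].

    ``constant_genes`` lists genes that had zero range within the cohort;
    their rows are all-zero and they are excluded from signature scoring.
    """

    constant_genes: tuple[str, ...] = field(default_factory=tuple)

    def validate(self) -> None:
        super().validate()
        if np.any(self.values > 1.0 + 1e-12):
            raise ValidationError("normalized values must lie in [0, 1]")


class ZeroOneNormalizer(BaseEstimator, TransformerMixin):
    """Min-max scaler over features with constant-feature flagging.

    Follows the scikit-learn transformer contract on arrays of shape
    (n_samples, n_features); in pipeline terms a "feature" is a gene and the
    fit set is the cohort.  Constant features are mapped to zero rather than
    left undefined, and recorded in ``constant_mask_``.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.range_ = self.data_max_ - self.data_min_
        self.constant_mask_ = self.range_ == 0
        return self

    def transform(self, X):
        check_is_fitted(self, "range_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        safe_range = np.where(self.constant_mask_, 1.0, self.range_)
        out = (X - self.data_min_) / safe_range
        out[:, self.constant_mask_] = 0.0
        return out


def zero_one_normalize(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Rescale each gene to [0, 1] across the cohort's samples.

    y_gs = (x_gs - min_s x_gs) / (max_s x_gs - min_s x_gs).  Genes constant
    across the cohort are set to all-zero and flagged.  Requires >= 2
    samples; the map is undefined on a single sample.
    """
    matrix.validate()
    if matrix.n_samples < 2:
        raise ValidationError("zero-one normalization needs at least 2 samples")
    scaler = ZeroOneNormalizer().fit(matrix.values.T)
    values = scaler.transform(matrix.values.T).T
    constant = tuple(g for g, c in zip(matrix.gene_ids, scaler.constant_mask_) if c)
    if constant:
        logger.warning("%d constant gene(s) flagged and zeroed during normalization",
                       len(constant))
    return NormalizedMatrix(list(matrix.gene_ids), list(matrix.sample_ids),
                            values, constant_genes=constant)


def fractional_rank(values) -> np.ndarray:
    """Tie-averaged ranks divided by n, giving values in (0, 1].

    Permutation-equivariant, invariant to positive affine rescaling of the
    input, and for n distinct values the sorted output is (1/n, ..., 1).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("fractional_rank expects a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("fractional_rank input contains NaN or infinite values")
    return rankdata(arr, method="average") / arr.size
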