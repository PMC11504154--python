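"""Per-sample proliferation, migration and Dichotomy Index scoring.

A signature score is the geometric mean of the zero-to-one-normalized
expression values of the genes that subserve the phenotype (a chromosomal
instability/proliferation program, e.g. CIN70, and the EMT-regulator
migration program).  Scores are fractionally ranked per cohort and the
Dichotomy Index (DI) is the ratio of the proliferation rank to the
migration rank: high DI marks proliferation-dominant samples, low DI
migration-dominant samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io_formats import ClinicalTable, GeneSet, ValidationError, canonical_symbol
from .preprocess import NormalizedMatrix, fractional_rank

logger = logging.getLogger(__name__)

SIGNATURE_COLUMNS = ["sample_id", "prolif_index", "migr_index",
                     "prolif_rank", "migr_rank", "di", "di_category"]


class CoverageError(ValidationError):
    """Too few signature genes are present in the expression matrix."""


def _match_genes(matrix_genes: list[str], gene_set: GeneSet,
                 exclude: set[str]) -> tuple[list[str], list[str]]:
    """Resolve set genes against matrix rows (case-insensitive + aliases).

    Returns (matrix row ids used, set genes not found).  Rows listed in
    ``exclude`` (constant-flagged genes) are dropped from the used list.
    """
    canon_to_row: dict[str, str] = {}
    for g in matrix_genes:
        canon_to_row.setdefault(canonical_symbol(g), g)
    used, missing = [], []
    for g in gene_set.genes:
        row = canon_to_row.get(canonical_symbol(g))
        if row is None:
            missing.append(g)
        elif row not in exclude:
            used.append(row)
    return used, missing


def geometric_mean_index(matrix: NormalizedMatrix, gene_set: GeneSet,
                         pseudocount: float = 1e-6) -> pd.Series:
    """Geometric-mean signature score per sample.

    score_s = (prod_g (y_gs + eps))^(1/k) - eps over the k set genes present
    and non-constant, clipped at zero.  The pseudocount keeps the product
    finite on min-max-normalized data, where every gene attains 0 in at
    least one sample.  Requires >= 50% of the set's genes to be present.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    matrix.validate()
    used, missing = _match_genes(matrix.gene_ids, gene_set,
                                 set(matrix.constant_genes))
    n_present = len(gene_set) - len(missing)
    if n_present < 0.5 * len(gene_set):
        raise CoverageError(
            f"gene set {gene_set.name!r}: only {n_present}/{len(gene_set)} genes "
            f"present in matrix; missing: {missing}"
        )
    if missing:
        logger.warning("gene set %s: %d/%d gene(s) absent from matrix",
                       gene_set.name, len(missing), len(gene_set))
    if not used:
        raise CoverageError(
            f"gene set {gene_set.name!r}: no usable genes after excluding "
            "constant-flagged rows"
        )
    frame = matrix.to_frame()
    sub = frame.loc[used].to_numpy()
    score = np.exp(np.log(sub + pseudocount).mean(axis=0)) - pseudocount
    return pd.Series(np.clip(score, 0.0, None), index=matrix.sample_ids,
                     name=gene_set.name)


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping a samples x genes frame to signature scores.

    Parameters
    ----------
    prolif_genes, migr_genes : sequences of gene symbols.
    pseudocount : float, geometric-mean pseudocount (default 1e-6).

    ``transform`` returns a frame with columns prolif_index, migr_index,
    prolif_rank, migr_rank and di.  Ranks are computed over the transformed
    cohort itself (the transform is cohort-level, like the normalisation).
    """

    def __init__(self, prolif_genes=(), migr_genes=(), pseudocount: float = 1e-6):
        self.prolif_genes = prolif_genes
        self.migr_genes = migr_genes
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("SignatureScorer expects a samples x genes DataFrame")
        canon = {canonical_symbol(c): c for c in X.columns}
        self.prolif_genes_ = [canon[canonical_symbol(g)] for g in self.prolif_genes
                              if canonical_symbol(g) in canon]
        self.migr_genes_ = [canon[canonical_symbol(g)] for g in self.migr_genes
                            if canonical_symbol(g) in canon]
        for name, found, asked in (("proliferation", self.prolif_genes_, self.prolif_genes),
                                   ("migration", self.migr_genes_, self.migr_genes)):
            if len(found) < 0.5 * len(list(asked)) or not found:
                raise CoverageError(f"{name} signature: insufficient gene coverage")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "prolif_genes_")
        eps = self.pseudocount
        out = pd.DataFrame(index=X.index)
        for col, genes in (("prolif_index", self.prolif_genes_),
                           ("migr_index", self.migr_genes_)):
            sub = X[genes].to_numpy(dtype=float)
            out[col] = np.clip(np.exp(np.log(sub + eps).mean(axis=1)) - eps, 0.0, None)
        out["prolif_rank"] = fractional_rank(out["prolif_index"].to_numpy())
        out["migr_rank"] = fractional_rank(out["migr_index"].to_numpy())
        out["di"] = out["prolif_rank"] / out["migr_rank"]
        return out


def compute_signature_table(matrix: NormalizedMatrix, clinical: ClinicalTable,
                            prolif_set: GeneSet, migr_set: GeneSet,
                            pseudocount: float = 1e-6) -> pd.DataFrame:
    """Score every sample present in both the matrix and the clinical table.

    Indices are geometric means, ranks are cohort-level fractional ranks and
    di = prolif_rank / migr_rank.  Samples missing from either input are
    dropped with a logged count.
    """
    shared = [s for s in matrix.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise ValidationError("no samples shared between matrix and clinical table")
    dropped = (matrix.n_samples - len(shared)) + (len(clinical.sample_ids) - len(shared))
    if dropped:
        logger.warning("dropped %d sample(s) absent from matrix or clinical table", dropped)

    prolif = geometric_mean_index(matrix, prolif_set, pseudocount)
    migr = geometric_mean_index(matrix, migr_set, pseudocount)
    table = pd.DataFrame({
        "sample_id": shared,
        "prolif_index": prolif.loc[shared].to_numpy(),
        "migr_index": migr.loc[shared].to_numpy(),
    })
    table["prolif_rank"] = fractional_rank(table["prolif_index"].to_numpy())
    table["migr_rank"] = fractional_rank(table["migr_index"].to_numpy())
    table["di"] = table["prolif_rank"] / table["migr_rank"]
    return table


def dichotomize_di(table: pd.DataFrame, method: str = "median") -> pd.DataFrame:
    """Assign the high/low DI category by a cohort-median split.

    di > median -> "high", di <= median -> "low".  The threshold is recorded
    in ``table.attrs["di_threshold"]``.  A degenerate cohort (all DI equal)
    is assigned all-low with a warning.
    """
    if method != "median":
        raise ValueError(f"unknown dichotomization method {method!r}")
    if len(table) < 2:
        raise ValidationError("DI dichotomization needs at least 2 samples")
    out = table.copy()
    di = out["di"].to_numpy(dtype=float)
    threshold = float(np.median(di))
    if np.all(di == di[0]):
        warnings.warn("all DI values identical; assigning every sample to 'low'")
        out["di_category"] = "low"
    else:
        out["di_category"] = np.where(di > threshold, "high", "low")
    out.attrs["di_threshold"] = threshold
    return out
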