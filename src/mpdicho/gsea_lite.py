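"""Lightweight phenotype-permutation gene set enrichment.

Implements the weighted Kolmogorov-Smirnov running-sum enrichment score,
signal-to-noise gene ranking between two phenotype classes, phenotype
permutation for nominal p and NES, the sign-stratified permutation FDR, and
leading-edge ("core enrichment") extraction.  Defaults mirror the reference
desktop conventions: weight 1, signal-to-noise metric, 1000 permutations,
standard-deviation floor of max(0.2 |mu|, 0.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, ValidationError, canonical_symbol
from .stats_core import OverlapZResult, two_proportion_z

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, scores non-increasing."""

    gene_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.gene_ids.size != self.scores.size or self.gene_ids.size < 2:
            raise ValidationError("ranked list needs >= 2 (gene, score) pairs")
        if len(set(self.gene_ids)) != self.gene_ids.size:
            raise ValidationError("ranked list genes must be unique")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValidationError("ranked list scores must be non-increasing")

    def __len__(self) -> int:
        return self.gene_ids.size


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: tuple[str, ...]


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_perm: int
    size: int  # set genes present in the ranked universe

    def to_dict(self) -> dict:
        d = asdict(self)
        d["leading_edge"] = list(self.leading_edge)
        return d


def _class_masks(labels: Sequence[str], classes: Sequence[str] | None):
    labels = np.asarray(labels, dtype=object)
    found = list(pd.unique(labels))
    if classes is None:
        classes = found
    if len(classes) != 2 or set(classes) != set(found):
        raise ValidationError(f"expected exactly 2 phenotype classes, got {found}")
    mask_a = labels == classes[0]
    if mask_a.sum() < 3 or (~mask_a).sum() < 3:
        raise ValidationError("signal-to-noise ranking needs >= 3 samples per class")
    return mask_a, tuple(classes)


def _signal_to_noise(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Per-gene (mu_A - mu_B) / (sd_A + sd_B) with the 0.2 floor on each sd."""
    out = []
    for mask in (mask_a, ~mask_a):
        sub = values[:, mask]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        sd = np.maximum(sd, np.maximum(0.2 * np.abs(mu), 0.2))
        out.append((mu, sd))
    (mu_a, sd_a), (mu_b, sd_b) = out
    return (mu_a - mu_b) / (sd_a + sd_b)


def _descending_order(gene_ids: np.ndarray, scores: np.ndarray) -> np.ndarray:
    # ties broken lexicographically by gene id for cross-platform determinism
    return np.lexsort((gene_ids.astype(str), -scores))


def rank_by_signal_to_noise(matrix: ExpressionMatrix, labels: Sequence[str],
                            classes: Sequence[str] | None = None) -> RankedList:
    """Rank all genes by the signal-to-noise metric between two classes.

    ``classes`` fixes which class is the positive pole (defaults to order of
    first appearance, the CLS convention).  Swapping the classes negates the
    scores and reverses the order up to tie-breaks.
    """
    matrix.validate()
    if len(labels) != matrix.n_samples:
        raise ValidationError("one label per sample required")
    mask_a, _ = _class_masks(labels, classes)
    s2n = _signal_to_noise(matrix.values, mask_a)
    gene_ids = np.asarray(matrix.gene_ids, dtype=object)
    order = _descending_order(gene_ids, s2n)
    return RankedList(gene_ids[order], s2n[order])


def _running_sum(scores: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    n = scores.size
    n_hit = int(hits.sum())
    w = np.abs(scores) ** weight
    denom = w[hits].sum()
    incr = np.zeros(n)
    if denom > 0:
        incr[hits] = w[hits] / denom
    else:  # all hit scores are zero: fall back to equal weights
        incr[hits] = 1.0 / n_hit
    incr[~hits] = -1.0 / (n - n_hit)
    return np.cumsum(incr)


def _es_only(scores: np.ndarray, hits: np.ndarray, weight: float) -> float:
    running = _running_sum(scores, hits, weight)
    return float(running[int(np.argmax(np.abs(running)))])


def enrichment_score(ranked: RankedList, gene_set: GeneSet,
                     weight: float = 1.0) -> ESResult:
    """Weighted KS enrichment score with running sum and leading edge.

    Hits advance the running sum by |score|^weight (normalized over hits),
    misses retreat by 1/(N - N_hit); the ES is the signed maximum deviation
    and the leading edge holds the set genes at or before the peak for a
    positive ES (at or after it for a negative ES).
    """
    if weight < 0:
        raise ValidationError("weight must be >= 0")
    members = {canonical_symbol(g) for g in gene_set.genes}
    hits = np.array([canonical_symbol(g) in members for g in ranked.gene_ids])
    if not hits.any():
        raise ValidationError(f"gene set {gene_set.name!r} has no overlap with the ranked list")
    if hits.all():
        raise ValidationError(f"gene set {gene_set.name!r} covers the whole ranked list")
    running = _running_sum(ranked.scores, hits, weight)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    if es >= 0:
        edge_mask = hits & (np.arange(len(ranked)) <= peak)
    else:
        edge_mask = hits & (np.arange(len(ranked)) >= peak)
    leading = tuple(str(g) for g in ranked.gene_ids[edge_mask])
    return ESResult(es=es, running_sum=running, peak_index=peak, leading_edge=leading)


def _normalize_by_sign(es: np.ndarray, pos_mean: float, neg_mean: float) -> np.ndarray:
    """Divide positive ES by the mean positive permuted ES and negative by
    the mean |negative| permuted ES (standard NES convention)."""
    out = np.zeros_like(es)
    pos = es >= 0
    out[pos] = es[pos] / pos_mean if pos_mean > 0 else np.nan
    out[~pos] = es[~pos] / neg_mean if neg_mean > 0 else np.nan
    return out


def gsea_phenotype(matrix: ExpressionMatrix, labels: Sequence[str],
                   gene_sets: Sequence[GeneSet], n_perm: int = 1000,
                   seed: int | None = None, weight: float = 1.0,
                   classes: Sequence[str] | None = None) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA over a collection of gene sets.

    For each permutation the class labels are shuffled with a seeded
    generator and the signal-to-noise ranking and per-set ES recomputed.
    p_nominal is the fraction of same-sign permuted ES at least as extreme
    as the observed ES; NES divides the ES by the mean magnitude of the
    same-sign permuted ES; the FDR q compares the permuted and observed NES
    distributions stratified by sign.  Deterministic given the seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm < 100 gives unstable p/FDR estimates")
    matrix.validate()
    mask_a, class_pair = _class_masks(labels, classes)
    gene_ids = np.asarray(matrix.gene_ids, dtype=object)
    values = matrix.values
    n_genes, n_samples = values.shape
    n_a = int(mask_a.sum())

    # observed ranking and per-set statistics
    s2n_obs = _signal_to_noise(values, mask_a)
    order = _descending_order(gene_ids, s2n_obs)
    ranked_obs = RankedList(gene_ids[order], s2n_obs[order])

    member_masks, es_obs, edges, sizes = [], [], [], []
    canon_rows = np.array([canonical_symbol(g) for g in gene_ids], dtype=object)
    for gs in gene_sets:
        res = enrichment_score(ranked_obs, gs, weight)
        es_obs.append(res.es)
        edges.append(res.leading_edge)
        members = {canonical_symbol(g) for g in gs.genes}
        mask = np.isin(canon_rows, list(members))
        member_masks.append(mask)
        sizes.append(int(mask.sum()))
    es_obs = np.array(es_obs)

    # permuted ES: shuffle which samples belong to class A
    rng = np.random.default_rng(seed)
    es_perm = np.empty((len(gene_sets), n_perm))
    idx = np.arange(n_samples)
    for j in range(n_perm):
        perm = rng.permutation(idx)
        pmask = np.zeros(n_samples, dtype=bool)
        pmask[perm[:n_a]] = True
        s2n = _signal_to_noise(values, pmask)
        p_order = np.lexsort((canon_rows.astype(str), -s2n))
        scores_sorted = s2n[p_order]
        for i, mask in enumerate(member_masks):
            es_perm[i, j] = _es_only(scores_sorted, mask[p_order], weight)

    # per-set same-sign summaries
    pos_means = np.array([es_perm[i][es_perm[i] >= 0].mean()
                          if (es_perm[i] >= 0).any() else 0.0
                          for i in range(len(gene_sets))])
    neg_means = np.array([np.abs(es_perm[i][es_perm[i] < 0]).mean()
                          if (es_perm[i] < 0).any() else 0.0
                          for i in range(len(gene_sets))])

    p_nominal = np.empty(len(gene_sets))
    nes_obs = np.empty(len(gene_sets))
    for i, es in enumerate(es_obs):
        same = es_perm[i] >= 0 if es >= 0 else es_perm[i] < 0
        n_same = int(same.sum())
        if n_same == 0:
            p_nominal[i] = 0.0
        else:
            p_nominal[i] = float((np.abs(es_perm[i][same]) >= abs(es)).sum() / n_same)
        scale = pos_means[i] if es >= 0 else neg_means[i]
        if scale == 0.0:  # no same-sign permutations: fall back to overall scale
            scale = np.abs(es_perm[i]).mean() or 1.0
        nes_obs[i] = es / scale

    # sign-stratified permutation FDR over the pooled NES distribution
    nes_perm = np.vstack([
        _normalize_by_sign(es_perm[i],
                           pos_means[i] if pos_means[i] > 0 else np.abs(es_perm[i]).mean() or 1.0,
                           neg_means[i] if neg_means[i] > 0 else np.abs(es_perm[i]).mean() or 1.0)
        for i in range(len(gene_sets))
    ]).ravel()
    nes_perm = nes_perm[np.isfinite(nes_perm)]

    fdr_q = np.empty(len(gene_sets))
    for i, nes in enumerate(nes_obs):
        if nes >= 0:
            perm_pool = nes_perm[nes_perm >= 0]
            obs_pool = nes_obs[nes_obs >= 0]
            num = (perm_pool >= nes).mean() if perm_pool.size else 1.0
            den = (obs_pool >= nes).mean() if obs_pool.size else 1.0
        else:
            perm_pool = nes_perm[nes_perm < 0]
            obs_pool = nes_obs[nes_obs < 0]
            num = (perm_pool <= nes).mean() if perm_pool.size else 1.0
            den = (obs_pool <= nes).mean() if obs_pool.size else 1.0
        fdr_q[i] = min(1.0, num / den) if den > 0 else 1.0

    logger.info("GSEA (%s vs %s): %d set(s), %d permutation(s)",
                class_pair[0], class_pair[1], len(gene_sets), n_perm)
    return [
        EnrichmentResult(set_name=gs.name, es=float(es_obs[i]), nes=float(nes_obs[i]),
                         p_nominal=float(p_nominal[i]), fdr_q=float(fdr_q[i]),
                         leading_edge=edges[i], n_perm=n_perm, size=sizes[i])
        for i, gs in enumerate(gene_sets)
    ]


def core_gene_compilation(results: Sequence[EnrichmentResult],
                          p_thresh: float = 0.05, q_thresh: float = 0.25,
                          direction: str | None = None) -> tuple[list[str], int]:
    """Union of leading-edge genes over the significantly enriched sets.

    Sets pass at p_nominal < p_thresh and fdr_q < q_thresh; ``direction``
    ("pos" or "neg") restricts to one enrichment pole.  Returns the sorted
    unique core-gene list and its size.
    """
    if not list(results):
        raise ValidationError("no enrichment results supplied")
    core: set[str] = set()
    for res in results:
        if res.p_nominal >= p_thresh or res.fdr_q >= q_thresh:
            continue
        if direction == "pos" and res.es < 0:
            continue
        if direction == "neg" and res.es >= 0:
            continue
        core.update(res.leading_edge)
    genes = sorted(core)
    return genes, len(genes)


def _count(core) -> int:
    return core if isinstance(core, (int, np.integer)) else len(set(core))


def core_overlap_comparison(core_a, total_a: int, core_b, total_b: int) -> OverlapZResult:
    """z test comparing two shared-core-gene fractions.

    ``core_a``/``core_b`` may be gene collections (counted uniquely) or
    pre-computed shared counts; delegates to the pooled two-proportion z.
    """
    return two_proportion_z(_count(core_a), int(total_a), _count(core_b), int(total_b))


def shared_core(core_x: Sequence[str], core_y: Sequence[str]) -> tuple[int, int]:
    """(|X ∩ Y|, |X ∪ Y|) for two core-gene lists."""
    sx, sy = set(core_x), set(core_y)
    return len(sx & sy), len(sx | sy)
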