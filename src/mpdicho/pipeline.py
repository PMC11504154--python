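"""End-to-end analysis: normalize, score, test, enrich, and render a verdict.

The pipeline estimates the migration-proliferation relationship of a cohort
(normalisation -> signature/DI scoring -> stage-wise Pearson correlations
with BH adjustment -> DI dominance-shift tests -> phenotype-permutation
GSEA for the DI and stage contrasts -> core-gene overlap z tests) and
classifies the cohort under one of three competing models:

* MPD  — migration-proliferation dichotomy: indices inversely correlated;
* SMP  — simultaneous migration-proliferation: directly correlated;
* PR   — phenotype-refractory clones: indices independent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gsea_lite import (EnrichmentResult, core_gene_compilation,
                        core_overlap_comparison, gsea_phenotype, shared_core)
from .io_formats import ClinicalTable, GeneSet, ValidationError
from .preprocess import zero_one_normalize
from .signatures import compute_signature_table, dichotomize_di
from .stats_core import (CorrelationResult, OverlapZResult, TestResult,
                         bh_adjust, chi_square_independence, independent_t,
                         pearson_r)

logger = logging.getLogger(__name__)

VERDICTS = ("MPD", "SMP", "PR", "indeterminate")
#: stage groups analysed separately when populated
STAGE_ORDER = ("early", "late", "metastasis", "unknown")


@dataclass
class AnalysisReport:
    correlations: list[CorrelationResult]          # stage groups, BH-adjusted
    overall: CorrelationResult | None
    subgroup_correlations: dict[str, CorrelationResult]
    di_t_test: TestResult | None
    di_chi2: TestResult | None
    shift_direction: str | None
    di_threshold: float | None
    enrichment_di: list[EnrichmentResult]
    enrichment_stage: list[EnrichmentResult]
    core_sizes: dict[str, int]
    overlap_tests: dict[str, OverlapZResult]
    verdict: str
    config: dict = field(default_factory=dict)
    signature_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "correlations": [c.to_dict() for c in self.correlations],
            "overall": self.overall.to_dict() if self.overall else None,
            "subgroup_correlations": {k: v.to_dict()
                                      for k, v in sorted(self.subgroup_correlations.items())},
            "di_t_test": self.di_t_test.to_dict() if self.di_t_test else None,
            "di_chi2": self.di_chi2.to_dict() if self.di_chi2 else None,
            "shift_direction": self.shift_direction,
            "di_threshold": self.di_threshold,
            "enrichment_di": [e.to_dict() for e in self.enrichment_di],
            "enrichment_stage": [e.to_dict() for e in self.enrichment_stage],
            "core_sizes": dict(sorted(self.core_sizes.items())),
            "overlap_tests": {k: v.to_dict() for k, v in sorted(self.overlap_tests.items())},
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def classify_model(stage_correlations: Sequence[CorrelationResult],
                   alpha: float = 0.05) -> str:
    """Model verdict from the signs of the significant stage-wise correlations.

    Significance is judged on the adjusted p (raw p when no adjustment was
    set).  All significant correlations negative (>= 1 of them) -> MPD; all
    positive -> SMP; none significant -> PR; mixed signs -> indeterminate.
    """
    results = list(stage_correlations)
    if not results:
        raise ValidationError("classify_model needs at least one correlation result")
    significant = [c for c in results
                   if (c.p_adj if c.p_adj is not None else c.p) < alpha]
    if not significant:
        return "PR"
    signs = {np.sign(c.r) for c in significant}
    if signs == {-1.0}:
        return "MPD"
    if signs == {1.0}:
        return "SMP"
    return "indeterminate"


def dominance_shift(signatures: pd.DataFrame, clinical: ClinicalTable,
                    groups: tuple[str, str] = ("early", "late"),
                    alpha: float = 0.05
                    ) -> tuple[TestResult, TestResult, str]:
    """Test whether phenotype dominance shifts between two stage groups.

    Runs an independent t test on DI between the groups and a chi-square
    test on di_category x stage.  When either test reaches ``alpha``, the
    direction follows the sign of the DI difference: a drop in DI from the
    first to the second group is a shift toward migration dominance, a rise
    a shift toward proliferation dominance.
    """
    stage = clinical.stage_of()
    merged = signatures.assign(stage=signatures["sample_id"].map(stage))
    sub = {g: merged[merged["stage"] == g] for g in groups}
    for g, frame in sub.items():
        if frame.empty:
            raise ValidationError(f"stage group {g!r} is empty")
    t_res = independent_t(sub[groups[0]]["di"], sub[groups[1]]["di"])
    counts = np.array([
        [(sub[g]["di_category"] == "high").sum() for g in groups],
        [(sub[g]["di_category"] == "low").sum() for g in groups],
    ])
    chi_res = chi_square_independence(counts)
    direction = "none"
    if min(t_res.p, chi_res.p) < alpha:
        diff = sub[groups[0]]["di"].mean() - sub[groups[1]]["di"].mean()
        direction = "toward_migration" if diff > 0 else "toward_proliferation"
    return t_res, chi_res, direction


def grouped_analysis(signatures: pd.DataFrame, clinical: ClinicalTable,
                     min_size: int = 10) -> tuple[dict[str, CorrelationResult], list[str]]:
    """Per-subgroup rank correlations (e.g. molecular subtypes).

    Subgroups below ``min_size`` samples are reported as skipped rather than
    tested (small subtypes give unstable correlations).
    """
    sub_col = clinical.table.set_index("sample_id")["subgroup"]
    if sub_col.isna().all():
        raise ValidationError("clinical table has no subgroup labels")
    merged = signatures.assign(subgroup=signatures["sample_id"].map(sub_col))
    results: dict[str, CorrelationResult] = {}
    skipped: list[str] = []
    for name, frame in merged.dropna(subset=["subgroup"]).groupby("subgroup"):
        if len(frame) < min_size:
            skipped.append(str(name))
            logger.warning("subgroup %s skipped (n=%d < %d)", name, len(frame), min_size)
            continue
        results[str(name)] = pearson_r(frame["prolif_rank"], frame["migr_rank"],
                                       label=str(name))
    if not results:
        logger.warning("no subgroup met the minimum size %d", min_size)
    return results, skipped


def _stage_correlations(signatures: pd.DataFrame, clinical: ClinicalTable,
                        min_group: int) -> tuple[list[CorrelationResult], CorrelationResult]:
    stage = clinical.stage_of()
    merged = signatures.assign(stage=signatures["sample_id"].map(stage))
    results = []
    for group in STAGE_ORDER:
        frame = merged[merged["stage"] == group]
        if len(frame) == 0:
            continue
        if len(frame) < max(min_group, 3):
            logger.warning("stage group %s skipped (n=%d below minimum %d)",
                           group, len(frame), max(min_group, 3))
            continue
        results.append(pearson_r(frame["prolif_rank"], frame["migr_rank"], label=group))
    if results:
        adj = bh_adjust([c.p for c in results])
        for c, a in zip(results, adj):
            c.p_adj = float(a)
    overall = pearson_r(merged["prolif_rank"], merged["migr_rank"], label="overall")
    overall.p_adj = overall.p  # single test, no family to adjust over
    return results, overall


def run_analysis(matrix, clinical: ClinicalTable, prolif_set: GeneSet,
                 migr_set: GeneSet, *, gene_sets: Sequence[GeneSet] | None = None,
                 n_perm: int = 1000, seed: int = 0, alpha: float = 0.05,
                 run_gsea: bool = True, min_group: int = 3,
                 pseudocount: float = 1e-6) -> AnalysisReport:
    """Run the full migration-proliferation dichotomy analysis on one cohort."""
    normalized = zero_one_normalize(matrix)
    signatures = compute_signature_table(normalized, clinical, prolif_set,
                                         migr_set, pseudocount)
    signatures = dichotomize_di(signatures)
    di_threshold = signatures.attrs.get("di_threshold")

    correlations, overall = _stage_correlations(signatures, clinical, min_group)

    stage = clinical.stage_of()
    merged_stage = signatures["sample_id"].map(stage)
    di_t = di_chi = None
    direction = None
    if {"early", "late"} <= set(merged_stage):
        try:
            di_t, di_chi, direction = dominance_shift(signatures, clinical, alpha=alpha)
        except ValidationError as exc:
            logger.warning("dominance-shift tests skipped: %s", exc)

    enrichment_di: list[EnrichmentResult] = []
    enrichment_stage: list[EnrichmentResult] = []
    core_sizes: dict[str, int] = {}
    overlap_tests: dict[str, OverlapZResult] = {}
    if run_gsea:
        sets = list(gene_sets) if gene_sets else [prolif_set, migr_set]
        keep = signatures["sample_id"].tolist()
        sub_matrix = _subset_samples(normalized, keep)
        di_labels = signatures["di_category"].tolist()
        stage_labels = merged_stage.tolist()
        try:
            enrichment_di = gsea_phenotype(sub_matrix, di_labels, sets,
                                           n_perm=n_perm, seed=seed,
                                           classes=("high", "low"))
        except ValidationError as exc:
            logger.warning("DI-contrast GSEA skipped: %s", exc)
        if {"early", "late"} <= set(stage_labels):
            el_mask = [s in ("early", "late") for s in stage_labels]
            el_matrix = _subset_samples(sub_matrix, list(np.array(keep)[el_mask]))
            el_labels = list(np.array(stage_labels)[el_mask])
            try:
                enrichment_stage = gsea_phenotype(el_matrix, el_labels, sets,
                                                  n_perm=n_perm, seed=seed + 1,
                                                  classes=("early", "late"))
            except ValidationError as exc:
                logger.warning("stage-contrast GSEA skipped: %s", exc)
        if enrichment_di and enrichment_stage:
            cores = {
                "high_di": core_gene_compilation(enrichment_di, direction="pos")[0],
                "low_di": core_gene_compilation(enrichment_di, direction="neg")[0],
                "early": core_gene_compilation(enrichment_stage, direction="pos")[0],
                "late": core_gene_compilation(enrichment_stage, direction="neg")[0],
            }
            core_sizes = {k: len(v) for k, v in cores.items()}
            overlap_tests = _core_overlaps(cores)

    verdict = classify_model(correlations, alpha=alpha)
    config = {"n_perm": n_perm if run_gsea else 0, "seed": seed, "alpha": alpha,
              "pseudocount": pseudocount, "min_group": min_group,
              "prolif_set": prolif_set.name, "migr_set": migr_set.name,
              "n_samples_scored": int(len(signatures))}
    return AnalysisReport(
        correlations=correlations, overall=overall, subgroup_correlations={},
        di_t_test=di_t, di_chi2=di_chi, shift_direction=direction,
        di_threshold=di_threshold, enrichment_di=enrichment_di,
        enrichment_stage=enrichment_stage, core_sizes=core_sizes,
        overlap_tests=overlap_tests, verdict=verdict, config=config,
        signature_table=signatures,
    )


def _subset_samples(matrix, sample_ids: list[str]):
    frame = matrix.to_frame()[sample_ids]
    from .preprocess import NormalizedMatrix
    return NormalizedMatrix(list(frame.index), sample_ids, frame.to_numpy(),
                            constant_genes=getattr(matrix, "constant_genes", ()))


def _core_overlaps(cores: dict[str, list[str]]) -> dict[str, OverlapZResult]:
    """Compare shared-core fractions across the four enrichment categories.

    For each stage category, the fraction of core genes shared with the
    low-DI core (k over the union size) is compared against the fraction
    shared with the high-DI core.
    """
    out: dict[str, OverlapZResult] = {}
    for stage_cat in ("early", "late"):
        k_low, n_low = shared_core(cores[stage_cat], cores["low_di"])
        k_high, n_high = shared_core(cores[stage_cat], cores["high_di"])
        if min(n_low, n_high) == 0 or (k_low + k_high) in (0, n_low + n_high):
            logger.warning("overlap z for %s skipped: degenerate counts", stage_cat)
            continue
        out[f"{stage_cat}_low_vs_high_di"] = core_overlap_comparison(
            k_low, n_low, k_high, n_high)
    return out


def write_report(report: AnalysisReport, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a report to JSON + TSV tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.json"}
    paths["report"].write_text(report.to_json() + "\n")
    if report.signature_table is not None:
        paths["signatures"] = out / "signature_table.tsv"
        report.signature_table.to_csv(paths["signatures"], sep="\t", index=False,
                                      float_format="%.6g")
    rows = [c.to_dict() for c in report.correlations]
    if report.overall:
        rows.append(report.overall.to_dict())
    if rows:
        paths["correlations"] = out / "correlations.tsv"
        pd.DataFrame(rows).to_csv(paths["correlations"], sep="\t", index=False,
                                  float_format="%.6g")
    for name, enr in (("enrichment_di", report.enrichment_di),
                      ("enrichment_stage", report.enrichment_stage)):
        if enr:
            frame = pd.DataFrame([{**e.to_dict(),
                                   "leading_edge": ";".join(e.leading_edge)}
                                  for e in enr])
            paths[name] = out / f"{name}.tsv"
            frame.to_csv(paths[name], sep="\t", index=False, float_format="%.6g")
    return paths
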