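"""Synthetic bulk-expression cohorts with a planted migration-proliferation structure.

A latent-factor linear-Gaussian generator: each sample carries a latent
proliferation activity P and migration activity M drawn from a bivariate
normal whose correlation rho encodes the competing hypotheses in one
parameter (dichotomy: rho < 0; simultaneous migration-proliferation:
rho > 0; phenotype-refractory independence: rho = 0).  A stage-dependent
mean shift delta moves early samples toward proliferation dominance and
late samples toward migration dominance.  Program genes load linearly on
their latent activity plus Gaussian noise; background genes are pure noise.
The generator returns the latent truth so parameter-recovery tests can
compare pipeline estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (ClinicalTable, ExpressionMatrix, GeneSet, ValidationError,
                         write_cls, write_clinical_table, write_expression_table,
                         write_gmt)

#: the nine EMT-regulator transcription factors of the migration program
EMT_REGULATORS = ("SNAI1", "SNAI2", "TWIST1", "TWIST2", "ZEB1", "ZEB2",
                  "GLI1", "GLI2", "KLF4")


@dataclass(frozen=True)
class SyntheticConfig:
    n_early: int = 333
    n_late: int = 293
    rho: float = -0.25          # latent migration-proliferation correlation
    delta: float = 0.35         # stage dominance shift, latent SD units
    n_prolif_genes: int = 70
    n_migr_genes: int = 9
    n_background: int = 150
    sigma: float = 0.5          # gene-level noise SD
    seed: int = 0

    def validate(self) -> None:
        if self.n_early < 10 or self.n_late < 10:
            raise ValidationError("need >= 10 samples per stage group")
        if not -1.0 < self.rho < 1.0:
            raise ValidationError("rho must lie in (-1, 1)")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if self.n_prolif_genes < 5 or self.n_migr_genes < 5:
            raise ValidationError("need >= 5 genes per program")
        if self.n_background < 0:
            raise ValidationError("n_background must be >= 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")


#: preset study conditions; sample sizes follow the cohorts being emulated
_PRESETS: dict[str, SyntheticConfig] = {
    "crc_like": SyntheticConfig(n_early=333, n_late=293, rho=-0.25, delta=0.35, seed=13),
    "gc_like": SyntheticConfig(n_early=59, n_late=382, rho=-0.55, delta=0.6, seed=17),
    "null_model": SyntheticConfig(n_early=200, n_late=200, rho=0.0, delta=0.0, seed=23),
    "smp_like": SyntheticConfig(n_early=200, n_late=200, rho=0.5, delta=0.0, seed=29),
    "pr_like": SyntheticConfig(n_early=200, n_late=200, rho=0.0, delta=0.75, seed=31),
}


def preset(name: str) -> SyntheticConfig:
    """Named study conditions: crc_like, gc_like, null_model, smp_like, pr_like."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def _gene_names(config: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    migr = list(EMT_REGULATORS[:config.n_migr_genes])
    migr += [f"MIG_{i:03d}" for i in range(len(migr), config.n_migr_genes)]
    prolif = [f"PRO_{i:03d}" for i in range(config.n_prolif_genes)]
    background = [f"BG_{i:04d}" for i in range(config.n_background)]
    return prolif, migr, background


def signature_gene_sets(config: SyntheticConfig) -> tuple[GeneSet, GeneSet]:
    """The proliferation and migration gene sets matching a generated cohort."""
    prolif, migr, _ = _gene_names(config)
    return (GeneSet("PROLIFERATION_PROGRAM", tuple(prolif)),
            GeneSet("EMT_REGULATORS", tuple(migr)))


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[ExpressionMatrix, ClinicalTable, pd.DataFrame]:
    """Draw one cohort; fully determined by ``config.seed``.

    Returns (expression matrix, clinical table, truth) where truth holds the
    latent (P, M) activities per sample for recovery tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_early + config.n_late
    stages = np.array(["early"] * config.n_early + ["late"] * config.n_late)

    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    latent = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    shift = np.where(stages == "early", config.delta, -config.delta)
    p_act = latent[:, 0] + shift
    m_act = latent[:, 1] - shift

    prolif_names, migr_names, bg_names = _gene_names(config)
    loads_p = rng.uniform(0.5, 1.5, size=config.n_prolif_genes)
    loads_m = rng.uniform(0.5, 1.5, size=config.n_migr_genes)
    noise = rng.normal(0.0, config.sigma,
                       size=(config.n_prolif_genes + config.n_migr_genes, n))
    prolif_block = loads_p[:, None] * p_act[None, :] + noise[:config.n_prolif_genes]
    migr_block = loads_m[:, None] * m_act[None, :] + noise[config.n_prolif_genes:]
    bg_block = rng.normal(0.0, 1.0, size=(config.n_background, n))

    values = np.vstack([prolif_block, migr_block, bg_block])
    values -= values.min()  # global shift to nonnegative; min-max is shift-invariant

    sample_ids = [f"S{i:04d}" for i in range(n)]
    matrix = ExpressionMatrix(prolif_names + migr_names + bg_names, sample_ids, values)
    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "stage_group": stages,
        "raw_stage": None,
        "subgroup": None,
    }))
    truth = pd.DataFrame({"sample_id": sample_ids, "stage_group": stages,
                          "P": p_act, "M": m_act})
    return matrix, clinical, truth


def write_cohort(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write GCT + clinical TSV + CLS + GMT + truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, clinical, truth = generate_cohort(config)
    prolif_set, migr_set = signature_gene_sets(config)
    paths = {
        "expression": out / "expression.gct",
        "clinical": out / "clinical.tsv",
        "phenotype": out / "stages.cls",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.tsv",
    }
    write_expression_table(matrix, paths["expression"], format="gct")
    write_clinical_table(clinical, paths["clinical"])
    write_cls(clinical.table["stage_group"].tolist(), paths["phenotype"])
    write_gmt([prolif_set, migr_set], paths["gene_sets"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    return paths
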