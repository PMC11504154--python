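# Methods

## Scoring model

Expression is first normalised per gene across the samples of one cohort:
y_gs = (x_gs − min_s x_gs) / (max_s x_gs − min_s x_gs). The axis matters and
is a design choice: per-gene scaling makes genes commensurate before they are
pooled by a geometric mean, whereas per-sample scaling would not. Genes with
zero range are set to all-zero, flagged, and excluded from signature scoring
(a constant gene carries no between-sample information and, pooled
geometrically, would only compress every score toward zero).

A signature score is the geometric mean of the normalised values of the
program's genes, computed as exp(mean(log(y + ε))) − ε with pseudocount
ε = 10⁻⁶ and clipped at zero. The pseudocount is required, not cosmetic:
min–max normalisation guarantees every gene attains exactly 0 in at least one
sample, which would otherwise annihilate the product. ε = 10⁻⁶ is small
enough that a sample whose program genes all equal v scores v to within
float precision, yet large enough to keep log() finite. Gene symbols are
matched case-insensitively with a small alias map (SNAIL→SNAI1, SLUG→SNAI2,
the literature names of two EMT regulators); a signature must find at least
50% of its genes in the matrix or scoring refuses, listing what is missing.

Scores are then fractionally ranked within the cohort (tie-averaged ranks
divided by n, values in (0, 1]) and the Dichotomy Index is the ratio of the
ranked indices, DI = prolif_rank / migr_rank. Ranks rather than raw
geometric means are used because the two programs differ in size (e.g. 70 vs
9 genes) and therefore in score dispersion; ranking makes the ratio
scale-free, bounded by n, and invariant to any monotone per-cohort
transformation of the scores. Raw indices are kept in the output table so
the choice is auditable. DI is dichotomised at the cohort median (di >
median → high); the median is the least arbitrary two-group split when no
external cut-point is defined, and the threshold is recorded in the report.

## Statistics

* Pearson correlation between the ranked indices, per stage group and
  overall; two-sided p from the t transform; 95% CI from the Fisher z
  transform, z ± 1.959964/√(n−3), tanh-backed. The CI is undefined at
  |r| = 1 and degenerates to the point estimate there.
* Benjamini–Hochberg adjustment (statsmodels) over the stage-wise
  correlation family within one cohort. The overall-cohort correlation is
  not a member of that family (it is not independent of the stage groups)
  and is reported with p_adj = p.
* Independent t test (Welch by default; pooled by flag). The companion
  F = t² with (1, df) is reported as well because two-group comparisons are
  conventionally printed as one-way-ANOVA F in clinical tables. Two
  identical zero-variance groups return t = 0, p = 1 rather than NaN.
* Pearson χ² of independence on the 2×k di_category × stage table, no
  continuity correction; zero margins are rejected.
* Pooled two-proportion z for core-gene overlap fractions:
  z = |p₁ − p₂| / √(p̂(1−p̂)(1/n₁ + 1/n₂)), two-sided normal p, no
  continuity correction. This convention reproduces the published worked
  values (15.086 and 19.538) exactly at three decimals.

## Enrichment engine

Genes are ranked by signal-to-noise between two phenotype classes,
(μ_A − μ_B)/(σ_A + σ_B), each class σ floored at max(0.2·|μ|, 0.2) and
computed with ddof = 1; ties are broken lexicographically by gene id so the
ranking is deterministic across platforms. The enrichment score is the
signed maximum deviation of the weighted Kolmogorov–Smirnov running sum
(hits advance by |score|^weight normalised over hits, misses retreat by
1/(N − N_hit); weight 1 by default). If every hit score is zero the hit
increments fall back to equal weights 1/N_hit. The running sum terminates
at 0 by construction. The leading edge ("core enrichment") is the set genes
at or before the peak for a positive ES, at or after it for a negative ES.

Significance uses phenotype permutation with a seeded generator (≥100
permutations enforced; 1000 by default): the nominal p is the fraction of
same-sign permuted ES at least as extreme as the observed ES (0 when no
same-sign permutation exists); NES divides ES by the mean magnitude of the
same-sign permuted ES (falling back to the overall mean magnitude when a
sign stratum is empty); the FDR q compares the pooled sign-stratified
permuted NES distribution with the observed NES distribution, clipped to
[0, 1]. Identical seeds give bitwise-identical results.

Core genes per category are the union of leading edges over sets passing
p < 0.05 and q < 0.25, split by enrichment direction (positive pole →
first class). The published analysis compares shared-core counts between
category pairs but does not define the denominators of its printed
fractions; this package uses k = |coreX ∩ coreY| over n = |coreX ∪ coreY|
for each pairing and feeds the two fractions to the two-proportion z test.

## Verdict rule

The verdict is a function of the stage-wise correlations at adjusted
α = 0.05: at least one significant and all significant negative → MPD; all
significant positive → SMP; none significant → PR; mixed signs →
indeterminate. Requiring at least one significant stage prevents an
underpowered cohort from being labelled MPD on sign alone. The dominance
shift direction is reported only when the DI t test or χ² reaches α; a DI
drop from the first to the second group is a shift toward migration
dominance. Subgroup (e.g. molecular subtype) correlations require at least
10 samples per subgroup; smaller subgroups are reported as skipped because
correlation estimates at single-digit n are uninformative.

## Synthetic cohorts

The generator draws latent per-sample activities (P, M) from a bivariate
normal with unit variances and correlation ρ — the single parameter that
realises the three hypotheses (MPD ρ<0, SMP ρ>0, PR ρ=0) — and a stage
shift δ (latent SD units) that moves early samples to (+δ, −δ) and late
samples to (−δ, +δ), encoding dominance as a population-composition effect.
Program genes load linearly on their activity with loadings uniform in
[0.5, 1.5] plus N(0, σ²) noise; background genes are N(0, 1); the matrix is
shifted so its global minimum is zero (min–max normalisation is
shift-invariant, so this only enforces the nonnegativity invariant).

Defaults: 70 proliferation genes, 9 migration genes (named after the EMT
regulators so the shipped GMT applies), 150 background genes, σ = 0.5.
Presets fix the cohort shapes being emulated — crc_like 333 early / 293
late with ρ = −0.25, δ = 0.35; gc_like 59/382 with ρ = −0.55, δ = 0.6
(the gastric-like cohort shows the stronger dominance shift); null_model,
smp_like (ρ = +0.5) and pr_like (δ = 0.75) use 200/200 samples. δ and σ
values were chosen once as plausible moderate effects; they are study
conditions, not tuning knobs.

What the generator does **not** emulate: count-based noise (RNA-Seq
overdispersion), library-size and batch effects, tumour purity, correlated
background genes, and missing clinical annotations. Passing tests therefore
demonstrate that the pipeline recovers planted population-level structure
under clean linear-Gaussian conditions — not that real cohorts satisfy the
model's assumptions.

## Problem sizes and numerical choices

The test suite and acceptance script run calibrations at deliberately
modest sizes: verdict calibration over 50 (tests) or 25 (script) seeded
cohorts per preset with GSEA disabled (the verdict depends only on the
correlations), GSEA null calibration over 4 seeds × 50 null sets at 200
permutations, and the enrichment-score oracle over a few hundred random
instances with N ≤ 30. Floating-point tolerances: ES agrees with
brute-force enumeration to 1e-9; round-trip file I/O preserves 6
significant digits; reported tables round to 3 decimals at serialisation,
never internally.

## Known limitations

* The proliferation signature is user-supplied; the package ships no CIN70
  gene list and validates coverage instead of hard-coding membership.
* The enrichment FDR is the permutation-ratio estimator; with very few gene
  sets it is coarse (granularity 1/#sets in the observed stratum).
* One published confidence interval (r = −0.572, n = 407) cannot be
  reproduced exactly from its printed three-decimal inputs; the bounds
  computed from the rounded r differ by ~0.001, consistent with the source
  having used the unrounded correlation.
* Stage-group vocabularies are a closed set (early/late/metastasis/unknown);
  mapping raw TNM strings is the caller's responsibility via `stage_map`.
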