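"""Readers and writers for the tabular formats the pipeline touches.

Expression tables (GCT 1.2 or plain TSV, genes as rows), gene sets (GMT),
categorical phenotype labels (CLS) and clinical annotation tables (TSV) are
all parsed into validated in-memory containers.  Parsers never drop records
silently: every collapse or remapping is emitted through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGE_GROUPS = ("early", "late", "metastasis", "unknown")

#: Gene symbols are matched case-insensitively and through this alias map.
#: SNAIL and SLUG are the literature names of the official symbols SNAI1/SNAI2.
GENE_ALIASES = {"SNAIL": "SNAI1", "SLUG": "SNAI2"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed object violates a container invariant."""


def canonical_symbol(symbol: str) -> str:
    """Upper-case a gene symbol and resolve known aliases."""
    up = symbol.strip().upper()
    return GENE_ALIASES.get(up, up)


def _check_unique_ids(ids: Sequence[str], what: str) -> None:
    if any(not isinstance(i, str) or not i for i in ids):
        raise ValidationError(f"empty or non-string {what} identifier")
    if len(set(ids)) != len(ids):
        dupes = pd.Series(ids).value_counts()
        dupes = dupes[dupes > 1].index.tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Dense gene x sample matrix of finite, nonnegative expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValidationError("expression matrix must be non-empty")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique_ids(self.gene_ids, "gene")
        _check_unique_ids(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free collection of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set name must be non-empty")
        genes = tuple(self.genes)
        if len(genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClinicalTable:
    """Per-sample stage annotation (early/late/metastasis/unknown) + optional subgroup."""

    table: pd.DataFrame  # columns: sample_id, stage_group, raw_stage, subgroup

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("raw_stage", "subgroup"):
            if col not in df.columns:
                df[col] = None
        missing = {"sample_id", "stage_group"} - set(df.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        _check_unique_ids(df["sample_id"].tolist(), "sample")
        bad = set(df["stage_group"]) - set(STAGE_GROUPS)
        if bad:
            raise ValidationError(f"stage_group outside vocabulary {STAGE_GROUPS}: {sorted(bad)}")
        self.table = df[["sample_id", "stage_group", "raw_stage", "subgroup"]].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def stage_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["stage_group"]


# ---------------------------------------------------------------------------
# expression tables


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    dup = frame.index.duplicated(keep=False)
    if dup.any():
        n = int(pd.Index(frame.index[dup]).nunique())
        logger.warning(
            "collapsed %d duplicated gene identifier(s) by arithmetic mean "
            "(%d rows affected)", n, int(dup.sum())
        )
        frame = frame.groupby(level=0, sort=False).mean()
    return frame


def read_expression_table(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 or TSV (genes x samples) expression table.

    Duplicate gene rows are collapsed by arithmetic mean with a logged
    warning; duplicate sample columns or negative values raise.
    """
    path = Path(path)
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    if fmt not in {"gct", "tsv"}:
        raise ValueError(f"unknown expression format {fmt!r}")

    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"line 1: expected GCT version '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError("line 2: expected '<n_genes>\\t<n_samples>'")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise FormatError(f"line 2: non-integer dimensions {dims}") from exc
            body = pd.read_csv(fh, sep="\t", header=0, dtype={0: str})
        if body.shape[1] != n_samples + 2:
            raise FormatError(
                f"declared {n_samples} samples but header has {body.shape[1] - 2} sample columns"
            )
        if body.shape[0] != n_genes:
            raise FormatError(f"declared {n_genes} data rows but found {body.shape[0]}")
        frame = body.set_index(body.columns[0]).drop(columns=body.columns[1])
    else:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
        if frame.shape[1] == 0:
            raise FormatError("TSV expression table has no sample columns")

    _check_unique_ids(list(frame.columns), "sample")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame = _collapse_duplicate_genes(frame)
    return ExpressionMatrix.from_frame(frame)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           format: str | None = None) -> None:
    """Write an expression table; round-trips to 6 significant digits."""
    matrix.validate()
    path = Path(path)
    fmt = format or ("gct" if path.suffix.lower() == ".gct" else "tsv")
    frame = matrix.to_frame()
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = frame.reset_index()
            out.insert(1, "Description", "na")
            out.columns = ["Name", "Description", *matrix.sample_ids]
            out.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    elif fmt == "tsv":
        frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    else:
        raise ValueError(f"unknown expression format {fmt!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line, name TAB description TAB genes..."""
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT line needs >=3 tab-separated fields")
            name, genes = fields[0], [g for g in fields[2:] if g.strip()]
            if name in names:
                raise ValidationError(f"line {lineno}: duplicate gene set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("gene set %s: removed %d duplicate gene(s)",
                               name, len(genes) - len(deduped))
            sets.append(GeneSet(name, tuple(deduped)))
            names.add(name)
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# CLS phenotype labels


def read_cls(path: str | Path) -> list[str]:
    """Read a categorical CLS file into a list of per-sample labels."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError("CLS file needs 3 non-empty lines")
    header = lines[0].split()
    if len(header) != 3:
        raise FormatError("CLS line 1 must be '<n_samples> <n_classes> 1'")
    n, k = int(header[0]), int(header[1])
    name_line = lines[1].split()
    if name_line[0] != "#" or len(name_line) - 1 != k:
        raise FormatError(f"CLS line 2 must be '# <name_1> ... <name_{k}>'")
    names = name_line[1:]
    tokens = lines[2].split()
    if len(tokens) != n:
        raise FormatError(f"CLS declares {n} samples but body has {len(tokens)} labels")
    # the label row may use class names or 0-based indices into line 2
    if all(t.isdigit() and int(t) < k for t in tokens):
        labels = [names[int(t)] for t in tokens]
    else:
        unknown = set(tokens) - set(names)
        if unknown:
            raise FormatError(f"CLS labels not declared on line 2: {sorted(unknown)}")
        labels = tokens
    return labels


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    labels = list(labels)
    if not labels:
        raise ValidationError("cannot write empty label list")
    classes = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(labels)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels) + "\n")


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical_table(path: str | Path, stage_map: dict[str, str] | None = None) -> ClinicalTable:
    """Read a clinical TSV with sample_id and stage_group columns.

    ``stage_map`` optionally maps raw stage strings (e.g. "IIA") to the
    closed vocabulary; anything unresolvable becomes "unknown" with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "stage_group"} - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing mandatory column(s): {sorted(missing)}")
    extra_map = {k.strip().lower(): v for k, v in (stage_map or {}).items()}
    raw = df["stage_group"].fillna("unknown").str.strip()
    folded = raw.str.lower().map(lambda s: extra_map.get(s, s))
    unmapped = ~folded.isin(STAGE_GROUPS)
    if unmapped.any():
        logger.warning("mapped %d unrecognised stage label(s) to 'unknown': %s",
                       int(unmapped.sum()), sorted(set(raw[unmapped]))[:5])
        folded = folded.where(~unmapped, "unknown")
    out = pd.DataFrame({
        "sample_id": df["sample_id"],
        "stage_group": folded,
        "raw_stage": df["raw_stage"] if "raw_stage" in df.columns else None,
        "subgroup": df["subgroup"] if "subgroup" in df.columns else None,
    })
    return ClinicalTable(out)


def write_clinical_table(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)
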