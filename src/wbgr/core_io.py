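"""Readers and writers for every on-disk artifact the pipeline consumes.

Conventions
-----------
* Count matrices, sample sheets, DEG tables and target tables are
  tab-separated UTF-8 text.  Counts are genes-as-rows with a header row of
  sample ids and first header cell ``gene_id``.
* Gene-set modules use the standard GMT format (one module per line:
  id, description, genes...).
* qPCR Ct sheets are comma-separated.

Every reader validates its input and raises :class:`~wbgr.errors.FormatError`
(malformed file, with the offending line/row/column named) or
:class:`~wbgr.errors.ValidationError` (well-formed but invariant-violating).
Writers are exact inverses of the readers: write -> read is the identity.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .types import (
    CountMatrix,
    ModuleFramework,
    PanelDefinition,
    QpcrSheet,
    SampleSheet,
    SAMPLE_SHEET_COLUMNS,
    TargetTable,
)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path: str | os.PathLike, assay: str = "mRNA") -> CountMatrix:
    """Read a genes-as-rows TSV count matrix.

    The file must have a header row of sample ids (first cell ``gene_id``)
    and nonnegative integer cells.  Row and column order are preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"count matrix {path} has no sample columns")
    values = np.empty(df.shape, dtype=np.int64)
    for j, sample in enumerate(df.columns):
        col = df.iloc[:, j].to_numpy()
        for i, cell in enumerate(col):
            gene = df.index[i]
            if cell == "":
                raise FormatError(
                    f"{path}: empty count cell for gene {gene!r}, sample {sample!r}"
                )
            try:
                x = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric count {cell!r} for gene {gene!r}, "
                    f"sample {sample!r}"
                ) from None
            if x != int(x):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} for gene {gene!r}, "
                    f"sample {sample!r}"
                )
            if x < 0:
                raise FormatError(
                    f"{path}: negative count {cell!r} for gene {gene!r}, "
                    f"sample {sample!r}"
                )
            values[i, j] = int(x)
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))
    out.index.name = "gene_id"
    return CountMatrix(out, assay=assay)


def write_count_matrix(matrix: CountMatrix, path: str | os.PathLike) -> None:
    df = matrix.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path: str | os.PathLike) -> SampleSheet:
    """Read a TSV sample sheet; unknown columns are kept as annotations."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | os.PathLike) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene-set modules


def read_gmt_modules(path: str | os.PathLike) -> ModuleFramework:
    """Parse a GMT file into a :class:`ModuleFramework`.

    Genes are de-duplicated per module; a line with fewer than three
    tab-separated fields is a format error naming the line number.
    """
    modules: dict[str, set[str]] = {}
    annotations: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT requires id, description and at least one gene"
                )
            mid, desc, genes = fields[0], fields[1], fields[2:]
            if mid in modules:
                raise ValidationError(f"{path}: duplicate module id {mid!r}")
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: module {mid!r} has no genes")
            modules[mid] = set(genes)
            annotations[mid] = desc
    return ModuleFramework(modules=modules, annotations=annotations)


def write_gmt_modules(framework: ModuleFramework, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mid in framework.modules:
            desc = framework.annotations.get(mid, "")
            genes = sorted(framework.modules[mid])
            fh.write("\t".join([mid, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# external DEG tables


def read_deg_list(path: str | os.PathLike) -> pd.DataFrame:
    """Read an external-cohort DEG table (gene_id, log2fc, fdr).

    Adds a ``direction`` column from the sign of log2fc; a log2fc of exactly
    0 yields direction ``"none"`` (such genes are later excluded from
    direction-aware overlap sets).  Rows with missing or non-numeric log2fc
    or fdr are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse DEG table {path}: {exc}") from exc
    missing = [c for c in ("gene_id", "log2fc", "fdr") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("log2fc", "fdr"):
        vals = []
        for i, cell in enumerate(df[col]):
            if cell == "":
                raise FormatError(
                    f"{path}: missing {col} for gene {df['gene_id'].iloc[i]!r}"
                )
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric {col} value {cell!r} for gene "
                    f"{df['gene_id'].iloc[i]!r}"
                ) from None
        df[col] = vals
    lfc = df["log2fc"].to_numpy()
    df["direction"] = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return df[["gene_id", "log2fc", "fdr", "direction"]]


def write_deg_list(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table[["gene_id", "log2fc", "fdr"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# miRNA target tables


def read_target_table(path: str | os.PathLike) -> TargetTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse target table {path}: {exc}") from exc
    missing = [
        c for c in ("mirna_id", "target_gene_id", "evidence") if c not in df.columns
    ]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return TargetTable(df)


def write_target_table(table: TargetTable, path: str | os.PathLike) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR Ct sheets


def read_qpcr_sheet(
    path: str | os.PathLike, reference_map: Mapping[str, str] | None = None
) -> QpcrSheet:
    """Read a CSV of triplicate Ct values.

    Columns: sample_id, group, gene_id, rna_class, replicate_index, ct_value.
    ``reference_map`` overrides the default reference genes
    (mRNA->GAPDH, miRNA->U6, lncRNA->18S).
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse qPCR sheet {path}: {exc}") from exc
    req = ["sample_id", "group", "gene_id", "rna_class", "replicate_index", "ct_value"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col, cast in (("replicate_index", int), ("ct_value", float)):
        vals = []
        for i, cell in enumerate(df[col]):
            try:
                vals.append(cast(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric {col} value {cell!r} on data row {i + 1}"
                ) from None
        df[col] = vals
    kwargs = {} if reference_map is None else {"reference_map": dict(reference_map)}
    return QpcrSheet(df, **kwargs)


def write_qpcr_sheet(sheet: QpcrSheet, path: str | os.PathLike) -> None:
    sheet.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# panels and config


def read_panel(path: str | os.PathLike) -> PanelDefinition:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise FormatError(f"cannot parse panel definition {path}: {exc}") from exc
    missing = [
        c for c in ("gene_id", "rna_class", "expected_direction") if c not in df.columns
    ]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return PanelDefinition(df)


def write_panel(panel: PanelDefinition, path: str | os.PathLike) -> None:
    panel.entries.to_csv(path, sep="\t", index=False)


def read_config(path: str | os.PathLike) -> dict:
    """Load a YAML configuration mapping (used by the CLI)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg
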