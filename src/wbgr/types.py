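"""Core in-memory containers shared by every wbgr stage.

All tabular objects wrap :class:`pandas.DataFrame` and validate their
invariants on construction, so downstream code can assume clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

GROUPS = ("control", "GBM")
SEXES = ("M", "F")
GR_STATUSES = ("pre", "post")
ASSAYS = ("mRNA", "miRNA")
RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
DIRECTIONS = ("up", "down", "none")

#: Required columns of a sample sheet, in canonical order.
SAMPLE_SHEET_COLUMNS = ("sample_id", "donor_id", "group", "sex", "gr_status", "assay")


def _check_enum(series: pd.Series, allowed: tuple[str, ...], what: str) -> None:
    bad = sorted(set(series.astype(str)) - set(allowed))
    if bad:
        raise ValidationError(
            f"invalid {what} value(s) {bad}; allowed values are {sorted(allowed)}"
        )


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Cells must be nonnegative integers; every sample must
        have at least one read.
    assay
        ``"mRNA"`` or ``"miRNA"``.
    """

    counts: pd.DataFrame
    assay: str = "mRNA"

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}; allowed: {list(ASSAYS)}")
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifier(s): {dups[:5]}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifier(s): {dups[:5]}")
        arr = c.to_numpy()
        if arr.size == 0:
            raise ValidationError("count matrix is empty")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric cells")
        if np.isnan(arr.astype(float)).any():
            g, s = np.argwhere(np.isnan(arr.astype(float)))[0]
            raise ValidationError(
                f"missing count for gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for gene {c.index[g]!r}, sample {c.columns[s]!r}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                g, s = np.argwhere(arr != np.round(arr))[0]
                raise ValidationError(
                    f"non-integer count for gene {c.index[g]!r}, sample {c.columns[s]!r}"
                )
            self.counts = c.astype(np.int64)
        colsums = self.counts.sum(axis=0)
        if (colsums <= 0).any():
            bad = colsums.index[colsums <= 0].tolist()
            raise ValidationError(f"sample(s) with zero total counts: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], assay=self.assay)


@dataclass
class SampleSheet:
    """Per-sample annotations: donor, disease group, sex, GR status, assay.

    Unknown extra columns are preserved untouched as opaque annotations.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample sheet missing required column(s): {missing}")
        d = self.data
        if d["sample_id"].duplicated().any():
            dups = d.loc[d["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dups}")
        _check_enum(d["group"], GROUPS, "group")
        _check_enum(d["sex"], SEXES, "sex")
        _check_enum(d["gr_status"], GR_STATUSES, "gr_status")
        _check_enum(d["assay"], ASSAYS, "assay")
        key = d[["donor_id", "gr_status", "assay"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"duplicate (donor_id, gr_status, assay) combination: {dup}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def require_match(self, matrix: CountMatrix) -> None:
        """Raise unless this sheet covers exactly the matrix's samples."""
        a, b = set(self.sample_ids), set(matrix.sample_ids)
        if a != b:
            raise ValidationError(
                f"sample sheet / matrix mismatch: sheet-only={sorted(a - b)[:5]}, "
                f"matrix-only={sorted(b - a)[:5]}"
            )

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all column==value conditions, in sheet order."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in conditions.items():
            mask &= self.data[col] == val
        return list(self.data.loc[mask, "sample_id"])

    def donor_of(self) -> pd.Series:
        """Mapping sample_id -> donor_id."""
        return self.data.set_index("sample_id")["donor_id"]

    def group_of(self) -> pd.Series:
        """Mapping sample_id -> group."""
        return self.data.set_index("sample_id")["group"]


@dataclass
class ModuleFramework:
    """A named repertoire of gene sets (blood transcriptional modules)."""

    modules: dict[str, set[str]]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, genes in self.modules.items():
            if not genes:
                raise ValidationError(f"module {mid!r} is empty")

    def __len__(self) -> int:
        return len(self.modules)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModuleFramework):
            return NotImplemented
        return self.modules == other.modules and self.annotations == other.annotations


@dataclass
class TargetTable:
    """miRNA -> target-gene interactions with evidence level."""

    data: pd.DataFrame  # columns: mirna_id, target_gene_id, evidence

    def __post_init__(self) -> None:
        req = ["mirna_id", "target_gene_id", "evidence"]
        missing = [c for c in req if c not in self.data.columns]
        if missing:
            raise ValidationError(f"target table missing column(s): {missing}")
        _check_enum(self.data["evidence"], ("validated", "predicted"), "evidence")
        if self.data[req].duplicated().any():
            dup = self.data[req][self.data[req].duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate target-table row: {dup}")

    def validated_pairs(self) -> set[tuple[str, str]]:
        v = self.data[self.data["evidence"] == "validated"]
        return set(zip(v["mirna_id"], v["target_gene_id"]))


#: Reference genes used to normalize qPCR Ct values, by RNA class.
DEFAULT_REFERENCE_MAP: dict[str, str] = {
    "mRNA": "GAPDH",
    "miRNA": "U6",
    "lncRNA": "18S",
}


@dataclass
class QpcrSheet:
    """Long-format qPCR Ct measurements plus the reference-gene map.

    ``data`` columns: sample_id, group, gene_id, rna_class, replicate_index,
    ct_value.  Reference genes appear as ordinary rows carrying the RNA class
    they normalize.
    """

    data: pd.DataFrame
    reference_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_MAP)
    )

    def __post_init__(self) -> None:
        req = ["sample_id", "group", "gene_id", "rna_class", "replicate_index", "ct_value"]
        missing = [c for c in req if c not in self.data.columns]
        if missing:
            raise ValidationError(f"qPCR sheet missing column(s): {missing}")
        _check_enum(self.data["group"], GROUPS, "group")
        _check_enum(self.data["rna_class"], RNA_CLASSES, "rna_class")
        ct = self.data["ct_value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or (ct <= 0).any():
            bad = self.data.loc[~np.isfinite(ct) | (ct <= 0)].iloc[0]
            raise ValidationError(
                f"non-finite or non-positive Ct for sample {bad['sample_id']!r}, "
                f"gene {bad['gene_id']!r}"
            )
        samples = set(self.data["sample_id"])
        for rc in sorted(set(self.data["rna_class"])):
            ref = self.reference_map.get(rc)
            if ref is None:
                raise ValidationError(f"no reference gene declared for rna_class {rc!r}")
            have = set(self.data.loc[self.data["gene_id"] == ref, "sample_id"])
            if have != samples:
                raise ValidationError(
                    f"reference gene {ref!r} ({rc}) missing Ct rows for "
                    f"sample(s) {sorted(samples - have)[:5]}"
                )

    def reference_genes(self) -> set[str]:
        return set(self.reference_map.values())


@dataclass
class PanelDefinition:
    """A biomarker panel: gene, RNA class, and the direction expected in GBM."""

    entries: pd.DataFrame  # columns: gene_id, rna_class, expected_direction

    def __post_init__(self) -> None:
        req = ["gene_id", "rna_class", "expected_direction"]
        missing = [c for c in req if c not in self.entries.columns]
        if missing:
            raise ValidationError(f"panel definition missing column(s): {missing}")
        if self.entries["gene_id"].duplicated().any():
            dups = self.entries.loc[self.entries["gene_id"].duplicated(), "gene_id"]
            raise ValidationError(f"duplicate panel gene(s): {dups.tolist()}")
        _check_enum(self.entries["rna_class"], RNA_CLASSES, "rna_class")
        _check_enum(self.entries["expected_direction"], ("up", "down"), "expected_direction")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries["gene_id"])

    def directions(self) -> dict[str, str]:
        return dict(zip(self.entries["gene_id"], self.entries["expected_direction"]))
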