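"""Biomarker-panel selection and qPCR validation analytics.

Panel candidates come from control-centered log2 expression: a gene's
frequency is the share of GBM samples that move past a margin in the gene's
expected direction, candidates must exceed 50% frequency, and the panel
must stay at least half upregulated (a practical constraint for assay
design).  Validation uses the 2^-ddCt model: triplicate Ct values are
averaged, referenced against the class-specific housekeeping gene
(GAPDH/U6/18S), centered on the control group, and compared with one-sided
t-tests oriented by each marker's expected direction.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DesignError,
    EmptyOutputError,
    InsufficientDataError,
    ValidationError,
)
from .types import PanelDefinition, QpcrSheet, SampleSheet


def load_gbm_dx_panel() -> PanelDefinition:
    """The bundled 10-marker GBM-Dx panel (7 mRNA, 1 lncRNA, 2 miRNA).

    Upregulated: MMP9, TMEM92, C1orf226, CD163, LINC00482, miR-3918;
    downregulated: AK5, CD200, MICU3, miR-760.
    """
    with resources.as_file(
        resources.files("wbgr.data").joinpath("gbm_dx_panel.tsv")
    ) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return PanelDefinition(df)


def infer_rna_class(gene_id: str) -> str:
    """Heuristic RNA class from the identifier naming convention."""
    low = gene_id.lower()
    if low.startswith(("mir-", "hsa-mir", "hsa-let", "let-")):
        return "miRNA"
    if low.startswith("linc") or "-as" in low:
        return "lncRNA"
    return "mRNA"


def compute_sample_frequency(
    centered: pd.DataFrame,
    sheet: SampleSheet,
    deg_directions: Mapping[str, str],
    margin: float = 0.5,
) -> pd.Series:
    """Per-gene fraction of GBM samples consistent with the DEG direction.

    ``centered`` must be control-mean-centered log2 values (output of
    :func:`wbgr.dge.center_on_control_mean`).  An up-gene's frequency is
    the share of GBM samples whose centered value exceeds +margin; a
    down-gene's, the share below -margin.  Larger margins can only lower
    frequencies.
    """
    if margin < 0:
        raise ValidationError(f"margin must be >= 0; got {margin}")
    gbm = [s for s in sheet.samples_where(group="GBM") if s in centered.columns]
    if not gbm:
        raise DesignError("no GBM samples in the centered matrix")
    genes = [g for g in deg_directions if g in centered.index]
    out = {}
    for g in genes:
        vals = centered.loc[g, gbm].to_numpy(dtype=float)
        if deg_directions[g] == "up":
            hits = vals > margin
        else:
            hits = vals < -margin
        out[g] = float(hits.sum()) / len(gbm)
    freq = pd.Series(out, name="frequency")
    freq.index.name = "gene_id"
    return freq


def select_panel_candidates(
    frequencies: pd.Series,
    deg_directions: Mapping[str, str],
    min_frequency: float = 0.5,
    min_up_share: float = 0.5,
    target_size: int | None = None,
    log2fc: Mapping[str, float] | None = None,
    rna_classes: Mapping[str, str] | None = None,
) -> PanelDefinition:
    """Frequency-based panel selection.

    Candidates are the genes with frequency strictly above
    ``min_frequency``.  If the upregulated share among candidates falls
    below ``min_up_share``, the lowest-frequency down-genes are dropped
    until it holds.  With ``target_size`` set, the top-frequency candidates
    are kept subject to the same constraint; ties break by larger |log2fc|
    then lexicographic gene id.
    """
    lfc = dict(log2fc or {})
    cands = [g for g in frequencies.index if frequencies[g] > min_frequency]
    if not cands:
        raise EmptyOutputError(
            f"no gene exceeds frequency {min_frequency}; panel would be empty"
        )
    # priority: higher frequency first, then larger |log2fc|, then gene id
    order = sorted(
        cands, key=lambda g: (-frequencies[g], -abs(lfc.get(g, 0.0)), g)
    )

    def up_share(genes: list[str]) -> float:
        ups = sum(1 for g in genes if deg_directions[g] == "up")
        return ups / len(genes) if genes else 1.0

    def enforce_up_share(genes: list[str]) -> list[str]:
        # down-genes are dropped while the up-share does not clear the bound;
        # the boundary itself counts as failing, so the result is strictly
        # more than half up whenever any down gene was dropped
        genes = list(genes)
        while genes and min_up_share > 0 and up_share(genes) <= min_up_share:
            downs = [g for g in genes if deg_directions[g] == "down"]
            if not downs:
                break
            genes.remove(downs[-1])  # lowest-priority down gene
        return genes

    selected = enforce_up_share(order)
    if target_size is not None and len(selected) > target_size:
        selected = enforce_up_share(selected[:target_size])
    if not selected:
        raise EmptyOutputError("up-share constraint removed every candidate")
    entries = pd.DataFrame(
        {
            "gene_id": selected,
            "rna_class": [
                (rna_classes or {}).get(g, infer_rna_class(g)) for g in selected
            ],
            "expected_direction": [deg_directions[g] for g in selected],
        }
    )
    return PanelDefinition(entries)


def ddct_analysis(sheet: QpcrSheet) -> pd.DataFrame:
    """2^-ddCt quantification of a qPCR sheet.

    Triplicates are averaged on the Ct scale; dCt = Ct_target -
    Ct_reference (reference chosen per RNA class); ddCt subtracts the
    control-group mean dCt per gene; fold change = 2^-ddCt and log2fc =
    -ddCt, so control-group log2fc averages to zero by construction.

    Returns one row per (sample, gene) with columns group, rna_class,
    mean_ct, ref_ct, delta_ct, ddct, fold_change, log2fc.
    """
    d = sheet.data
    mean_ct = (
        d.groupby(["sample_id", "group", "gene_id", "rna_class"])["ct_value"]
        .mean()
        .reset_index()
        .rename(columns={"ct_value": "mean_ct"})
    )
    ref_rows = {}
    for rc, ref_gene in sheet.reference_map.items():
        sub = mean_ct.loc[mean_ct["gene_id"] == ref_gene, ["sample_id", "mean_ct"]]
        ref_rows[rc] = dict(zip(sub["sample_id"], sub["mean_ct"]))
    out = mean_ct.copy()
    ref_ct = []
    for _, row in out.iterrows():
        rc = row["rna_class"]
        refs = ref_rows.get(rc, {})
        if row["sample_id"] not in refs:
            raise ValidationError(
                f"no reference Ct for rna_class {rc!r} in sample {row['sample_id']!r}"
            )
        ref_ct.append(refs[row["sample_id"]])
    out["ref_ct"] = ref_ct
    out["delta_ct"] = out["mean_ct"] - out["ref_ct"]
    ctrl = out.loc[out["group"] == "control"]
    if ctrl.empty:
        raise DesignError("qPCR sheet has no control samples")
    ctrl_mean = ctrl.groupby("gene_id")["delta_ct"].mean()
    missing = sorted(set(out["gene_id"]) - set(ctrl_mean.index))
    if missing:
        raise DesignError(f"gene(s) without control-group measurements: {missing[:5]}")
    out["ddct"] = out["delta_ct"] - out["gene_id"].map(ctrl_mean)
    out["fold_change"] = np.exp2(-out["ddct"])
    out["log2fc"] = -out["ddct"]
    return out


def compare_groups_onesided(
    ddct: pd.DataFrame, expected_direction: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene one-sided Welch-free two-sample t-test on ddCt log2fc values.

    The alternative is oriented by the gene's expected direction: "up"
    tests GBM > control, "down" tests GBM < control.  Identical degenerate
    groups give p = 0.5 with a warning.
    """
    rows = []
    for g, direction in expected_direction.items():
        sub = ddct.loc[ddct["gene_id"] == g]
        a = sub.loc[sub["group"] == "GBM", "log2fc"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == "control", "log2fc"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"gene {g!r} needs >= 2 samples per group; got {len(a)} GBM, {len(b)} control"
            )
        alternative = "greater" if direction == "up" else "less"
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            warnings.warn(
                f"gene {g!r}: degenerate variance with equal means; p = 0.5",
                RuntimeWarning,
                stacklevel=2,
            )
            t, p = 0.0, 0.5
        else:
            t, p = stats.ttest_ind(a, b, alternative=alternative)
        rows.append((g, direction, float(t), float(p)))
    return pd.DataFrame(
        rows, columns=["gene_id", "expected_direction", "t_statistic", "p_value"]
    ).set_index("gene_id")


def patient_panel_profile(
    values: pd.DataFrame, panel: PanelDefinition
) -> pd.DataFrame:
    """Per-patient, per-specimen stacked panel profiles.

    ``values`` is long-format with columns patient_id, specimen (e.g.
    "blood"/"tissue"), gene_id and log2 value.  Returns one row per
    (patient, specimen) with a column per panel gene (NaN where the gene
    was not measured -- gaps, not zeros) and ``panel_sum``, the stacked sum
    over measured panel genes.
    """
    req = ["patient_id", "specimen", "gene_id", "value"]
    missing = [c for c in req if c not in values.columns]
    if missing:
        raise ValidationError(f"profile input missing column(s): {missing}")
    panel_genes = panel.gene_ids
    sub = values.loc[values["gene_id"].isin(panel_genes)]
    for pid, grp in values.groupby("patient_id"):
        if not set(grp["gene_id"]) & set(panel_genes):
            raise InsufficientDataError(f"patient {pid!r} has no panel genes measured")
    wide = sub.pivot_table(
        index=["patient_id", "specimen"], columns="gene_id", values="value", aggfunc="mean"
    )
    wide = wide.reindex(columns=panel_genes)
    wide["panel_sum"] = wide[panel_genes].sum(axis=1, skipna=True)
    return wide
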