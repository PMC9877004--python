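"""Module enrichment scoring and multi-cohort DEG evidence integration.

A blood transcriptional module's score is x - y, where x is the percentage
of its tested transcripts significantly upregulated and y the percentage
significantly downregulated; +100 means every tested transcript moved up.
Module-level significance uses a two-sided Fisher exact test of
significant-vs-not membership against the rest of the tested universe,
BH-corrected across modules and called at FDR <= 0.05.

Evidence integration counts, for every blood DEG, the number of independent
sources (blood plus external tissue cohorts) supporting it with a
consistent direction; genes supported by at least two sources are retained.
The miRNA layer contributes experimentally validated targets only.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .dge import ThresholdSpec, adjust_bh
from .errors import FormatError, ValidationError
from .types import ModuleFramework, TargetTable


def score_modules(
    deg_table: pd.DataFrame,
    framework: ModuleFramework,
    spec: ThresholdSpec,
    module_fdr: float = 0.05,
) -> pd.DataFrame:
    """Score every module against a DGE table.

    ``deg_table`` is a DGE table indexed by gene (as from
    :func:`wbgr.dge.fit_nb_dge`); significance of individual genes follows
    ``spec``.  The tested universe is the table's gene set; module genes
    outside it cannot contribute and modules with no tested gene are
    skipped with a warning.

    Returns a DataFrame with per-module n_genes, x, y, score, p_value,
    fdr and a ``significant`` flag at ``module_fdr``.
    """
    if len(framework) == 0:
        raise ValidationError("empty module framework")
    q = deg_table["fdr"] if spec.significance_on == "fdr" else deg_table["p_value"]
    fc_ok = np.exp2(np.abs(deg_table["log2fc"])) >= spec.min_fc
    sig = (q <= spec.max_q) & fc_ok
    sig_up = sig & (deg_table["direction"] == "up")
    sig_down = sig & (deg_table["direction"] == "down")
    universe = set(deg_table.index)
    n_sig_total = int(sig.sum())
    n_total = len(universe)

    rows = []
    for mid, genes in framework.modules.items():
        tested = sorted(genes & universe)
        if not tested:
            warnings.warn(
                f"module {mid!r} has no tested gene; skipped", RuntimeWarning, stacklevel=2
            )
            continue
        n = len(tested)
        n_up = int(sig_up.loc[tested].sum())
        n_down = int(sig_down.loc[tested].sum())
        n_sig = int(sig.loc[tested].sum())
        x = 100.0 * n_up / n
        y = 100.0 * n_down / n
        # 2x2: significant vs not, inside vs outside the module
        contingency = [
            [n_sig, n - n_sig],
            [n_sig_total - n_sig, (n_total - n) - (n_sig_total - n_sig)],
        ]
        _, p = stats.fisher_exact(contingency, alternative="two-sided")
        rows.append((mid, n, x, y, x - y, p))
    if not rows:
        raise ValidationError("no module overlaps the tested gene universe")
    out = pd.DataFrame(
        rows, columns=["module_id", "n_genes", "x", "y", "score", "p_value"]
    ).set_index("module_id")
    out["fdr"] = adjust_bh(out["p_value"].to_list())
    out["significant"] = out["fdr"] <= module_fdr
    return out


def _direction_map(source: pd.DataFrame, label: str) -> dict[str, str]:
    if source["gene_id"].duplicated().any():
        dups = source.loc[source["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene(s) in source {label!r}: {dups[:5]}")
    d = dict(zip(source["gene_id"], source["direction"]))
    return {g: v for g, v in d.items() if v in ("up", "down")}


def integrate_evidence(
    blood_degs: pd.DataFrame,
    tissue_deg_tables: list[pd.DataFrame],
    require_direction_match: bool = True,
) -> pd.DataFrame:
    """Per-blood-DEG evidence matrix across tissue cohorts.

    ``blood_degs`` and each tissue table need columns ``gene_id`` and
    ``direction`` (a DGE subset with its index reset, or a table from
    :func:`wbgr.core_io.read_deg_list`).  Genes with direction "none" carry
    no directional evidence and are ignored.  Support = 1 (blood) + number
    of tissue tables containing the gene, direction-consistent when
    ``require_direction_match`` is set.  The tissue-table list order does
    not affect support.
    """
    if not tissue_deg_tables:
        raise ValidationError("at least one tissue DEG table is required")
    blood = blood_degs.reset_index() if "gene_id" not in blood_degs.columns else blood_degs
    blood_dir = _direction_map(blood, "blood")
    tissue_dirs = [
        _direction_map(t, f"tissue_{i + 1}") for i, t in enumerate(tissue_deg_tables)
    ]
    rows = []
    for g in sorted(blood_dir):
        d = blood_dir[g]
        flags = []
        for td in tissue_dirs:
            hit = g in td and (not require_direction_match or td[g] == d)
            flags.append(bool(hit))
        rows.append((g, d, 1 + sum(flags), *flags))
    cols = ["gene_id", "direction", "support"] + [
        f"in_tissue_{i + 1}" for i in range(len(tissue_dirs))
    ]
    return pd.DataFrame(rows, columns=cols).set_index("gene_id")


def retain_multi_evidence(evidence: pd.DataFrame, min_support: int = 2) -> pd.DataFrame:
    """Genes supported by at least ``min_support`` sources, with provenance."""
    if min_support < 1:
        raise ValidationError(f"min_support must be >= 1; got {min_support}")
    return evidence.loc[evidence["support"] >= min_support].copy()


def map_dem_targets(
    dems: Iterable[str], targets: TargetTable, blood_degs: Iterable[str]
) -> set[str]:
    """Blood DEGs that are experimentally validated targets of the DEMs.

    Predicted-only interactions are ignored.
    """
    if len(targets.data) == 0:
        raise ValidationError("target table is empty")
    dems = set(dems)
    degs = set(blood_degs)
    validated = targets.validated_pairs()
    return {g for (m, g) in validated if m in dems and g in degs}


def filter_pathway_results(pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Keep pathway rows with FDR < 0.1 and fold enrichment > 1.4 (strict)."""
    for col in ("fdr", "fold_enrichment"):
        if col not in pathway_table.columns:
            raise FormatError(f"pathway table missing column {col!r}")
        try:
            pathway_table[col] = pathway_table[col].astype(float)
        except (TypeError, ValueError):
            raise FormatError(f"non-numeric value in pathway column {col!r}") from None
    keep = (pathway_table["fdr"] < 0.1) & (pathway_table["fold_enrichment"] > 1.4)
    return pathway_table.loc[keep].copy()
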