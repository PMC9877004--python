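"""Globin-dominance statistics for whole-blood RNA-seq.

For each sample, each hemoglobin-registry gene contributes a read fraction
alpha_i = count_i / total.  Their sum N_G is the sample's globin share, and
the globin noise reduction index

    N_G_RI = (1 - N_G) / N_G

measures how much of the library is informative, non-globin signal: higher
is better, and globin depletion should raise it by orders of magnitude.
This module also provides the paired pre/post N_G_RI comparison, the
per-sample gene-count binning used to show sensitivity gains across
abundance classes, and the pre/post expression-concordance check on
non-globin genes.

These statistics are defined for mRNA libraries; miRNA matrices bypass this
module since globin transcripts are mRNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PairingError, ValidationError
from .types import CountMatrix, SampleSheet

#: Half-open count-bin edges; genes below 5 counts are not binned.
COUNT_BIN_EDGES = (5, 20, 100, 500, 2000, 5000, 10000)
COUNT_BIN_LABELS = (
    "[5,20)",
    "[20,100)",
    "[100,500)",
    "[500,2000)",
    "[2000,5000)",
    "[5000,10000)",
    "[10000,inf)",
)


@dataclass(frozen=True)
class GlobinRegistry:
    """The set of hemoglobin-related genes whose reads count as globin noise."""

    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValidationError("globin registry must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)


def default_globin_registry() -> GlobinRegistry:
    """The bundled 15-gene registry.

    Ten protein-coding hemoglobin-subunit genes (HBA1, HBA2, HBB, HBD,
    HBE1, HBG1, HBG2, HBM, HBQ1, HBZ) plus five hemoglobin pseudogenes,
    totalling the 15 Ensembl-annotated hemoglobin-related genes.  The
    pseudogene picks are a package convention; override with
    :func:`load_globin_registry` if your annotation differs.
    """
    text = resources.files("wbgr.data").joinpath("globin_registry.txt").read_text()
    return GlobinRegistry(frozenset(line.strip() for line in text.splitlines() if line.strip()))


def load_globin_registry(path) -> GlobinRegistry:
    """Load a registry from a plain-text file, one gene id per line."""
    with open(path, "r", encoding="utf-8") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(genes) != len(set(genes)):
        raise ValidationError(f"duplicate gene id(s) in registry {path}")
    return GlobinRegistry(frozenset(genes))


@dataclass
class GlobinReport:
    """Per-sample globin statistics.

    Attributes
    ----------
    per_sample
        DataFrame indexed by sample_id with columns ``n_g`` (globin share)
        and ``ngri`` ((1 - N_G)/N_G; +inf where N_G is exactly 0).
    alpha
        Registry-genes x samples DataFrame of per-gene read fractions;
        registry genes absent from the matrix contribute 0.
    """

    per_sample: pd.DataFrame
    alpha: pd.DataFrame


def compute_globin_stats(matrix: CountMatrix, registry: GlobinRegistry) -> GlobinReport:
    """Compute alpha_i, N_G and N_G_RI for every sample.

    Requires at least one registry gene present in the matrix.  A sample
    with zero globin reads gets N_G_RI = +inf with a warning.
    """
    present = [g for g in matrix.gene_ids if g in registry.gene_ids]
    if not present:
        raise ValidationError("no registry gene present in the count matrix")
    totals = matrix.column_sums().to_numpy(dtype=float)
    reg_order = sorted(registry.gene_ids)
    alpha = pd.DataFrame(0.0, index=reg_order, columns=matrix.sample_ids)
    alpha.loc[present] = matrix.counts.loc[present].to_numpy() / totals
    n_g = alpha.sum(axis=0)
    with np.errstate(divide="ignore"):
        ngri = (1.0 - n_g) / n_g
    if (n_g == 0).any():
        zero = n_g.index[n_g == 0].tolist()
        warnings.warn(
            f"sample(s) {zero} have zero globin reads; N_G_RI reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    per_sample = pd.DataFrame({"n_g": n_g, "ngri": ngri})
    per_sample.index.name = "sample_id"
    return GlobinReport(per_sample=per_sample, alpha=alpha)


@dataclass
class PairedNgriSummary:
    """Paired pre/post comparison of N_G_RI by donor."""

    n_pairs: int
    mean_pre_ng: float
    mean_post_ng: float
    mean_pre_ngri: float
    mean_post_ngri: float
    t_statistic: float
    p_value: float


def summarize_ngri_paired(
    pre_stats: GlobinReport, post_stats: GlobinReport, pairing: SampleSheet
) -> PairedNgriSummary:
    """Two-sided paired t-test on per-donor N_G_RI differences.

    ``pairing`` must assign every pre and every post sample to a donor, and
    every donor must have exactly one sample on each side.  Exactly-zero
    variance of the differences yields p = 1.0 with a warning (this occurs
    legitimately at depletion efficiency 0).
    """
    donor_of = pairing.donor_of()
    status_of = pairing.data.set_index("sample_id")["gr_status"]

    def by_donor(report: GlobinReport, want: str) -> dict[str, float]:
        out = {}
        for sid in report.per_sample.index:
            if sid not in donor_of.index:
                raise PairingError(f"sample {sid!r} missing from the pairing sheet")
            if status_of[sid] != want:
                continue
            donor = donor_of[sid]
            if donor in out:
                raise PairingError(f"donor {donor!r} has multiple {want} samples")
            out[donor] = float(report.per_sample.loc[sid, "ngri"])
        return out

    pre = by_donor(pre_stats, "pre")
    post = by_donor(post_stats, "post")
    if set(pre) != set(post):
        odd = sorted(set(pre) ^ set(post))
        raise PairingError(f"donor(s) without a matched pre/post pair: {odd}")
    donors = sorted(pre)
    if len(donors) < 2:
        raise PairingError("paired t-test needs at least 2 donors")
    a = np.array([pre[d] for d in donors])
    b = np.array([post[d] for d in donors])
    diffs = b - a
    if np.allclose(diffs.std(ddof=1), 0.0):
        warnings.warn(
            "zero variance of paired N_G_RI differences; p-value reported as 1.0",
            RuntimeWarning,
            stacklevel=2,
        )
        t_stat, p = (0.0 if np.allclose(diffs, 0) else np.inf * np.sign(diffs.mean()), 1.0)
    else:
        t_stat, p = stats.ttest_rel(b, a)
    return PairedNgriSummary(
        n_pairs=len(donors),
        mean_pre_ng=float(pre_stats.per_sample["n_g"].mean()),
        mean_post_ng=float(post_stats.per_sample["n_g"].mean()),
        mean_pre_ngri=float(a.mean()),
        mean_post_ngri=float(b.mean()),
        t_statistic=float(t_stat),
        p_value=float(p),
    )


def bin_gene_counts(matrix: CountMatrix) -> pd.DataFrame:
    """Per-sample gene counts in the half-open abundance bins.

    Bins: [5,20), [20,100), [100,500), [500,2000), [2000,5000),
    [5000,10000), [10000,inf).  Genes with fewer than 5 counts in a sample
    are excluded from that sample's tally.
    """
    edges = np.array([*COUNT_BIN_EDGES, np.inf])
    out = {}
    for sid in matrix.sample_ids:
        col = matrix.counts[sid].to_numpy()
        hist, _ = np.histogram(col[col >= 5], bins=edges)
        out[sid] = hist
    df = pd.DataFrame(out, index=list(COUNT_BIN_LABELS)).T
    df.index.name = "sample_id"
    return df


def concordance_pre_post(
    pre: CountMatrix,
    post: CountMatrix,
    registry: GlobinRegistry,
    pairing: SampleSheet,
) -> pd.Series:
    """Per-donor Pearson R of log2(CPM + 1) over non-globin genes.

    CPM normalization makes the comparison invariant to the depth shift the
    depletion-and-resampling step introduces.  Requires at least 3 shared
    non-globin genes.
    """
    donor_of = pairing.donor_of()
    status_of = pairing.data.set_index("sample_id")["gr_status"]
    shared = [g for g in pre.gene_ids if g in set(post.gene_ids) and g not in registry.gene_ids]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared non-globin gene(s); need at least 3"
        )

    def log_cpm(matrix: CountMatrix, sid: str) -> np.ndarray:
        col = matrix.counts[sid].astype(float)
        cpm = col / col.sum() * 1e6
        return np.log2(cpm.loc[shared].to_numpy() + 1.0)

    pre_by_donor = {}
    post_by_donor = {}
    for matrix, store, want in ((pre, pre_by_donor, "pre"), (post, post_by_donor, "post")):
        for sid in matrix.sample_ids:
            if sid not in donor_of.index:
                raise PairingError(f"sample {sid!r} missing from the pairing sheet")
            if status_of[sid] == want:
                store[donor_of[sid]] = sid
    donors = sorted(set(pre_by_donor) & set(post_by_donor))
    if not donors:
        raise PairingError("no donor with both a pre and a post sample")
    r = {
        d: float(stats.pearsonr(log_cpm(pre, pre_by_donor[d]), log_cpm(post, post_by_donor[d]))[0])
        for d in donors
    }
    out = pd.Series(r, name="pearson_r")
    out.index.name = "donor_id"
    return out
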