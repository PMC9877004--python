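"""Synthetic whole-blood RNA-seq cohorts with planted ground truth.

The generator emulates the statistical structure of globin-dominated whole
blood: a handful of hemoglobin genes soaking up 20-63% of each library, a
log-normal baseline over the remaining transcriptome, negative-binomial
count noise, planted case/control and sex effects, and an in-silico globin
depletion step that models the fixed-capacity behaviour of a sequencer --
removing globin reads frees capacity that flows to non-globin genes.

Every generator is deterministic under a fixed seed and records its planted
effects in a :class:`SynthTruth`, so downstream stages can be tested for
parameter recovery without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .types import CountMatrix, PanelDefinition, QpcrSheet, SampleSheet

#: Read-share split of the globin pool across the hemoglobin registry.
#: Adult whole blood is dominated by HBB and the two alpha subunits; the
#: remaining subunits and pseudogenes carry trace expression.  Only the
#: aggregate globin share matters downstream, so the split is a convention.
DEFAULT_GLOBIN_PROPORTIONS: dict[str, float] = {
    "HBA1": 0.20,
    "HBA2": 0.27,
    "HBB": 0.45,
    "HBD": 0.030,
    "HBE1": 0.002,
    "HBG1": 0.015,
    "HBG2": 0.015,
    "HBM": 0.004,
    "HBQ1": 0.002,
    "HBZ": 0.002,
    "HBAP1": 0.002,
    "HBBP1": 0.002,
    "HBZP1": 0.002,
    "HBDP1": 0.002,
    "HBGP1": 0.002,
}


@dataclass
class SynthConfig:
    """Parameters of a simulated whole-blood cohort.

    Defaults mirror the discovery-cohort regime: 12 control and 10 GBM
    donors, pre-depletion globin shares uniform on [20.0%, 62.6%], 99.5%
    globin-depletion efficiency, planted case effects of at least twofold,
    and a log2-normal(4, 2) baseline over the non-globin transcriptome.
    """

    n_control: int = 12
    n_gbm: int = 10
    library_size: int = 20_000_000
    n_genes: int = 10_000
    globin_fraction_range: tuple[float, float] = (0.200, 0.626)
    depletion_efficiency: float = 0.995
    nb_dispersion: float = 0.05
    n_de_genes: int = 60
    de_log2fc_range: tuple[float, float] = (1.0, 3.0)
    frac_de_up: float = 0.5
    n_sex_genes: int = 20
    sex_log2fc: float = 1.0
    seed: int = 0
    globin_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLOBIN_PROPORTIONS)
    )

    def validate(self, with_globin: bool = True) -> None:
        lo, hi = self.globin_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"globin_fraction_range must lie inside (0, 1); got {self.globin_fraction_range}"
            )
        if not (0.0 <= self.depletion_efficiency <= 1.0):
            raise ConfigurationError(
                f"depletion_efficiency must be in [0, 1]; got {self.depletion_efficiency}"
            )
        if self.n_control < 0 or self.n_gbm < 0 or self.n_control + self.n_gbm < 1:
            raise ConfigurationError("need at least one donor")
        if self.library_size < 1:
            raise ConfigurationError("library_size must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be nonnegative")
        flo, fhi = self.de_log2fc_range
        if flo > fhi or flo < 0:
            raise ConfigurationError(
                f"de_log2fc_range must be 0 <= lo <= hi; got {self.de_log2fc_range}"
            )
        if not (0.0 <= self.frac_de_up <= 1.0):
            raise ConfigurationError("frac_de_up must be in [0, 1]")
        n_globin = len(self.globin_proportions) if with_globin else 0
        if self.n_de_genes + self.n_sex_genes + n_globin > self.n_genes:
            raise ConfigurationError(
                "n_de_genes + n_sex_genes + globin registry exceeds n_genes"
            )

    @classmethod
    def mirna_defaults(cls, **overrides) -> "SynthConfig":
        """A configuration sized for the small-RNA layer: no globin genes,
        a smaller universe, and planted effects of at least 2.5-fold."""
        base = dict(
            n_genes=800,
            library_size=2_000_000,
            n_de_genes=20,
            de_log2fc_range=(math.log2(2.5), 3.0),
            n_sex_genes=0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SynthTruth:
    """Ground truth of a simulated cohort: planted multipliers and globin state.

    ``sample_compositions`` holds each sample's realized relative-abundance
    vector (genes x samples, columns summing to 1): the composition of the
    RNA tube after biological noise, from which the library was drawn.  The
    depletion simulator thins its globin components and redraws a library,
    so pre and post share the tube's biological state and differ only by
    depletion and independent sequencing sampling.
    """

    de_genes: dict[str, float]  # gene -> planted log2 fold change (GBM vs control)
    sex_genes: dict[str, float]  # gene -> planted log2 fold change (F vs M)
    globin_genes: set[str]
    globin_fraction: dict[str, float]  # sample_id -> pre-depletion globin share
    gene_ids: list[str] = field(default_factory=list)
    sample_compositions: pd.DataFrame | None = None

    def non_de_genes(self) -> list[str]:
        planted = set(self.de_genes) | set(self.sex_genes) | self.globin_genes
        return [g for g in self.gene_ids if g not in planted]


def _assign_sexes(n: int) -> list[str]:
    # round-robin keeps both sexes represented in each group for n >= 2,
    # so the sex covariate is never aliased with group
    return ["M" if i % 2 == 0 else "F" for i in range(n)]


def _gamma_noise(
    rng: np.random.Generator, expectation: np.ndarray, dispersion: float
) -> np.ndarray:
    """Multiply expectations by unit-mean gamma noise with CV^2 = dispersion.

    This is the biological layer of a gamma-Poisson (negative-binomial)
    model: the tube's realized relative abundances scatter around their
    expectations, and a fixed-capacity multinomial library draw on top
    yields marginally NB counts with that dispersion.
    """
    if dispersion <= 0:
        return expectation.copy()
    shape = 1.0 / dispersion
    return expectation * rng.gamma(shape, 1.0 / shape, size=expectation.shape)


def _simulate_cohort(
    config: SynthConfig, assay: str, with_globin: bool
) -> tuple[CountMatrix, SampleSheet, SynthTruth]:
    config.validate(with_globin=with_globin)
    rng = np.random.default_rng(config.seed)

    globin_genes = list(config.globin_proportions) if with_globin else []
    n_other = config.n_genes - len(globin_genes)
    prefix = "miR-" if assay == "miRNA" else "G"
    other_genes = [f"{prefix}{i + 1:05d}" for i in range(n_other)]
    gene_ids = globin_genes + other_genes

    # log-normal baseline on the log2 scale over the non-globin transcriptome
    baseline = np.exp2(rng.normal(4.0, 2.0, size=n_other))

    # plant case and sex effects on disjoint non-globin genes
    perm = rng.permutation(n_other)
    de_idx = perm[: config.n_de_genes]
    sex_idx = perm[config.n_de_genes : config.n_de_genes + config.n_sex_genes]
    flo, fhi = config.de_log2fc_range
    n_up = int(round(config.frac_de_up * config.n_de_genes))
    signs = np.array([1.0] * n_up + [-1.0] * (config.n_de_genes - n_up))
    de_lfc = rng.uniform(flo, fhi, size=config.n_de_genes) * signs
    sex_lfc = np.full(config.n_sex_genes, config.sex_log2fc)

    de_genes = {other_genes[i]: float(l) for i, l in zip(de_idx, de_lfc)}
    sex_genes = {other_genes[i]: float(l) for i, l in zip(sex_idx, sex_lfc)}

    donors = [f"C{i + 1:02d}" for i in range(config.n_control)] + [
        f"P{i + 1:02d}" for i in range(config.n_gbm)
    ]
    groups = ["control"] * config.n_control + ["GBM"] * config.n_gbm
    sexes = _assign_sexes(config.n_control) + _assign_sexes(config.n_gbm)
    gr_status = "pre"
    suffix = "_mir" if assay == "miRNA" else "_pre"
    sample_ids = [d + suffix for d in donors]

    globin_props = (
        np.array([config.globin_proportions[g] for g in globin_genes])
        if with_globin
        else np.empty(0)
    )
    if with_globin:
        globin_props = globin_props / globin_props.sum()

    counts = np.zeros((config.n_genes, len(donors)), dtype=np.int64)
    proportions = np.zeros((config.n_genes, len(donors)))
    globin_fraction: dict[str, float] = {}
    lo, hi = config.globin_fraction_range
    for j, (sid, grp, sex) in enumerate(zip(sample_ids, groups, sexes)):
        mult = np.ones(n_other)
        if grp == "GBM":
            mult[de_idx] *= np.exp2(de_lfc)
        if sex == "F":
            mult[sex_idx] *= np.exp2(sex_lfc)
        # the tube's realized non-globin abundances: expectation times
        # donor-level gamma noise, shared later by the depleted aliquot
        expr = _gamma_noise(rng, baseline * mult, config.nb_dispersion)
        if with_globin:
            f = float(rng.uniform(lo, hi))
            globin_fraction[sid] = f
            composition = np.concatenate(
                [f * globin_props, (1.0 - f) * expr / expr.sum()]
            )
        else:
            globin_fraction[sid] = 0.0
            composition = expr / expr.sum()
        proportions[:, j] = composition
        counts[:, j] = rng.multinomial(config.library_size, composition)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        assay=assay,
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "donor_id": donors,
                "group": groups,
                "sex": sexes,
                "gr_status": gr_status,
                "assay": assay,
            }
        )
    )
    truth = SynthTruth(
        de_genes=de_genes,
        sex_genes=sex_genes,
        globin_genes=set(globin_genes),
        globin_fraction=globin_fraction,
        gene_ids=gene_ids,
        sample_compositions=pd.DataFrame(
            proportions, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids
        ),
    )
    return matrix, sheet, truth


def simulate_blood_cohort(
    config: SynthConfig,
) -> tuple[CountMatrix, SampleSheet, SynthTruth]:
    """Simulate a pre-depletion whole-blood mRNA cohort.

    Per sample, a globin share f is drawn uniformly from
    ``config.globin_fraction_range``; the globin pool f*library_size splits
    across the registry genes in fixed proportions, while the non-globin
    log-normal baseline (with planted group and sex multipliers) is scaled
    to the remaining (1-f)*library_size after donor-level gamma noise.  The
    library is a single multinomial draw of exactly ``library_size`` reads
    from the realized composition, so counts are marginally
    negative-binomial with the configured dispersion and every column sums
    to the library size exactly.
    """
    return _simulate_cohort(config, assay="mRNA", with_globin=True)


def simulate_mirna_cohort(
    config: SynthConfig,
) -> tuple[CountMatrix, SampleSheet, SynthTruth]:
    """Simulate the small-RNA layer: no globin genes, smaller universe.

    Planted effects must be at least 2.5-fold (|log2fc| >= log2 2.5), the
    significance regime used for miRNAs.
    """
    if config.de_log2fc_range[0] < math.log2(2.5) - 1e-12 and config.n_de_genes > 0:
        raise ConfigurationError(
            "miRNA cohorts require planted |log2fc| >= log2(2.5); "
            f"got lower bound {config.de_log2fc_range[0]:.3f}"
        )
    return _simulate_cohort(config, assay="miRNA", with_globin=False)


def simulate_globin_depletion(
    pre: CountMatrix, truth: SynthTruth, efficiency: float, seed: int
) -> CountMatrix:
    """In-silico globin reduction under fixed sequencing capacity.

    Depletion acts on the RNA aliquot before sequencing: the sample's
    realized tube composition has its globin components thinned to
    retention (1 - efficiency) and renormalized, and the post library is an
    independent multinomial draw of the original per-sample library size
    from that depleted composition.  Because sequencing capacity -- not
    input RNA -- is the binding constraint, the capacity freed by depletion
    flows to non-globin genes: a post-GR library carries more informative
    reads than its pre-GR twin instead of being a degraded resampling of
    it.  Pre and post share the tube's biological noise and differ only by
    depletion and sequencing sampling.  Post samples keep their donor, with
    sample ids switched from ``*_pre`` to ``*_post``.

    Falls back to the realized pre-GR counts as the composition estimate
    when ``truth.sample_compositions`` is unavailable.
    """
    if not (0.0 <= efficiency <= 1.0):
        raise ConfigurationError(f"efficiency must be in [0, 1]; got {efficiency}")
    rng = np.random.default_rng(seed)
    globin_mask = np.array([g in truth.globin_genes for g in pre.gene_ids])
    if truth.sample_compositions is not None:
        comp = truth.sample_compositions.loc[pre.gene_ids, pre.sample_ids].to_numpy().copy()
    else:
        comp = pre.counts.to_numpy(dtype=float).copy()
    libraries = pre.column_sums().to_numpy()
    post = np.zeros(pre.shape, dtype=np.int64)
    for j, sid in enumerate(pre.sample_ids):
        depleted = comp[:, j].copy()
        depleted[globin_mask] *= 1.0 - efficiency
        total = depleted.sum()
        if total <= 0:
            raise ConfigurationError(f"sample {sid!r} has no reads left after depletion")
        post[:, j] = rng.multinomial(int(libraries[j]), depleted / total)
    post_ids = [post_sample_id(s) for s in pre.sample_ids]
    return CountMatrix(
        pd.DataFrame(post, index=pre.counts.index.copy(), columns=post_ids),
        assay=pre.assay,
    )


def post_sample_id(pre_id: str) -> str:
    return pre_id[: -len("_pre")] + "_post" if pre_id.endswith("_pre") else pre_id + "_post"


def post_sample_sheet(pre_sheet: SampleSheet) -> SampleSheet:
    """Sheet for the depleted samples: same donors, gr_status flipped to post."""
    d = pre_sheet.data.copy()
    d["sample_id"] = [post_sample_id(s) for s in d["sample_id"]]
    d["gr_status"] = "post"
    return SampleSheet(d)


def combined_sample_sheet(pre_sheet: SampleSheet, post_sheet: SampleSheet) -> SampleSheet:
    """Concatenate pre and post sheets into one pairing table."""
    return SampleSheet(
        pd.concat([pre_sheet.data, post_sheet.data], ignore_index=True)
    )


def simulate_tissue_cohorts(
    config: SynthConfig,
    truth: SynthTruth,
    shared_fraction: float,
    n_cohorts: int,
    n_decoys: int = 200,
    fdr_ceiling: float = 0.05,
) -> list[pd.DataFrame]:
    """External-cohort DEG tables sharing part of the blood-planted signal.

    Each cohort's table contains an exact ``round(shared_fraction *
    n_planted)``-sized seeded draw of the blood-planted genes (same
    directions) plus cohort-private decoy genes; FDR values fall below
    ``fdr_ceiling``.  Decoys are disjoint across cohorts and from the blood
    universe, so cross-cohort overlap comes only from planted genes.
    """
    if not (0.0 <= shared_fraction <= 1.0):
        raise ConfigurationError(f"shared_fraction must be in [0, 1]; got {shared_fraction}")
    if n_cohorts < 1:
        raise ConfigurationError(f"n_cohorts must be >= 1; got {n_cohorts}")
    rng = np.random.default_rng(config.seed + 104729)  # decoupled stream
    planted = sorted(truth.de_genes)
    n_shared = int(round(shared_fraction * len(planted)))
    tables = []
    for c in range(n_cohorts):
        chosen = sorted(rng.choice(planted, size=n_shared, replace=False)) if n_shared else []
        rows = []
        for g in chosen:
            sign = 1.0 if truth.de_genes[g] > 0 else -1.0
            rows.append(
                (g, sign * rng.uniform(1.0, 3.0), rng.uniform(0.0, fdr_ceiling))
            )
        for i in range(n_decoys):
            rows.append(
                (
                    f"DECOY_C{c + 1}_{i + 1:04d}",
                    rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 3.0),
                    rng.uniform(0.0, fdr_ceiling),
                )
            )
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "fdr"])
        lfc = df["log2fc"].to_numpy()
        df["direction"] = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
        tables.append(df)
    return tables


def simulate_module_framework(
    truth: SynthTruth,
    n_modules: int = 20,
    module_size_range: tuple[int, int] = (10, 30),
    enrichment: float = 0.8,
    n_hot_up: int = 2,
    n_hot_down: int = 2,
    seed: int = 0,
):
    """A module repertoire with designated 'hot' modules.

    Hot modules draw ``enrichment`` of their genes from planted DE genes of
    one direction; the rest of their genes, and all genes of cold modules,
    are uniform draws from the non-DE universe.  Hot modules carry
    annotation ``"hot_up"``/``"hot_down"``, cold modules ``"random"``.
    """
    from .types import ModuleFramework

    if not (0.0 <= enrichment <= 1.0):
        raise ConfigurationError(f"enrichment must be in [0, 1]; got {enrichment}")
    if module_size_range[0] < 1:
        raise ConfigurationError("module_size_range lower bound must be >= 1")
    if n_hot_up + n_hot_down > n_modules:
        raise ConfigurationError("more hot modules than modules")
    rng = np.random.default_rng(seed)
    up_pool = sorted(g for g, l in truth.de_genes.items() if l > 0)
    down_pool = sorted(g for g, l in truth.de_genes.items() if l < 0)
    cold_pool = truth.non_de_genes()
    modules: dict[str, set[str]] = {}
    annotations: dict[str, str] = {}
    for m in range(n_modules):
        size = int(rng.integers(module_size_range[0], module_size_range[1] + 1))
        if m < n_hot_up:
            kind, pool = "hot_up", up_pool
        elif m < n_hot_up + n_hot_down:
            kind, pool = "hot_down", down_pool
        else:
            kind, pool = "random", []
        if kind != "random":
            n_hot = min(int(round(enrichment * size)), len(pool))
            hot = list(rng.choice(pool, size=n_hot, replace=False)) if n_hot else []
            n_cold = size - len(hot)
        else:
            hot, n_cold = [], size
        cold = (
            list(rng.choice(cold_pool, size=min(n_cold, len(cold_pool)), replace=False))
            if n_cold
            else []
        )
        mid = f"M{m // 10 + 1}.{m % 10 + 1}"
        modules[mid] = set(hot) | set(cold)
        annotations[mid] = kind
    return ModuleFramework(modules=modules, annotations=annotations)


def simulate_qpcr(
    panel: PanelDefinition,
    n_control: int,
    n_gbm: int,
    planted_log2fc: Mapping[str, float],
    ct_noise_sd: float,
    seed: int,
    n_replicates: int = 3,
    reference_ct: float = 18.0,
    baseline_delta_ct: float = 6.0,
    reference_map: Mapping[str, str] | None = None,
) -> QpcrSheet:
    """Triplicate Ct values consistent with planted log2 fold changes.

    Reference genes have a constant expected Ct per sample; each target's
    expected Ct is reference + baseline ΔCt, lowered by the planted log2fc
    in GBM samples (one PCR cycle per twofold).  Replicates share the same
    expectation and differ only by Gaussian noise.
    """
    from .types import DEFAULT_REFERENCE_MAP

    if ct_noise_sd < 0:
        raise ConfigurationError(f"ct_noise_sd must be >= 0; got {ct_noise_sd}")
    ref_map = dict(DEFAULT_REFERENCE_MAP if reference_map is None else reference_map)
    rng = np.random.default_rng(seed)
    samples = [(f"QC{i + 1:02d}", "control") for i in range(n_control)] + [
        (f"QP{i + 1:02d}", "GBM") for i in range(n_gbm)
    ]
    classes = sorted(set(panel.entries["rna_class"]))
    rows = []
    for sid, grp in samples:
        for rc in classes:
            ref = ref_map[rc]
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (sid, grp, ref, rc, rep, reference_ct + rng.normal(0, ct_noise_sd))
                )
        for _, entry in panel.entries.iterrows():
            g = entry["gene_id"]
            expect = reference_ct + baseline_delta_ct
            if grp == "GBM":
                expect -= planted_log2fc.get(g, 0.0)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (
                        sid,
                        grp,
                        g,
                        entry["rna_class"],
                        rep,
                        expect + rng.normal(0, ct_noise_sd),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "gene_id", "rna_class", "replicate_index", "ct_value"],
    )
    return QpcrSheet(df, reference_map=ref_map)
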