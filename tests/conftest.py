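import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wbgr import globin_metrics, synthetic_data as synth
from wbgr.types import CountMatrix, SampleSheet

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: A small but fully featured cohort used across test modules.
SMALL_COHORT = dict(
    n_control=4,
    n_gbm=4,
    library_size=200_000,
    n_genes=400,
    n_de_genes=10,
    n_sex_genes=4,
    seed=11,
)


@pytest.fixture(scope="session")
def blood_cohort():
    cfg = synth.SynthConfig(**SMALL_COHORT)
    return synth.simulate_blood_cohort(cfg)


@pytest.fixture(scope="session")
def depleted(blood_cohort):
    pre, sheet, truth = blood_cohort
    post = synth.simulate_globin_depletion(pre, truth, efficiency=0.995, seed=12)
    return post, synth.post_sample_sheet(sheet)


@pytest.fixture(scope="session")
def registry():
    return globin_metrics.default_globin_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_matrix(counts, genes=None, samples=None, assay="mRNA"):
    """Build a CountMatrix from a nested list / array with default ids."""
    arr = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples), assay=assay)


def make_sheet(rows):
    """Build a SampleSheet from (sample, donor, group, sex, gr, assay) tuples."""
    return SampleSheet(
        pd.DataFrame(
            rows,
            columns=["sample_id", "donor_id", "group", "sex", "gr_status", "assay"],
        )
    )
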