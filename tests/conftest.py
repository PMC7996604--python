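import numpy as np
import pytest

from crossfluid import core_io, synthetic
from crossfluid.core_io import MetabolomicsDataset, SampleKey


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(n_subjects=4, n_replicates=2, n_metabolites=3, seed=0):
    """Small dense dataset with both fluids for every subject."""
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    for i in range(n_subjects):
        group = "glioma" if i % 2 == 0 else "control"
        for fluid in ("plasma", "csf"):
            for rep in range(1, n_replicates + 1):
                samples.append(SampleKey(f"S{i}", group, fluid, rep))
                rows.append(rng.uniform(10, 1000, size=n_metabolites))
    mets = [f"M{j}" for j in range(n_metabolites)]
    return MetabolomicsDataset(samples, mets, np.array(rows))


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def default_cohort():
    """Study-sized synthetic cohort with the default planted correlation mix."""
    cfg = synthetic.SimulationConfig(seed=7)
    return synthetic.simulate_dataset(cfg)


@pytest.fixture
def default_paired(default_cohort):
    ds, truth = default_cohort
    ds = core_io.average_replicates(ds)
    ds = core_io.ln_transform(ds)
    ds = core_io.filter_detected(ds)
    return core_io.build_paired_table(ds), truth
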