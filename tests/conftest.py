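import numpy as np
import pandas as pd
import pytest

from folrsig.harmonize import PooledCohort, harmonize_cohorts
from folrsig.simulate import SimConfig, simulate


def make_pooled(values: pd.DataFrame, reference=None) -> PooledCohort:
    """Wrap a plain matrix as a single-dataset PooledCohort for unit tests."""
    return PooledCohort(
        values=values,
        dataset_of=pd.Series("d1", index=values.columns),
        reference_samples=frozenset(
            reference if reference is not None else values.columns
        ),
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One small simulated study, harmonized and split, shared across tests.

    Low anchor noise so the median split recovers the true class well;
    three cohorts so there are held-out validation samples.
    """
    cfg = SimConfig(
        seed=20240,
        n_cohorts=3,
        samples_per_cohort=100,
        n_genes=600,
        n_module_genes=80,
        module_log2fc=1.0,
        anchor_noise_sd=0.1,
    )
    sim = simulate(cfg)
    tumors = sim.tumor_sample_ids
    pooled = harmonize_cohorts(sim.cohorts, tumors)
    return {"cfg": cfg, "sim": sim, "tumors": tumors, "pooled": pooled}


@pytest.fixture
def rng():
    return np.random.default_rng(7)
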