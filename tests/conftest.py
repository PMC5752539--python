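import numpy as np
import pytest

from mirtarkey import RunConfig, SimulationConfig, simulate_cohort


def small_sim_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Scaled-down cohort for fast unit tests (not the acceptance scale)."""
    kwargs = dict(
        n_tumor=120,
        n_normal=24,
        n_genes=400,
        n_mirnas=60,
        n_planted_regulations=12,
        n_planted_prognostic=5,
        ppi_n_nodes=300,
        n_pathways=20,
        n_decoy_disease_mirnas=10,
        decoys_per_mirna=8,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_sim_config())


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the standard simulation scale."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def fast_run_config():
    return RunConfig(n_resamples=100, n_permutations=50, rng_seed=7)


@pytest.fixture(scope="session")
def survival_fixture():
    """50-subject survival data with ties and censoring for oracle checks."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=50)
    event_time = rng.exponential(scale=1.0 / np.exp(0.6 * x))
    event_time = np.round(event_time, 1) + 0.1  # induce tied event times
    censor = rng.uniform(0, 3.0, size=50)
    time = np.minimum(event_time, censor)
    event = (event_time <= censor).astype(int)
    return x, time, event
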