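import numpy as np
import pandas as pd
import pytest

from epiprs.synthetic_data import (SimulationConfig, simulate_cohort,
                                   simulate_summary_stats, simulate_true_effects)


@pytest.fixture(scope="session")
def cfg_small() -> SimulationConfig:
    """A quick cohort: moderate prevalence and a common enough major variant
    that both screen strata are populated at small n."""
    return SimulationConfig(m_snps=120, n_cases=200, n_controls=200, n_trios=30,
                            prevalence_k=0.05, carrier_freq=0.05, seed=42)


@pytest.fixture(scope="session")
def effects(cfg_small):
    return simulate_true_effects(cfg_small)


@pytest.fixture(scope="session")
def sumstats(effects, cfg_small):
    return simulate_summary_stats(effects, cfg_small.n_discovery, seed=cfg_small.seed)


@pytest.fixture(scope="session")
def cohort(effects, cfg_small):
    return simulate_cohort(effects, cfg_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
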