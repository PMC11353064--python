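import numpy as np
import pytest

from echofit import (
    DesignConfig,
    PopulationParams,
    SimulationConfig,
    simulate_experiment,
)

PHASES = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi, 2.0 * np.pi)


@pytest.fixture(scope="session")
def exp1_design():
    return DesignConfig.for_experiment(1)


@pytest.fixture(scope="session")
def exp2_design():
    return DesignConfig.for_experiment(2)


@pytest.fixture(scope="session")
def small_table():
    """6-subject experiment-1 dataset with the default (moderate) effect."""
    cfg = SimulationConfig(n_subjects=6, seed=42)
    table, truth = simulate_experiment(cfg)
    return table, truth


@pytest.fixture(scope="session")
def noiseless_compression_table():
    """Near-noiseless listeners with pure baseline compression gamma0=0.25.

    Every phase condition then carries slope 0.75 exactly, i.e. a flat
    3-semitone accuracy profile.
    """
    pop = PopulationParams(
        gamma0_mean=0.25, gamma0_sd=0.0,
        gamma1_mean=0.0, gamma1_sd=0.0,
        sigma0_mean=1e-9, sigma0_sd=0.0,
        beta_sd=0.0, kappa_phase=1e9,
    )
    cfg = SimulationConfig(n_subjects=3, population=pop, seed=7)
    table, _ = simulate_experiment(cfg)
    return table
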