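import numpy as np
import pytest

from nigcmr.simulate import (
    SimulationConfig,
    corrupt_to_replicates,
    simulate_population,
)


@pytest.fixture(scope="session")
def default_sim():
    """One mid-size simulated dataset shared across test modules."""
    cfg = SimulationConfig(seed=101)
    truth = simulate_population(cfg)
    replicates, samples = corrupt_to_replicates(truth)
    return cfg, truth, replicates, samples


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free capture process: no genotyping errors, no misidentification,
    every genotype fully separable (high-resolution pattern classes)."""
    cfg = SimulationConfig(
        seed=5,
        alpha=1.0,
        dropout_rate=0.0,
        false_allele_rate=0.0,
        missing_replicate_rate=0.0,
        sry_dropout=0.0,
        n_females=25,
        n_males=25,
        p_capture=0.6,
        c_recapture=0.6,
        n_pso=6,
        sso_per_pso=5,
        pattern_class_count=40,
    )
    truth = simulate_population(cfg)
    replicates, samples = corrupt_to_replicates(truth)
    return cfg, truth, replicates, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
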