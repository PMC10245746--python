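import numpy as np
import pytest

from pulsekin import SimulationConfig, simulate_dataset

TIMEPOINTS = [1.0, 2.0, 4.0, 6.0]


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small noise-free dataset: every heavy fraction equals the model exactly."""
    cfg = SimulationConfig(
        n_proteins=25,
        peptides_per_protein=(1, 2),
        tissues=["liver"],
        timepoints_hours=TIMEPOINTS,
        replicates_per_timepoint=2,
        cv_light=0.0,
        cv_heavy=0.0,
        missing_rate=0.0,
        frac_double_residue=0.2,
        seed=7,
    )
    quant, meta, truth = simulate_dataset(cfg)
    return cfg, quant, meta, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Dataset at the study's noise scale (CV 14%/22%, 5% missing, 2 batches)."""
    cfg = SimulationConfig(
        n_proteins=60,
        peptides_per_protein=(2, 3),
        tissues=["liver", "brain"],
        timepoints_hours=TIMEPOINTS,
        replicates_per_timepoint=3,
        batch_log2_offsets={"batch_liver": 0.0, "batch_brain": 1.5},
        seed=11,
    )
    quant, meta, truth = simulate_dataset(cfg)
    return cfg, quant, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
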