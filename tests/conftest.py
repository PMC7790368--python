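import numpy as np
import pytest

from kinesynergy import GaitSimConfig, generate_trial, random_synergy_basis


@pytest.fixture(scope="session")
def clean_config():
    """Noise- and jitter-free structured gait; stride frequency 1 Hz at
    1.2 m/s so one stride is exactly 100 frames."""
    return GaitSimConfig(
        phase_jitter_sd_deg=0.0,
        noise_sd=0.0,
        duration_s=20.0,
        perturbed_duration_s=30.0,
        stride_freq_base=1.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    trial, truth = generate_trial(clean_config, "S01", 1.2, "normal")
    return trial, truth


@pytest.fixture(scope="session")
def clean_perturbed(clean_config):
    trial, truth = generate_trial(clean_config, "S01", 1.2, "perturbed")
    return trial, truth


@pytest.fixture(scope="session")
def planted_basis():
    return random_synergy_basis(20, 3, seed=11)


@pytest.fixture(scope="session")
def lowrank_trials(planted_basis):
    """18 noiseless low-rank trials (6 subjects x 3 speeds) spanning a planted
    3-synergy basis with fractions (0.80, 0.15, 0.05)."""
    cfg = GaitSimConfig(
        n_subjects=6,
        synergy_vectors=planted_basis,
        synergy_variance_fractions=(0.80, 0.15, 0.05),
        noise_sd=0.0,
        duration_s=15.0,
        stride_freq_base=1.0,
        seed=5,
    )
    trials = [
        generate_trial(cfg, f"S{i:02d}", s, "normal")[0]
        for i in range(1, 7)
        for s in cfg.speeds
    ]
    return cfg, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
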