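import numpy as np
import pytest

from avmsi.studies import _simulate_study_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One small simulated subject (all three modality cells, direct gaze)."""
    return _simulate_study_subject(
        seed=42, n_channels=6, trials_per_cell=3, duration_s=12.0, noise_sd=3.0
    )
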