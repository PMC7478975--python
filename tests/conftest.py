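import numpy as np
import pytest

from mfkinetics import TwoStateParams, generate_two_state_activity


@pytest.fixture(scope="session")
def two_state_pair():
    """A noise-free two-state trace plus its ground truth (session-shared)."""
    params = TwoStateParams(n_rounds=500, amplitude_noise_sd=0.0)
    return generate_two_state_activity(params, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
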