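import warnings

import numpy as np
import pytest

from symptomnet.glasso import estimate_network
from symptomnet.simulate import default_study_preset


@pytest.fixture(scope="session")
def preset():
    """Default study conditions at the study sample size (n=406, seed 1)."""
    return default_study_preset(1)


@pytest.fixture(scope="session")
def preset_large():
    """Default study conditions at n=2000 (recovery-scale sample)."""
    return default_study_preset(1, n=2000)


@pytest.fixture(scope="session")
def estimated_large(preset_large):
    """Estimated network on the n=2000 preset (shared across tests)."""
    _, _, data = preset_large
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_network(data)


@pytest.fixture
def random_corr():
    """Factory for random positive-definite correlation matrices."""

    def make(p, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((p, p + 3))
        S = A @ A.T
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        np.fill_diagonal(S, 1.0)
        return S

    return make
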