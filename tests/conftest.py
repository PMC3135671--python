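import numpy as np
import pytest

from confsel.synthetic import (EnsembleConfig, build_scaffold,
                               generate_ensemble, generate_reference_complex)


@pytest.fixture(scope="session")
def reference_complex():
    return generate_reference_complex()


@pytest.fixture(scope="session")
def small_two_state_ensemble():
    """200 frames, two-state gating, fixed seed."""
    return generate_ensemble(EnsembleConfig(n_frames=200, dynamics_model="two_state", seed=11))


@pytest.fixture(scope="session")
def small_continuous_ensemble():
    return generate_ensemble(EnsembleConfig(n_frames=200, dynamics_model="continuous", seed=12))


@pytest.fixture
def open_frame():
    """Fully open canonical-orientation scaffold (gating 8 Å, no jitter)."""
    return build_scaffold(8.0)


@pytest.fixture
def closed_frame():
    """Fully closed scaffold (gating 3.5 Å): the lining blocks the axis."""
    return build_scaffold(3.5)


@pytest.fixture
def intermediate_frame():
    """Semi-open scaffold (gating 5.5 Å): enterable, not deeply."""
    return build_scaffold(5.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
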