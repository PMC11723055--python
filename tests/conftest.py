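import numpy as np
import pytest

from epiloop import synthetic as syn
from epiloop.config import RunConfig

#: Slope subwindow of exactly 8 samples at the Bonn-like sampling rate.
BONN_SLP_MS = 8 / syn.BONN_FS * 1000


@pytest.fixture(scope="session")
def bonn_cfg() -> RunConfig:
    """Run configuration for the 173.61 Hz detection-level fixtures."""
    return RunConfig(fs=syn.BONN_FS, slp_subwindow_ms=BONN_SLP_MS)


@pytest.fixture(scope="session")
def background_recording():
    """Seizure-free interictal background (fixed seed)."""
    return syn.generate(syn.background_config(seed=11))


@pytest.fixture(scope="session")
def single_seizure_recording():
    """30-epoch recording with one single-epoch seizure at epoch 20."""
    return syn.generate(syn.single_seizure_config(seed=7))


@pytest.fixture(scope="session")
def planted_grid_recording():
    """Fixture with a planted single-feature optimum at (M, N) = (2, 1)."""
    return syn.generate(syn.planted_grid_config(seed=3))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
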