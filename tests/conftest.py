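import numpy as np
import pytest

from skindepth import (
    MapSimConfig,
    PreprocessConfig,
    Spectrum,
    make_map,
    make_references,
)


@pytest.fixture
def cfg():
    return PreprocessConfig()


@pytest.fixture
def axis():
    """Uniform 400–2300 cm⁻¹ axis at 2 cm⁻¹ spacing (951 channels)."""
    return 400.0 + 2.0 * np.arange(951)


@pytest.fixture
def noisy_spectrum(axis):
    rng = np.random.default_rng(42)
    return Spectrum(axis, 100.0 + rng.normal(0, 5, size=axis.shape))


@pytest.fixture(scope="session")
def sim_refs():
    return make_references(MapSimConfig(seed=0))


@pytest.fixture(scope="session")
def sim_map(sim_refs):
    """Default simulated map + ground truth (93 pixels, 2 low-signal)."""
    cfg = MapSimConfig(seed=0)
    return make_map(cfg, sim_refs)
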