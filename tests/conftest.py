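import numpy as np
import pytest

from mvtomo.io_volumes import LabelVolume, Volume
from mvtomo.synthetic import SimulationConfig, simulate_patch


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_patch():
    """One noiseless 16^3 synthetic patch with two classes available."""
    cfg = SimulationConfig(shape=(16, 16, 16), n_classes=2,
                           particles_per_patch=(1, 2), radius_range=(2.5, 4.0),
                           snr=float("inf"), seed=7)
    return simulate_patch(cfg)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.normal(size=(8, 8, 8)).astype(np.float32))


def make_labels(arr, n_classes):
    return LabelVolume(np.asarray(arr, dtype=np.int64), n_classes)
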