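import numpy as np
import pytest

from glycocal.calibration import assemble_training_set
from glycocal.masses import build_standard_panel
from glycocal.simulate import GroundTruth, simulate_standard_rts


@pytest.fixture(scope="session")
def panel():
    return build_standard_panel()


@pytest.fixture()
def truth():
    return GroundTruth(seed=0)


@pytest.fixture(scope="session")
def training_points():
    """One default simulated 33-point training set (seed 0)."""
    panel = build_standard_panel()
    truth = GroundTruth(seed=0)
    rts = simulate_standard_rts(panel, truth, seed=0)
    return assemble_training_set(panel, rts)


def gaussian_trace(times, centers, areas, sigma):
    y = np.zeros_like(times)
    for c, a in zip(centers, areas):
        y += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(-((times - c) ** 2) / (2 * sigma**2))
    return y
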