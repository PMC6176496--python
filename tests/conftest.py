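import logging

import numpy as np
import pytest

from mmnconn.config import Coupling, SimulationConfig
from mmnconn.preprocess import AnalysisWindow
from mmnconn.simulate import EventSequence

logging.getLogger("mmnconn").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """60-tone single block, 20 ROIs: fast but structurally complete."""
    return SimulationConfig(tones_per_block=60, n_standard=40,
                            n_deviant_low=10, n_deviant_high=10,
                            n_rois=20, seed=7)


@pytest.fixture
def coupled_config():
    """100 standard tones, one strongly coupled ROI pair (5 -> 18)."""
    return SimulationConfig(
        tones_per_block=100, n_standard=100, n_deviant_low=0,
        n_deviant_high=0, n_rois=20, seed=9,
        coupling_spec=(Coupling(5, 18, np.pi / 4, 0.95, "both"),))


@pytest.fixture
def window_160():
    return AnalysisWindow(160.0, (110.0, 210.0), "Fz")


def make_events(labels, soa_ms=1075.0, start_ms=1075.0):
    """Hand-built event sequence from a label list like ['S','S','D']."""
    expand = {"S": "standard", "D": "deviant_low", "Dh": "deviant_high"}
    labels = [expand.get(l, l) for l in labels]
    onsets = start_ms + soa_ms * np.arange(len(labels))
    return EventSequence(onsets, np.array(labels),
                         np.zeros(len(labels), dtype=int),
                         validate_spacing=False)
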