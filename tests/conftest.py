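import numpy as np
import pytest

import ssvepgrid as sg
from ssvepgrid.decoders import ShrinkageLDA
from ssvepgrid.features import psd_features, select_channels


@pytest.fixture(scope="session")
def grid():
    return sg.DEFAULT_GRID


@pytest.fixture(scope="session")
def montage():
    return sg.default_montage()


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-scale generator config for fast unit tests (not the study design)."""
    return sg.SynthConfig(seed=7, trials_per_class=8, duration=2.0)


@pytest.fixture(scope="session")
def epochs_td(small_cfg):
    return sg.simulate_epochs(small_cfg, sg.condition("top_down"))


@pytest.fixture(scope="session")
def features_td(epochs_td):
    return psd_features(epochs_td)


@pytest.fixture(scope="session")
def eeg_features_td(features_td, epochs_td):
    return select_channels(features_td, epochs_td.montage.eeg_channels)


def cv_decision_values(eeg, labels, chrono, k=4):
    """Out-of-sample LDA decision values via chronological CV."""
    res = sg.chronological_cv(eeg, labels, chrono, k=k, classifier=ShrinkageLDA())
    return res
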