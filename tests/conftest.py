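"""Shared fixtures: synthetic trial sets and feature datasets.

Expensive objects (TFR feature matrices) are session-scoped so the
classification and importance tests can share them.
"""

import numpy as np
import pytest

from tfrinfo import ProtocolSpec, make_dataset
from tfrinfo.io import build_method_datasets
from tfrinfo.synthetic import NoiseSpec


@pytest.fixture(scope="session")
def rf_trials():
    """Default receptive-field-like set: 8 classes x 10 trials, 3 s."""
    spec = ProtocolSpec.default("rf_like")
    return make_dataset(spec, seed=42)


@pytest.fixture(scope="session")
def rf_cwt_dataset(rf_trials):
    signals, labels = rf_trials
    return build_method_datasets(signals, labels, "rf_like", ["cwt"])["cwt"]


@pytest.fixture(scope="session")
def eeg_trials():
    """Default EEG-like set: 90 'seen' vs 60 'nothing' trials."""
    spec = ProtocolSpec.default("eeg_like")
    return make_dataset(spec, seed=42)


@pytest.fixture(scope="session")
def eeg_cwt_dataset(eeg_trials):
    signals, labels = eeg_trials
    return build_method_datasets(signals, labels, "eeg_like", ["cwt"])["cwt"]


@pytest.fixture(scope="session")
def eeg_planted_trials():
    """EEG-like set with a strong, narrow 10 Hz planted class effect."""
    spec = ProtocolSpec.default("eeg_like", effect_size=5.0, band=(9.5, 10.5))
    return make_dataset(spec, seed=3)


@pytest.fixture(scope="session")
def srcs_contaminated_trials():
    """SRCS-like set with weak bursts and heavy broadband transients."""
    spec = ProtocolSpec.default(
        "srcs_like",
        effect_size=0.2,
        noise=NoiseSpec(one_over_f_exponent=1.0, noise_power=0.1, transient_rate=8.0),
    )
    return make_dataset(spec, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
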