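"""Shared fixtures: synthetic sessions and trained models.

Session-scoped fixtures cache the expensive artifacts (simulated
sessions, feature tables, fitted classifiers) so the suite stays fast
while every test exercises the real pipeline.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sp_signal

from neurobrake import (
    PipelineConfig,
    SessionRecording,
    SimulationConfig,
    simulate_session,
)
from neurobrake.pipeline import build_dataset, fit_classifier
from neurobrake.simulate import ar_denominator


@pytest.fixture(scope="session")
def session600() -> SessionRecording:
    """A 10-min default-condition driving session (~25 events)."""
    return simulate_session(SimulationConfig(duration_s=600.0, seed=42))


@pytest.fixture(scope="session")
def session_null() -> SessionRecording:
    """Same conditions but with no pre-braking EEG signature."""
    return simulate_session(
        SimulationConfig(duration_s=600.0, seed=7, signature_strength=0.0)
    )


@pytest.fixture(scope="session")
def ar_config() -> PipelineConfig:
    return PipelineConfig(feature="ar", ar_order=10, pre_braking_ms=600.0, seed=0)


@pytest.fixture(scope="session")
def ar_table(session600, ar_config):
    return build_dataset(session600, ar_config)


@pytest.fixture(scope="session")
def trained_ar(ar_table, ar_config):
    """(network, standardizer) fit on the full AR table."""
    return fit_classifier(ar_table, config=ar_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_eeg_window(seed: int = 0, n: int = 128, signature: float = 0.0) -> np.ndarray:
    """An (8, n) array of independent baseline-EEG channels."""
    rng = np.random.default_rng(seed)
    a = ar_denominator(signature)
    out = np.vstack(
        [
            sp_signal.lfilter([1.0], a, rng.standard_normal(n + 500))[500:]
            for _ in range(8)
        ]
    )
    return out


@pytest.fixture()
def eeg_window_array() -> np.ndarray:
    return make_eeg_window(seed=5)
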