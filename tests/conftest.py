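"""Shared fixtures: synthetic recordings and the acceptance cohort fit.

Everything is generated programmatically at fixed seeds; the expensive
cohort-level fit (14 subjects, full motor montage) is session-scoped so
recovery and classification checks share one computation.
"""

from dataclasses import replace

import numpy as np
import pytest

from fatiguersp import FatigueSpectralModel, SimConfig, simulate_subject
from fatiguersp.simulate import simulate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def calibrated_config() -> SimConfig:
    """Study-condition config without between-subject spread."""
    return SimConfig(seed=0, between_subject_sd=0.0)


@pytest.fixture(scope="session")
def subject_recording(calibrated_config):
    """One default-length subject (60 trials) with exact injected effects."""
    return simulate_subject(calibrated_config, 0)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two-subject, 30-trial config for fast structural tests."""
    return SimConfig(n_subjects=2, n_trials=30, seed=1)


@pytest.fixture(scope="session")
def cohort_results():
    """Fitted study cohort: 14 subjects, 60 trials, full montage.

    Injected alpha increments 0 / +1.5 / +3.0 dB with 1 dB between-subject
    spread; the contraction-only effect (rest fraction 0) isolates the
    task-window contrast.  The frequency grid covers theta-beta so both
    the alpha recovery contrast and the 12-D classification features are
    available from one fit.
    """
    config = replace(SimConfig(seed=0), rest_fraction=0.0)
    recordings = simulate_cohort(config)
    model = FatigueSpectralModel(
        recordings, window="steady",
        channels=list(config.channel_labels),
        freqs=np.arange(4.0, 31.0),
    )
    return model.fit()
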