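"""Shared fixtures: scaled-down generator settings and tiny recordings.

Tests use reduced trial counts / sampling rates for speed; population effect
means and SDs stay at the package defaults unless a test injects controlled
values on purpose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from exobci.config import GeneratorParams, PreprocConfig
from exobci.io_prep import Event, Recording
from exobci.montage import CHANNELS_64
from exobci.synthgen import make_subject_profile, simulate_run


def small_params(**kw) -> GeneratorParams:
    defaults = dict(
        sampling_rate=500.0, trials_per_run=16, runs_per_task=1,
        blink_rate_per_min=0.0, rng_seed=7,
    )
    defaults.update(kw)
    return GeneratorParams(**defaults)


def zero_effect_params(**kw) -> GeneratorParams:
    """All effect means and SDs set to zero (pure noise model)."""
    p = small_params(**kw)
    for key in p.effects:
        p.effects[key] = {name: (0.0, 0.0) for name in p.effects[key]}
    return p


@pytest.fixture(scope="session")
def hs_profile():
    return make_subject_profile("HS", small_params(), seed=11)


@pytest.fixture(scope="session")
def small_run(hs_profile):
    return simulate_run(hs_profile, "PAS", 1, small_params())


@pytest.fixture(scope="session")
def noprep_policy():
    return PreprocConfig(ica_enabled=False)


def toy_recording(data: np.ndarray, fs: float = 200.0, labels=None,
                  events=None) -> Recording:
    labels = labels or list(CHANNELS_64[: data.shape[0]])
    return Recording(
        channel_labels=labels, reference_label="FCz", sampling_rate=fs,
        data=np.asarray(data, float), events=events or [], subject_id="toy",
    )


def sinusoid_recording(freq: float, fs: float = 1000.0, dur: float = 20.0,
                       n_channels: int = 4) -> Recording:
    t = np.arange(int(dur * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return toy_recording(data, fs=fs)
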