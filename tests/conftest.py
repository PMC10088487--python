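"""Shared fixtures: small synthetic datasets reused across test modules.

Session scope keeps the expensive generator + preprocessing runs to one
execution each; tests must not mutate fixture arrays in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from passive_lp import dpr_mapping as dm
from passive_lp.preprocess import bandpass_series, preprocess_trial, standardize_series
from passive_lp.nse_tracking import EnvelopeSignal
from passive_lp.synthetic import (ClassEffect, EnvelopeCoupling,
                                  SyntheticConfig, generate_dataset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230325)


@pytest.fixture(scope="session")
def null_dataset():
    """Pure-noise trial (no class effects, no envelope coupling)."""
    cfg = SyntheticConfig(seed=41, duration_s=148.0, n_channels=8)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def vowel_dataset():
    """Trial with a 2 SD vowel-locked bump at 120 ms on channels 2 and 3."""
    w = np.zeros(8)
    w[[2, 3]] = 1.0
    cfg = SyntheticConfig(
        seed=42, duration_s=148.0, n_channels=8,
        class_effects={"V": ClassEffect(amplitude_sd=2.0, latency_ms=120.0,
                                        duration_ms=60.0, channel_weights=w)},
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def vowel_epoch_sets(vowel_dataset):
    rec = preprocess_trial(vowel_dataset["recording"])
    sets = dm.extract_epochs(rec, vowel_dataset["annotation"])
    return dm.reject_epochs(sets)


def _coupled_dataset(seed: int, lag_ms: float):
    w = np.ones(8)
    w[[6, 7]] = 0.0  # two uncoupled channels act as internal controls
    cfg = SyntheticConfig(
        seed=seed, duration_s=148.0, n_channels=8,
        envelope_coupling=EnvelopeCoupling(amplitude_sd=0.25, lag_ms=lag_ms,
                                           channel_weights=w),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session", params=[48.0, 252.0])
def coupled_dataset(request):
    return _coupled_dataset(seed=43 + int(request.param), lag_ms=request.param)


@pytest.fixture(scope="session")
def preprocessed_envelope():
    """Band-pass + standardize an envelope the same way the pipeline does."""
    def _prep(env: EnvelopeSignal) -> EnvelopeSignal:
        return EnvelopeSignal(
            values=standardize_series(bandpass_series(env.values, env.rate_hz)),
            rate_hz=env.rate_hz)
    return _prep
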