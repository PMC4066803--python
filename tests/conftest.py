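"""Shared fixtures: the expensive synthetic datasets are session-scoped so
the acceptance-grade checks and the unit tests reuse one detection pass."""

from __future__ import annotations

import numpy as np
import pytest

from quadpop.model import QuadruplexPopulationModel
from quadpop.pipeline import DEFAULT_FPP_TIMES, detect_events
from quadpop.simulate import make_condition, simulate_fpp_series, simulate_fx_dataset


@pytest.fixture(scope="session")
def transcription_ts():
    """2000 regular-transcription F-X curves (fixed seed)."""
    return simulate_fx_dataset(make_condition("transcription"), n_curves=2000, seed=101)


@pytest.fixture(scope="session")
def transcription_events(transcription_ts):
    events, _ = detect_events(transcription_ts)
    return events


@pytest.fixture(scope="session")
def deaza_ts():
    return simulate_fx_dataset(make_condition("deaza"), n_curves=2000, seed=102)


@pytest.fixture(scope="session")
def deaza_events(deaza_ts):
    events, _ = detect_events(deaza_ts)
    return events


@pytest.fixture(scope="session")
def population_fit(transcription_events, deaza_events, transcription_ts, deaza_ts):
    """Full population analysis (3000 bootstrap resamples) on the
    transcription + deaza pair."""
    model = QuadruplexPopulationModel(
        {"transcription": transcription_events, "deaza": deaza_events},
        {"transcription": transcription_ts.n_curves, "deaza": deaza_ts.n_curves},
    )
    return model.fit(n_boot=3000, seed=7)


@pytest.fixture(scope="session")
def fpp_transcription():
    """FPP series under transcription: 8 incubation times x 500 cycles."""
    ts = simulate_fpp_series(
        make_condition("transcription"), DEFAULT_FPP_TIMES, n_cycles=500, seed=103
    )
    events, cycles = detect_events(ts)
    return ts, events, cycles


@pytest.fixture(scope="session")
def fpp_no_transcription():
    ts = simulate_fpp_series(
        make_condition("no_transcription"), DEFAULT_FPP_TIMES, n_cycles=500, seed=104
    )
    events, cycles = detect_events(ts)
    return ts, events, cycles


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
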