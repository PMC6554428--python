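"""Shared fixtures.

Tests run the full pipeline at the 250 Hz fast mode; the decoders only
depend on band ratios, not the absolute rate, so nothing scientific is
lost relative to the 1000 Hz acquisition default.
"""

from __future__ import annotations

import numpy as np
import pytest

from mmbci import blink as blink_mod
from mmbci import cicsp as cicsp_mod
from mmbci import controller as ctrl
from mmbci import synth
from mmbci.types import DEFAULT_CHANNELS, EEGRecording, EpochWindow

FAST_FS = 250.0


@pytest.fixture()
def fast_cfg() -> synth.SynthConfig:
    return synth.SynthConfig(fs=FAST_FS, seed=11)


@pytest.fixture(scope="session")
def mi_model() -> cicsp_mod.CICSPModel:
    cfg = synth.SynthConfig(fs=FAST_FS, seed=11)
    trials = synth.make_mi_trials(30, cfg)
    return cicsp_mod.fit_cicsp(trials)


@pytest.fixture(scope="session")
def blink_params() -> blink_mod.BlinkParams:
    cfg = synth.SynthConfig(fs=FAST_FS, seed=11)
    trials = synth.make_blink_trials(10, cfg)
    h = blink_mod.calibrate_h(trials)
    return blink_mod.BlinkParams(h=h)


@pytest.fixture(scope="session")
def decoders(mi_model, blink_params) -> ctrl.DecoderSet:
    return ctrl.DecoderSet(blink_params=blink_params, mi_model=mi_model)


def as_window(rec: EEGRecording, onset_s: float = 0.0,
              intent: str | None = None) -> EpochWindow:
    return EpochWindow(rec.data, rec.labels, rec.fs,
                       onset_s=onset_s, intent=intent)


@pytest.fixture()
def zero_recording() -> EEGRecording:
    n = int(1.5 * FAST_FS)
    return EEGRecording(np.zeros((len(DEFAULT_CHANNELS), n)),
                        DEFAULT_CHANNELS, FAST_FS)
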