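"""Shared signal conditioning: band-pass filtering, common average
reference, and the 1.5 s / 1 s sliding-window segmentation.

Each decoder consumes a differently filtered view of the same raw block:
0.3-30 Hz for blink detection, 5-40 Hz for SSVEP, 9-12 Hz (plus CAR over
the 10 sensorimotor electrodes) for motor imagery.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import signal

from .types import EEGRecording, EpochWindow, MI_CHANNELS

__all__ = ["bandpass", "car", "window_stream",
           "BLINK_BAND", "SSVEP_BAND", "MI_BAND",
           "WINDOW_S", "STRIDE_S"]

BLINK_BAND = (0.3, 30.0)
SSVEP_BAND = (5.0, 40.0)
MI_BAND = (9.0, 12.0)

#: Decoding window length and command cadence, seconds.
WINDOW_S = 1.5
STRIDE_S = 1.0

_FILTER_ORDER = 4


def _sos(lo: float, hi: float, fs: float) -> np.ndarray:
    return signal.butter(_FILTER_ORDER, [lo, hi], btype="bandpass",
                         fs=fs, output="sos")


def bandpass(rec: EEGRecording, lo: float, hi: float) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    A 4th-order filter is applied forward and backward (``sosfiltfilt``)
    so troughs and oscillation phases are not delayed; edges are handled
    by scipy's odd-reflection padding.
    """
    if not (0 < lo < hi < rec.fs / 2):
        raise ValueError(
            f"band [{lo}, {hi}] Hz invalid for fs={rec.fs} (need 0 < lo < hi < fs/2)"
        )
    out = signal.sosfiltfilt(_sos(lo, hi, rec.fs), rec.data, axis=1)
    filtered = rec.copy()
    filtered.data = np.ascontiguousarray(out)
    return filtered


def car(rec: EEGRecording, subset: Sequence[str] = MI_CHANNELS) -> EEGRecording:
    """Common average reference over *subset*; other channels untouched.

    At every sample the instantaneous mean across the subset channels is
    subtracted from each of them, removing spatially uniform activity
    (reference drift, the common component of the mu rhythm).
    """
    subset = tuple(subset)
    if len(subset) < 2:
        raise ValueError("CAR needs at least 2 channels")
    idx = [rec.index(l) for l in subset]
    out = rec.copy()
    out.data[idx] -= out.data[idx].mean(axis=0, keepdims=True)
    return out


def window_stream(
    rec: EEGRecording,
    length_s: float = WINDOW_S,
    stride_s: float = STRIDE_S,
    intents: Sequence[str] | None = None,
) -> Iterator[EpochWindow]:
    """Yield decoding windows at onsets 0, stride, 2*stride, ... while a
    full window fits.  Consecutive windows overlap by ``length - stride``.

    A recording shorter than one window yields nothing (not an error).
    When *intents* gives a per-sample ground-truth track, each window is
    tagged with the majority intent of its span.
    """
    if length_s <= 0 or stride_s <= 0:
        raise ValueError("length_s and stride_s must be positive")
    n_win = int(round(length_s * rec.fs))
    n_hop = int(round(stride_s * rec.fs))
    start = 0
    while start + n_win <= rec.n_samples:
        intent = None
        if intents is not None:
            span = list(intents[start:start + n_win])
            intent = max(set(span), key=span.count)
        yield EpochWindow(
            rec.data[:, start:start + n_win].copy(), rec.labels, rec.fs,
            onset_s=start / rec.fs, intent=intent,
        )
        start += n_hop
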