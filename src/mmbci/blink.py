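"""Conscious double-blink detection by the counting-trough method.

A voluntary blink produces a sharp negative deflection at the prefrontal
electrode Fp2.  Within each 1.5 s block the 0.3-30 Hz filtered Fp2 trace
is scanned for local minima deeper than a calibrated height ``h``,
accepted greedily left to right subject to a minimum spacing derived
from the trained inter-blink distance ``d`` (0.75 s).  Two accepted
troughs signal the hover-and-switch gesture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocess
from .types import BLINK_CHANNEL, EpochWindow, LabeledTrialSet

__all__ = ["BlinkParams", "CalibrationError", "calibrate_h",
           "count_troughs", "detect_blink"]


class CalibrationError(RuntimeError):
    """No usable troughs in the calibration trials."""


@dataclass
class BlinkParams:
    """Counting-trough parameters.

    ``d_s`` is the trained average distance between the two troughs of a
    conscious double blink; ``h`` the minimum absolute trough height in
    µV; ``beta`` relaxes the spacing constraint to ``beta * d_s`` so
    natural jitter in blink timing is tolerated.
    """

    d_s: float = 0.75
    h: float = 50.0
    count_threshold: int = 2
    beta: float = 0.6

    def __post_init__(self) -> None:
        if self.d_s <= 0:
            raise ValueError("d_s must be positive")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.count_threshold < 1:
            raise ValueError("count_threshold must be >= 1")


def _trough_depths(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and (positive) depths of strict local minima below zero.

    A plateau minimum is credited to its first sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return np.array([], dtype=int), np.array([])
    # plateau: equal to the right neighbor but eventually rising again is
    # still a single trough, credited to its first sample
    idx = []
    i = 1
    while i < len(x) - 1:
        if x[i] < x[i - 1]:
            j = i
            while j < len(x) - 1 and x[j + 1] == x[i]:
                j += 1
            if j < len(x) - 1 and x[j + 1] > x[i]:
                idx.append(i)
                i = j + 1
                continue
        i += 1
    idx = np.asarray(idx, dtype=int)
    neg = idx[x[idx] < 0] if idx.size else idx
    return neg, -x[neg]


def calibrate_h(
    blink_trials: LabeledTrialSet,
    alpha: float = 0.5,
    blink_label: str = "blink",
    prefiltered: bool = False,
) -> float:
    """Estimate the minimum trough height from calibration blinks.

    For every blink-labeled trial the deepest trough of the 0.3-30 Hz
    filtered Fp2 trace is taken; ``h`` is the mean of those depths scaled
    by the safety factor *alpha* (default 0.5), so blinks at least as
    strong as the trained ones are reliably caught.
    """
    depths = []
    trials = blink_trials.by_label(blink_label)
    if not trials:
        raise ValueError(f"no {blink_label!r}-labeled calibration trials")
    for rec in trials:
        if not prefiltered:
            rec = preprocess.bandpass(rec, *preprocess.BLINK_BAND)
        _, d = _trough_depths(rec.channel(BLINK_CHANNEL))
        if d.size:
            depths.append(d.max())
    if not depths:
        raise CalibrationError("no troughs found in any calibration trial")
    return alpha * float(np.mean(depths))


def count_troughs(x: np.ndarray, params: BlinkParams, fs: float) -> int:
    """Count qualifying troughs in one filtered Fp2 block.

    A sample qualifies if it is a local minimum at or below ``-h``;
    qualifying troughs are accepted greedily left to right, each at least
    ``beta * d_s`` seconds after the previously accepted one.
    """
    idx, depths = _trough_depths(np.asarray(x, dtype=float))
    min_gap = params.beta * params.d_s * fs
    count = 0
    last = -np.inf
    for i, dep in zip(idx, depths):
        if dep >= params.h and i - last >= min_gap:
            count += 1
            last = i
    return count


def detect_blink(
    window: EpochWindow, params: BlinkParams, prefiltered: bool = False
) -> bool:
    """True iff the window's Fp2 trace carries a conscious double blink."""
    rec = window if prefiltered else preprocess.bandpass(
        window, *preprocess.BLINK_BAND
    )
    x = rec.channel(BLINK_CHANNEL)
    return count_troughs(x, params, window.fs) >= params.count_threshold
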