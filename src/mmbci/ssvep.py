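"""SSVEP frequency recognition by canonical correlation analysis.

Gazing at an LED flickering at frequency f entrains the occipital EEG at
f and its harmonics.  For each candidate frequency a reference set of
sin/cos pairs at f..Nh*f is built and the first canonical correlation
with the Oz trace is computed; the candidate with the largest
correlation wins (ties go to the lower frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .types import EpochWindow, SSVEP_CHANNEL

__all__ = ["ReferenceSet", "CCAResult", "build_reference",
           "cca_coefficient", "classify_ssvep", "DEFAULT_FREQS"]

#: Stimulus frequencies of the top (rise) and bottom (fall) LEDs, Hz.
DEFAULT_FREQS = (12.4, 18.0)

#: Number of harmonics in a reference set.
DEFAULT_NH = 2

_RIDGE = 1e-8


@dataclass
class ReferenceSet:
    """Harmonic sin/cos reference series for one candidate frequency."""

    freq: float
    matrix: np.ndarray  # (2*Nh) x n_samples
    nh: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != 2 * self.nh:
            raise ValueError("reference matrix must have 2*Nh rows")


@dataclass
class CCAResult:
    """Per-frequency canonical correlations and the argmax decision."""

    coefficients: dict[float, float]
    decision: float


def build_reference(
    freq: float, nh: int, fs: float, n_samples: int
) -> ReferenceSet:
    """Sin/cos pairs at k*freq, k = 1..nh, sampled at t = 0, 1/fs, ...

    Rows alternate sin, cos per harmonic, matching the Fourier-series
    reference construction standard in SSVEP recognition.
    """
    if nh * freq >= fs / 2:
        raise ValueError(
            f"highest harmonic {nh * freq} Hz aliases at fs={fs}"
        )
    t = np.arange(n_samples) / fs
    rows = []
    for k in range(1, nh + 1):
        rows.append(np.sin(2 * np.pi * k * freq * t))
        rows.append(np.cos(2 * np.pi * k * freq * t))
    return ReferenceSet(freq=freq, matrix=np.vstack(rows), nh=nh)


def cca_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """First canonical correlation between row-variable sets X and Y.

    Computed as the largest singular value of the whitened
    cross-covariance ``Cxx^{-1/2} Cxy Cyy^{-1/2}``; a small ridge
    (1e-8 of the trace) keeps the whitening stable when a set is close
    to rank-deficient.  Returns a value clipped to [0, 1].
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[1]
    if Y.shape[1] != n:
        raise ValueError("X and Y must have the same number of samples")
    if n <= max(X.shape[0], Y.shape[0]):
        raise ValueError("need more samples than variables in either set")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if not Xc.any() or not Yc.any():
        warnings.warn("zero-variance input to CCA; returning rho = 0",
                      stacklevel=2)
        return 0.0
    Cxx = Xc @ Xc.T / (n - 1)
    Cyy = Yc @ Yc.T / (n - 1)
    Cxy = Xc @ Yc.T / (n - 1)
    Cxx += _RIDGE * np.trace(Cxx) / Cxx.shape[0] * np.eye(Cxx.shape[0])
    Cyy += _RIDGE * np.trace(Cyy) / Cyy.shape[0] * np.eye(Cyy.shape[0])
    Wx = linalg.inv(linalg.sqrtm(Cxx).real)
    Wy = linalg.inv(linalg.sqrtm(Cyy).real)
    s = linalg.svdvals(Wx @ Cxy @ Wy)
    return float(np.clip(s[0], 0.0, 1.0))


def classify_ssvep(
    window: EpochWindow,
    freqs: tuple[float, ...] = DEFAULT_FREQS,
    nh: int = DEFAULT_NH,
) -> CCAResult:
    """Decide which stimulus frequency a (5-40 Hz filtered) window follows.

    The Oz trace is correlated against each candidate's harmonic
    reference set; the largest first canonical correlation decides, with
    ties broken toward the lower frequency.
    """
    x = window.channel(SSVEP_CHANNEL)[None, :]
    coeffs: dict[float, float] = {}
    for f in freqs:
        ref = build_reference(f, nh, window.fs, window.n_samples)
        coeffs[f] = cca_coefficient(x, ref.matrix)
    best = min(sorted(coeffs), key=lambda f: (-coeffs[f], f))
    return CCAResult(coefficients=coeffs, decision=best)
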