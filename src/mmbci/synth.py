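"""Synthetic multichannel EEG with the statistical structure each decoder
assumes: pink-noise background with a sensorimotor mu rhythm, lateralized
mu-band ERD for left/right motor imagery, occipital SSVEP at the stimulus
frequency and its first harmonic, and large negative blink troughs at Fp2.

Every generator is deterministic given ``(config, seed)``, so decoder
tests and end-to-end controller runs are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .types import (
    BLINK_CHANNEL,
    DEFAULT_CHANNELS,
    EEGRecording,
    LabeledTrialSet,
    SSVEP_CHANNEL,
)

__all__ = [
    "SynthConfig",
    "generate_background",
    "inject_ssvep",
    "inject_mi_erd",
    "inject_blinks",
    "generate_session",
    "make_mi_trials",
    "make_ssvep_trials",
    "make_blink_trials",
    "CONTRALATERAL",
    "IPSILATERAL",
]

#: Channels whose mu power drops during imagery of each hand (ERD is
#: contralateral: left-hand imagery desynchronizes the right hemisphere).
CONTRALATERAL = {
    "left": ("FC2", "FC4", "C2", "C4", "CP2"),
    "right": ("FC1", "FC3", "C1", "C3", "CP1"),
}
#: ... while the same-side hemisphere synchronizes (ERS).
IPSILATERAL = {"left": CONTRALATERAL["right"], "right": CONTRALATERAL["left"]}

#: Relative mu-rhythm strength per sensorimotor channel (strongest over
#: the hand knob C3/C4, fading frontally and parietally).
_MU_TOPOGRAPHY = {
    "C3": 1.0, "C4": 1.0, "C1": 0.85, "C2": 0.85,
    "CP1": 0.7, "CP2": 0.7, "FC3": 0.6, "FC4": 0.6,
    "FC1": 0.5, "FC2": 0.5,
}

_MU_FREQ = 10.0  # Hz, center of the 9-12 Hz band

#: Intents a session script may use.
SESSION_INTENTS = ("left", "right", "f12.4", "f18", "blink", "idle")


@dataclass
class SynthConfig:
    """Free parameters of the synthetic EEG.

    Amplitudes are in microvolts.  The defaults describe a clean,
    calibration-quality recording; ``erd_depth=0`` or ``ssvep_amp=0``
    produce null (chance-level) data for negative controls.
    """

    duration_s: float = 1.5
    fs: float = 1000.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    noise_scale: float = 10.0        # µV RMS of 1/f background per channel
    mu_amp: float = 8.0              # µV, mu oscillation at C3/C4
    ssvep_amp: float = 4.0           # µV at the fundamental
    ssvep_harmonic_ratio: float = 0.5  # amplitude of 2f relative to f
    erd_depth: float = 0.8           # fractional mu attenuation, in [0, 1]
    erd_ipsi_gain: float = 0.5       # ERS strength relative to depth
    blink_depth: float = 120.0       # µV trough magnitude
    blink_width_s: float = 0.2       # s, full width of the blink pulse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0 <= self.erd_depth <= 1:
            raise ValueError(f"erd_depth must lie in [0, 1], got {self.erd_depth}")


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-RMS noise with 1/f amplitude spectrum, per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    weight = np.zeros_like(f)
    weight[1:] = 1.0 / f[1:]          # drop DC entirely
    x = np.fft.irfft(spec * weight, n=n, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def generate_background(config: SynthConfig) -> EEGRecording:
    """Pink-noise background plus a common mu-band rhythm on the
    sensorimotor channels, with the topography of :data:`_MU_TOPOGRAPHY`.

    Deterministic under ``config.seed``; with ``noise_scale=0`` and
    ``mu_amp=0`` the output is identically zero.
    """
    n = int(round(config.duration_s * config.fs))
    labels = tuple(config.channel_labels)
    rng = np.random.default_rng(config.seed)
    data = np.zeros((len(labels), n))
    if config.noise_scale > 0:
        data += config.noise_scale * _pink_noise(rng, len(labels), n)
    if config.mu_amp > 0:
        t = np.arange(n) / config.fs
        mu = np.sin(2 * np.pi * _MU_FREQ * t)
        for i, lab in enumerate(labels):
            gain = _MU_TOPOGRAPHY.get(_canonical(lab), 0.0)
            data[i] += config.mu_amp * gain * mu
    return EEGRecording(data, labels, config.fs)


def _canonical(label: str) -> str:
    for k in _MU_TOPOGRAPHY:
        if k.lower() == label.lower():
            return k
    return label


def inject_ssvep(
    rec: EEGRecording, freq: float, amp: float, harmonic_ratio: float = 0.5
) -> EEGRecording:
    """Add a steady-state response at *freq* and its first harmonic to Oz.

    Only the occipital channel is touched: the response is
    ``amp*sin(2*pi*f*t) + amp*harmonic_ratio*sin(2*pi*2f*t)``.
    """
    if freq >= rec.fs / 4:
        raise ValueError(
            f"freq={freq} too high: 2*freq must stay below Nyquist (fs={rec.fs})"
        )
    out = rec.copy()
    if amp == 0:
        return out
    i = out.index(SSVEP_CHANNEL)
    t = out.times
    out.data[i] += amp * np.sin(2 * np.pi * freq * t)
    out.data[i] += amp * harmonic_ratio * np.sin(2 * np.pi * 2 * freq * t)
    return out


def inject_mi_erd(
    rec: EEGRecording,
    side: str,
    depth: float,
    ipsi_gain: float = 0.5,
) -> EEGRecording:
    """Lateralized event-related (de)synchronization of the mu band.

    The 9-12 Hz component of the hemisphere contralateral to the imagined
    hand is attenuated by ``(1 - depth)``; the ipsilateral hemisphere is
    amplified by ``(1 + depth*ipsi_gain)``.  Other channels and the rest
    of the spectrum are untouched.
    """
    if side not in CONTRALATERAL:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not 0 <= depth <= 1:
        raise ValueError(f"depth must lie in [0, 1], got {depth}")
    out = rec.copy()
    if depth == 0:
        return out
    band = preprocess.bandpass(rec, *preprocess.MI_BAND)
    for lab in CONTRALATERAL[side]:
        i = out.index(lab)
        out.data[i] -= depth * band.data[i]
    for lab in IPSILATERAL[side]:
        i = out.index(lab)
        out.data[i] += depth * ipsi_gain * band.data[i]
    return out


def _blink_pulse(width_s: float, fs: float) -> np.ndarray:
    n = max(int(round(width_s * fs)), 3)
    w = np.hanning(n)
    return w / w.max()  # peak exactly 1 so the trough depth is exact


def inject_blinks(
    rec: EEGRecording,
    times: list[float],
    depth: float,
    width_s: float = 0.2,
) -> EEGRecording:
    """Subtract a raised-cosine pulse of magnitude *depth* from Fp2 at
    each time, emulating the sharp negative deflection of an eye blink.

    Pulses must fit inside the recording and must not overlap.
    """
    out = rec.copy()
    if not times:
        return out
    times = sorted(times)
    for a, b in zip(times, times[1:]):
        if b - a < width_s:
            raise ValueError(
                f"blink pulses at {a:.3f}s and {b:.3f}s overlap (width {width_s}s)"
            )
    pulse = depth * _blink_pulse(width_s, rec.fs)
    half = len(pulse) // 2
    i = out.index(BLINK_CHANNEL)
    for t in times:
        c = int(round(t * rec.fs))
        lo, hi = c - half, c - half + len(pulse)
        if lo < 0 or hi > rec.n_samples:
            raise ValueError(f"blink at {t:.3f}s does not fit in the recording")
        out.data[i, lo:hi] -= pulse
    return out


def _apply_intent_span(
    rec: EEGRecording,
    band: EEGRecording,
    intent: str,
    i0: int,
    i1: int,
    config: SynthConfig,
) -> None:
    """Mutate rec.data on samples [i0, i1) according to *intent*."""
    fs = rec.fs
    if intent in ("left", "right"):
        d, g = config.erd_depth, config.erd_ipsi_gain
        for lab in CONTRALATERAL[intent]:
            i = rec.index(lab)
            rec.data[i, i0:i1] -= d * band.data[i, i0:i1]
        for lab in IPSILATERAL[intent]:
            i = rec.index(lab)
            rec.data[i, i0:i1] += d * g * band.data[i, i0:i1]
    elif intent in ("f12.4", "f18"):
        freq = float(intent[1:])
        i = rec.index(SSVEP_CHANNEL)
        t = np.arange(i0, i1) / fs
        rec.data[i, i0:i1] += config.ssvep_amp * (
            np.sin(2 * np.pi * freq * t)
            + config.ssvep_harmonic_ratio * np.sin(2 * np.pi * 2 * freq * t)
        )
    elif intent == "blink":
        # a conscious double blink every 1.5 s stretch of the span
        pulse = config.blink_depth * _blink_pulse(config.blink_width_s, fs)
        half = len(pulse) // 2
        i = rec.index(BLINK_CHANNEL)
        block = int(round(1.5 * fs))
        for start in range(i0, i1 - block + 1, block):
            for rel in (0.3, 1.05):
                c = start + int(round(rel * fs))
                lo, hi = c - half, c - half + len(pulse)
                if lo >= 0 and hi <= rec.n_samples:
                    rec.data[i, lo:hi] -= pulse
    elif intent != "idle":
        raise ValueError(f"unknown intent {intent!r}")


def generate_session(
    script: list[tuple[str, float]], config: SynthConfig
) -> tuple[EEGRecording, np.ndarray]:
    """Concatenate intent spans into one recording with a per-sample
    ground-truth track.

    *script* is a list of ``(intent, duration_s)`` with intents drawn from
    ``{left, right, f12.4, f18, blink, idle}``.  Returns the recording and
    an array of intent labels, one per sample.
    """
    if not script:
        raise ValueError("session script is empty")
    durations = [d for _, d in script]
    if any(d <= 0 for d in durations):
        raise ValueError("span durations must be positive")
    total = float(sum(durations))
    cfg = SynthConfig(**{**config.__dict__, "duration_s": total})
    rec = generate_background(cfg)
    band = preprocess.bandpass(rec, *preprocess.MI_BAND)
    truth = np.empty(rec.n_samples, dtype=object)
    pos = 0.0
    for intent, dur in script:
        if intent not in SESSION_INTENTS:
            raise ValueError(f"unknown intent {intent!r}")
        i0 = int(round(pos * cfg.fs))
        i1 = int(round((pos + dur) * cfg.fs))
        i1 = min(i1, rec.n_samples)
        _apply_intent_span(rec, band, intent, i0, i1, cfg)
        truth[i0:i1] = intent
        pos += dur
    truth[truth == None] = "idle"  # noqa: E711 — object array fill
    return rec, truth.astype(str)


# ---------------------------------------------------------------------------
# Calibration trial sets


def make_mi_trials(
    n_per_class: int, config: SynthConfig, trial_s: float = 1.5
) -> LabeledTrialSet:
    """Left/right motor-imagery calibration trials at ``config.erd_depth``."""
    trials = []
    for k in range(n_per_class):
        for j, side in enumerate(("left", "right")):
            cfg = SynthConfig(**{**config.__dict__,
                                 "duration_s": trial_s,
                                 "seed": config.seed + 2 * k + j + 1})
            rec = generate_background(cfg)
            rec = inject_mi_erd(rec, side, cfg.erd_depth, cfg.erd_ipsi_gain)
            trials.append((rec, side))
    return LabeledTrialSet(trials)


def make_ssvep_trials(
    n_per_class: int, config: SynthConfig,
    freqs: tuple[float, ...] = (12.4, 18.0), trial_s: float = 1.5,
) -> LabeledTrialSet:
    """SSVEP trials, one label ``f<freq>`` per stimulus frequency."""
    trials = []
    for k in range(n_per_class):
        for j, f in enumerate(freqs):
            cfg = SynthConfig(**{**config.__dict__,
                                 "duration_s": trial_s,
                                 "seed": config.seed + len(freqs) * k + j + 1})
            rec = generate_background(cfg)
            rec = inject_ssvep(rec, f, cfg.ssvep_amp, cfg.ssvep_harmonic_ratio)
            trials.append((rec, f"f{f:g}"))
    return LabeledTrialSet(trials)


def make_blink_trials(
    n_per_class: int, config: SynthConfig, trial_s: float = 1.5
) -> LabeledTrialSet:
    """Double-blink vs. idle trials for calibrating the trough height."""
    trials = []
    for k in range(n_per_class):
        for j, lab in enumerate(("blink", "no-blink")):
            cfg = SynthConfig(**{**config.__dict__,
                                 "duration_s": trial_s,
                                 "seed": config.seed + 2 * k + j + 1})
            rec = generate_background(cfg)
            if lab == "blink":
                rec = inject_blinks(rec, [0.3, 1.05], cfg.blink_depth,
                                    cfg.blink_width_s)
            trials.append((rec, lab))
    return LabeledTrialSet(trials)
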