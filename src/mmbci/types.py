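"""Core containers shared by every decoding stage.

An :class:`EEGRecording` is a channels x samples matrix in microvolts with
named channels and a sampling rate.  An :class:`EpochWindow` is the 1.5 s
decoding segment the online pipeline consumes.  A :class:`LabeledTrialSet`
holds calibration trials with intent labels for training the decoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EEGRecording",
    "EpochWindow",
    "LabeledTrialSet",
    "MissingChannelError",
    "DEFAULT_CHANNELS",
    "MI_CHANNELS",
    "SSVEP_CHANNEL",
    "BLINK_CHANNEL",
]

#: The 12-electrode montage used throughout (10/20 labels, reference Cz).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "CP1", "CP2", "FC1", "FC2", "FC3", "FC4",
    "C1", "C2", "C3", "C4", "Oz", "Fp2",
)

#: The 10 sensorimotor electrodes used for motor-imagery decoding.
MI_CHANNELS: tuple[str, ...] = (
    "CP1", "CP2", "FC1", "FC2", "FC3", "FC4", "C1", "C2", "C3", "C4",
)

#: Occipital channel carrying the steady-state visual evoked response.
SSVEP_CHANNEL = "Oz"

#: Prefrontal channel carrying the blink artifact.
BLINK_CHANNEL = "Fp2"


class MissingChannelError(KeyError):
    """Raised when an operation needs a channel the recording lacks."""


def _validate(data: np.ndarray, labels: Sequence[str], fs: float) -> None:
    if data.ndim != 2:
        raise ValueError(f"data must be 2-D (channels x samples), got ndim={data.ndim}")
    if data.shape[0] != len(labels):
        raise ValueError(
            f"{data.shape[0]} data rows but {len(labels)} channel labels"
        )
    lowered = [l.lower() for l in labels]
    if len(set(lowered)) != len(lowered):
        raise ValueError("channel labels must be unique (case-insensitive)")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts.
    labels
        Channel names, one per row.  Matching is case-insensitive.
    fs
        Sampling rate in Hz.
    """

    data: np.ndarray
    labels: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = tuple(self.labels)
        _validate(self.data, self.labels, self.fs)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def index(self, label: str) -> int:
        """Row index of *label* (case-insensitive)."""
        lowered = [l.lower() for l in self.labels]
        try:
            return lowered.index(label.lower())
        except ValueError:
            raise MissingChannelError(
                f"channel {label!r} not in {list(self.labels)}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """1-D view of one channel's samples."""
        return self.data[self.index(label)]

    def has_channel(self, label: str) -> bool:
        return label.lower() in (l.lower() for l in self.labels)

    def pick(self, labels: Iterable[str]) -> "EEGRecording":
        """Sub-recording restricted to *labels*, in the given order."""
        labels = tuple(labels)
        idx = [self.index(l) for l in labels]
        return EEGRecording(self.data[idx].copy(), labels, self.fs)

    def copy(self) -> "EEGRecording":
        return EEGRecording(self.data.copy(), self.labels, self.fs)

    def crop(self, start_s: float, stop_s: float) -> "EEGRecording":
        """Sub-recording spanning [start_s, stop_s)."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError(f"crop [{start_s}, {stop_s}) outside recording")
        return EEGRecording(self.data[:, i0:i1].copy(), self.labels, self.fs)


@dataclass
class EpochWindow(EEGRecording):
    """A decoding segment (nominally 1.5 s) with its onset time.

    ``intent`` optionally carries the ground-truth label when the window
    came from a scripted synthetic session.
    """

    onset_s: float = 0.0
    intent: str | None = None

    @classmethod
    def from_recording(
        cls, rec: EEGRecording, onset_s: float, length_s: float,
        intent: str | None = None,
    ) -> "EpochWindow":
        sub = rec.crop(onset_s, onset_s + length_s)
        return cls(sub.data, sub.labels, sub.fs, onset_s=onset_s, intent=intent)


@dataclass
class LabeledTrialSet:
    """Calibration trials with class labels.

    Every trial must share the sampling rate and channel set of the first;
    this is what the covariance/CCA estimators assume.
    """

    trials: list[tuple[EEGRecording, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trials:
            ref = self.trials[0][0]
            for rec, _ in self.trials[1:]:
                if rec.fs != ref.fs:
                    raise ValueError("trials must share a sampling rate")
                if tuple(l.lower() for l in rec.labels) != tuple(
                    l.lower() for l in ref.labels
                ):
                    raise ValueError("trials must share the channel set")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, lab in self.trials:
            seen.setdefault(lab, None)
        return tuple(seen)

    def by_label(self, label: str) -> list[EEGRecording]:
        return [rec for rec, lab in self.trials if lab == label]

    def map(self, fn) -> "LabeledTrialSet":
        """Apply *fn* to every trial recording, keeping labels."""
        return LabeledTrialSet([(fn(rec), lab) for rec, lab in self.trials])
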