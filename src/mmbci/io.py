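"""Readers and writers for recordings, ground-truth tracks, and command
logs.

Recordings move through two interchangeable formats: a delimited text
matrix (header row of channel labels, first column time in seconds,
values in µV) and EDF (European Data Format).  EDF reading goes through
mne; writing uses a minimal EDF encoder since the installed stack has no
EDF exporter.  Channel-label matching is case-insensitive everywhere.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .controller import CommandLog
from .types import EEGRecording

__all__ = [
    "write_delimited", "read_delimited",
    "write_edf", "read_edf",
    "truth_to_spans", "write_truth_csv", "read_truth_csv", "spans_to_track",
    "write_command_csv", "read_command_csv",
]


# ---------------------------------------------------------------------------
# Delimited text matrix


def write_delimited(rec: EEGRecording, path, sep: str = ",") -> None:
    """Header row = ``time`` + channel labels; one row per sample."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
    df.insert(0, "time", rec.times)
    df.to_csv(path, sep=sep, index=False, float_format="%.6f")


def read_delimited(path, sep: str = ",") -> EEGRecording:
    df = pd.read_csv(path, sep=sep)
    time_col = next(c for c in df.columns if c.lower() == "time")
    t = df[time_col].to_numpy()
    if len(t) < 2:
        raise ValueError("need at least 2 samples to infer the sampling rate")
    fs = 1.0 / np.median(np.diff(t))
    labels = tuple(c for c in df.columns if c != time_col)
    return EEGRecording(df[list(labels)].to_numpy().T, labels, round(fs, 6))


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path) -> None:
    """Minimal EDF writer: int16 quantization against per-channel
    physical ranges, µV units, 1 s data records when the sample count
    allows, otherwise a single full-length record."""
    n_ch, n = rec.n_channels, rec.n_samples
    fs = rec.fs
    if n % int(fs) == 0 and fs == int(fs):
        spr = int(fs)           # samples per record
        record_dur = 1.0
    else:
        spr = n
        record_dur = n / fs
    n_records = n // spr
    dig_min, dig_max = -32768, 32767
    pmins, pmaxs, scaled = [], [], []
    for ch in rec.data:
        amp = max(np.abs(ch).max(), 1.0)
        pmin, pmax = -amp, amp
        gain = (dig_max - dig_min) / (pmax - pmin)
        d = np.round((ch - pmin) * gain + dig_min).astype("<i2")
        pmins.append(pmin)
        pmaxs.append(pmax)
        scaled.append(d)
    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X", 80),
        _edf_field("mmbci synthetic", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(f"{record_dur:g}", 8),
        _edf_field(n_ch, 4),
    ])
    sig_fields = [
        [lab for lab in rec.labels],                  # label, 16
        ["" for _ in rec.labels],                     # transducer, 80
        ["uV" for _ in rec.labels],                   # dimension, 8
        [f"{p:.6g}"[:8] for p in pmins],              # physical min, 8
        [f"{p:.6g}"[:8] for p in pmaxs],              # physical max, 8
        [dig_min for _ in rec.labels],                # digital min, 8
        [dig_max for _ in rec.labels],                # digital max, 8
        ["" for _ in rec.labels],                     # prefiltering, 80
        [spr for _ in rec.labels],                    # samples/record, 8
        ["" for _ in rec.labels],                     # reserved, 32
    ]
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    for vals, width in zip(sig_fields, widths):
        header += b"".join(_edf_field(v, width) for v in vals)
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for d in scaled:
                fh.write(d[r * spr:(r + 1) * spr].tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file through mne; values are returned in µV."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts
    return EEGRecording(data, tuple(raw.ch_names), float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# Ground-truth intent track


def truth_to_spans(truth: np.ndarray, fs: float) -> pd.DataFrame:
    """Compress a per-sample intent track to (onset_s, duration_s, intent)."""
    truth = np.asarray(truth, dtype=str)
    change = np.flatnonzero(truth[1:] != truth[:-1]) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(truth)]])
    return pd.DataFrame({
        "onset_s": starts / fs,
        "duration_s": (stops - starts) / fs,
        "intent": truth[starts],
    })


def write_truth_csv(truth: np.ndarray, fs: float, path) -> None:
    truth_to_spans(truth, fs).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def spans_to_track(spans: pd.DataFrame, fs: float, n_samples: int) -> np.ndarray:
    """Expand a span table back to one intent label per sample."""
    track = np.full(n_samples, "idle", dtype=object)
    for _, row in spans.iterrows():
        i0 = int(round(row.onset_s * fs))
        i1 = min(int(round((row.onset_s + row.duration_s) * fs)), n_samples)
        track[i0:i1] = row.intent
    return track.astype(str)


# ---------------------------------------------------------------------------
# Command log


def write_command_csv(log: CommandLog, path) -> None:
    rows = [{
        "onset_s": e.onset_s,
        "mode": e.mode_before.value,
        "command": e.command.kind.value,
        "yaw_deg": e.command.yaw_deg,
        "forward_mps": e.command.forward_mps,
        "vertical_mps": e.command.vertical_mps,
    } for e in log]
    pd.DataFrame(rows, columns=["onset_s", "mode", "command", "yaw_deg",
                                "forward_mps", "vertical_mps"]
                 ).to_csv(path, index=False)


def read_command_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
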