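"""Flight-performance metrics for physical-world BCI tasks.

Four metrics summarize a flight log: the Fitts-law index of difficulty
divided by the average gate acquisition time gives an analogous
information transfer rate (ITR, bit/min); AGAT (min/gate) measures
speed; OBUT measures boundary violations per unit time; PTC is the
fraction of gate attempts that succeeded.

The OBUT formula as usually written (crossings / (total time / average
trial time)) algebraically reduces to crossings per trial, yet published
per-subject values are consistently crossings per minute of flight;
both variants are available, the time-rate one ("table") by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskGeometry", "FlightLog", "MetricsReport", "UndefinedMetricError",
    "index_of_difficulty", "agat", "obut", "ptc", "analogous_itr",
    "summarize", "table_mean",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. no gates passed)."""


@dataclass(frozen=True)
class TaskGeometry:
    """Start-to-gate distance and gate width, meters."""

    distance_m: float = 4.75
    gate_width_m: float = 3.5

    def __post_init__(self) -> None:
        if self.distance_m <= 0 or self.gate_width_m <= 0:
            raise ValueError("geometry must be positive")


@dataclass(frozen=True)
class FlightLog:
    """Raw counts for one subject's session of repeated gate passages."""

    subject: str
    trials: int
    gates_passed: int
    boundary_crossings: int
    total_flight_time_min: float
    gates_per_trial: int = 1

    def __post_init__(self) -> None:
        if min(self.trials, self.gates_passed, self.boundary_crossings) < 0:
            raise ValueError("counts must be non-negative")
        if self.gates_passed > self.trials * self.gates_per_trial:
            raise ValueError("more gates passed than attempted")

    @property
    def failures(self) -> int:
        """Gate attempts that did not succeed."""
        return self.trials * self.gates_per_trial - self.gates_passed


@dataclass(frozen=True)
class MetricsReport:
    agat_min_per_gate: float
    obut_per_min: float
    ptc_fraction: float
    itr_bit_per_min: float
    difficulty_bits: float


def index_of_difficulty(geom: TaskGeometry) -> float:
    """Fitts-law index of difficulty, ``log2(distance/width + 1)`` bits."""
    return math.log2(geom.distance_m / geom.gate_width_m + 1.0)


def agat(total_flight_time_min: float, gates_passed: int) -> float:
    """Average gate acquisition time: total flight time / gates passed."""
    if gates_passed <= 0:
        raise UndefinedMetricError("AGAT undefined with zero gates passed")
    return total_flight_time_min / gates_passed


def obut(
    boundary_crossings: int,
    total_flight_time_min: float,
    trials: int | None = None,
    variant: str = "table",
) -> float:
    """Out-of-boundary rate.

    ``variant="table"`` (default): crossings per minute of total flight
    time.  ``variant="equation"``: crossings / (total time / average
    trial time), which reduces to crossings per trial and then needs
    *trials*.
    """
    if variant == "table":
        if total_flight_time_min <= 0:
            raise UndefinedMetricError("OBUT undefined with zero flight time")
        return boundary_crossings / total_flight_time_min
    if variant == "equation":
        if trials is None or trials <= 0:
            raise ValueError("equation variant needs a positive trial count")
        return boundary_crossings / trials
    raise ValueError(f"unknown OBUT variant {variant!r}")


def ptc(gates_passed: int, failures: int) -> float:
    """Percent task correct as a fraction: gates / (gates + failures)."""
    if gates_passed + failures <= 0:
        raise UndefinedMetricError("PTC undefined with no attempts")
    if min(gates_passed, failures) < 0:
        raise ValueError("counts must be non-negative")
    return gates_passed / (gates_passed + failures)


def analogous_itr(
    geom: TaskGeometry, total_flight_time_min: float, gates_passed: int
) -> float:
    """Index of difficulty over the (unrounded) gate acquisition time."""
    return index_of_difficulty(geom) / agat(total_flight_time_min, gates_passed)


def _report(log: FlightLog, geom: TaskGeometry, variant: str) -> MetricsReport:
    return MetricsReport(
        agat_min_per_gate=agat(log.total_flight_time_min, log.gates_passed),
        obut_per_min=obut(log.boundary_crossings, log.total_flight_time_min,
                          log.trials, variant=variant),
        ptc_fraction=ptc(log.gates_passed, log.failures),
        itr_bit_per_min=analogous_itr(geom, log.total_flight_time_min,
                                      log.gates_passed),
        difficulty_bits=index_of_difficulty(geom),
    )


def summarize(
    logs: list[FlightLog],
    geom: TaskGeometry = TaskGeometry(),
    variant: str = "table",
) -> pd.DataFrame:
    """Per-subject metrics plus an ``Average`` row (arithmetic mean of the
    per-subject metrics, computed from unrounded intermediates)."""
    if not logs:
        raise ValueError("need at least one flight log")
    gpt = {log.gates_per_trial for log in logs}
    if len(gpt) != 1:
        raise ValueError("logs mix gates_per_trial values")
    rows = []
    for log in logs:
        r = _report(log, geom, variant)
        rows.append({
            "subject": log.subject,
            "agat_min_per_gate": r.agat_min_per_gate,
            "obut_per_min": r.obut_per_min,
            "ptc_pct": 100.0 * r.ptc_fraction,
            "itr_bit_per_min": r.itr_bit_per_min,
        })
    df = pd.DataFrame(rows).set_index("subject")
    df.loc["Average"] = df.mean(axis=0)
    return df


def table_mean(column) -> float:
    """Arithmetic mean of a printed column, reported to 2 decimals."""
    column = np.asarray(column, dtype=float)
    if column.size == 0:
        raise ValueError("empty column")
    return round(float(column.mean()), 2)
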