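"""Published per-subject results shipped as inputs.

These are the printed per-subject cells of the original study's result
tables: calibration success rates for the three recognition modes, and
the raw counts of the simple (one gate per trial) and complex (two gates
per trial) outdoor flight tasks.  They are inputs to the metric
computations, not outputs of this package.
"""

from __future__ import annotations

import pandas as pd

from .flight_metrics import FlightLog

__all__ = [
    "calibration_success_rates",
    "simple_task_logs",
    "complex_task_logs",
    "simple_task_table",
]


def calibration_success_rates() -> pd.DataFrame:
    """Calibration-phase success rates (%) for nine subjects.

    Columns: SSVEP recognition, motor imagery with plain CSP and with
    CICSP features, eye-blink detection, and the entire-task rate.
    """
    data = {
        "subject": [1, 2, 3, 4, 5, 6, 7, 8, 9],
        "ssvep": [78.44, 62.19, 99.38, 50.63, 97.76, 97.06, 97.62, 87.05, 80.80],
        "mi_csp": [82.61, 74.72, 51.54, 41.62, 86.94, 91.51, 92.04, 85.99, 86.20],
        "mi_cicsp": [84.43, 78.82, 60.14, 49.63, 88.76, 93.70, 91.63, 87.97, 88.95],
        "eye_blinking": [100.0, 97.92, 100.0, 100.0, 97.92, 100.0, 100.0, 95.83, 100.0],
        "entire_task": [87.62, 79.64, 86.51, 66.75, 94.81, 96.92, 96.42, 90.28, 89.92],
    }
    return pd.DataFrame(data).set_index("subject")


def simple_task_table() -> pd.DataFrame:
    """Simple flight task: 10 trials per subject, one gate per trial."""
    data = {
        "subject": ["Sub5", "Sub6", "Sub7", "Sub8", "Sub9"],
        "trials": [10, 10, 10, 10, 10],
        "gates_passed": [9, 10, 10, 9, 8],
        "boundary_crossings": [0, 0, 0, 1, 1],
        "total_flight_time_min": [4.8, 3.8, 4.2, 5.2, 5.1],
    }
    return pd.DataFrame(data).set_index("subject")


def simple_task_logs() -> list[FlightLog]:
    return [
        FlightLog(subject=s, trials=int(r.trials),
                  gates_passed=int(r.gates_passed),
                  boundary_crossings=int(r.boundary_crossings),
                  total_flight_time_min=float(r.total_flight_time_min),
                  gates_per_trial=1)
        for s, r in simple_task_table().iterrows()
    ]


def complex_task_logs() -> list[FlightLog]:
    """Complex flight task: 20 trials per subject, two gates per trial.

    A full success passes both gates, a half success one; gates_passed is
    2 * successes + half_successes.
    """
    raw = [
        # subject, trials, successes, half, gates, crossings, time (min)
        ("Sub5", 20, 16, 4, 36, 0, 27.4),
        ("Sub6", 20, 19, 1, 39, 0, 20.7),
        ("Sub7", 20, 19, 0, 38, 1, 22.1),
        ("Sub8", 20, 16, 1, 33, 3, 30.0),
        ("Sub9", 20, 12, 3, 27, 5, 34.0),
    ]
    logs = []
    for subject, trials, succ, half, gates, crossings, time_min in raw:
        assert gates == 2 * succ + half, "gate count inconsistent with outcomes"
        logs.append(FlightLog(
            subject=subject, trials=trials, gates_passed=gates,
            boundary_crossings=crossings, total_flight_time_min=time_min,
            gates_per_trial=2,
        ))
    return logs
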