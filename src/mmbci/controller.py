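"""Mode-switching flight controller.

Every second a 1.5 s EEG window is decoded.  The blink check runs first:
a conscious double blink emits HOVER_SWITCH (zero velocities) and
toggles between the two flight modes.  Otherwise the window goes to the
active mode's decoder — motor imagery steers left-forward/right-forward,
SSVEP steers rise/fall.  A one-stride refractory period after a switch
stops a blink that spans two overlapping windows from toggling twice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import blink as blink_mod
from . import cicsp as cicsp_mod
from . import preprocess
from . import ssvep as ssvep_mod
from .types import EEGRecording, EpochWindow

__all__ = ["Mode", "CommandKind", "ControlCommand", "ControllerState",
           "DecoderSet", "CommandLog", "command_payload", "step",
           "run_session", "INTENT_COMMAND"]


class Mode(enum.Enum):
    MI = "MI"
    SSVEP = "SSVEP"


class CommandKind(enum.Enum):
    LEFT_FORWARD = "LEFT_FORWARD"
    RIGHT_FORWARD = "RIGHT_FORWARD"
    RISE = "RISE"
    FALL = "FALL"
    HOVER_SWITCH = "HOVER_SWITCH"


@dataclass(frozen=True)
class ControlCommand:
    """One actuation: yaw setpoint and forward/vertical velocities."""

    kind: CommandKind
    yaw_deg: float
    forward_mps: float
    vertical_mps: float


#: Fixed payload per command: left/right-forward fly at 0.25 m/s with a
#: -42/+42 degree yaw, rise climbs at 0.2 m/s, fall descends at 0.3 m/s,
#: hover zeroes everything while the mode switches.
_PAYLOADS = {
    CommandKind.LEFT_FORWARD: (-42.0, 0.25, 0.0),
    CommandKind.RIGHT_FORWARD: (42.0, 0.25, 0.0),
    CommandKind.RISE: (0.0, 0.0, 0.2),
    CommandKind.FALL: (0.0, 0.0, -0.3),
    CommandKind.HOVER_SWITCH: (0.0, 0.0, 0.0),
}

#: Which command a scripted synthetic intent should ideally elicit.
INTENT_COMMAND = {
    "left": CommandKind.LEFT_FORWARD,
    "right": CommandKind.RIGHT_FORWARD,
    "f12.4": CommandKind.RISE,
    "f18": CommandKind.FALL,
    "blink": CommandKind.HOVER_SWITCH,
}


def command_payload(kind: CommandKind) -> ControlCommand:
    yaw, fwd, vert = _PAYLOADS[kind]
    return ControlCommand(kind=kind, yaw_deg=yaw, forward_mps=fwd,
                          vertical_mps=vert)


@dataclass(frozen=True)
class ControllerState:
    """Active flight mode plus the blink refractory countdown (strides)."""

    mode: Mode = Mode.SSVEP
    refractory: int = 0


@dataclass
class DecoderSet:
    """The three trained decoders the controller dispatches to."""

    blink_params: blink_mod.BlinkParams
    mi_model: cicsp_mod.CICSPModel
    ssvep_freqs: tuple[float, ...] = ssvep_mod.DEFAULT_FREQS
    ssvep_nh: int = ssvep_mod.DEFAULT_NH
    #: maps the winning SSVEP frequency to a command
    rise_freq: float = 12.4


@dataclass
class LogEntry:
    onset_s: float
    mode_before: Mode
    command: ControlCommand
    diagnostics: dict


@dataclass
class CommandLog:
    entries: list[LogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def commands(self) -> list[CommandKind]:
        return [e.command.kind for e in self.entries]


def step(
    window: EpochWindow, state: ControllerState, decoders: DecoderSet
) -> tuple[ControlCommand, ControllerState, dict]:
    """Decode one window: blink check first, then the active mode.

    Returns the command, the next state, and a diagnostics dict (trough
    count, CCA coefficients or the MI decision, whichever applied).
    """
    diagnostics: dict = {}
    if state.refractory == 0:
        blink_win = preprocess.bandpass(window, *preprocess.BLINK_BAND)
        n = blink_mod.count_troughs(
            blink_win.channel("Fp2"), decoders.blink_params, window.fs
        )
        diagnostics["trough_count"] = n
        if n >= decoders.blink_params.count_threshold:
            new_mode = Mode.SSVEP if state.mode is Mode.MI else Mode.MI
            return (
                command_payload(CommandKind.HOVER_SWITCH),
                ControllerState(mode=new_mode, refractory=1),
                diagnostics,
            )
    next_state = ControllerState(mode=state.mode,
                                 refractory=max(state.refractory - 1, 0))
    if state.mode is Mode.MI:
        side = cicsp_mod.predict_mi_online(window, decoders.mi_model)
        diagnostics["mi_decision"] = side
        kind = (CommandKind.LEFT_FORWARD if side == "left"
                else CommandKind.RIGHT_FORWARD)
        return command_payload(kind), next_state, diagnostics
    filtered = preprocess.bandpass(window, *preprocess.SSVEP_BAND)
    result = ssvep_mod.classify_ssvep(filtered, decoders.ssvep_freqs,
                                      decoders.ssvep_nh)
    diagnostics["cca"] = result.coefficients
    kind = (CommandKind.RISE if result.decision == decoders.rise_freq
            else CommandKind.FALL)
    return command_payload(kind), next_state, diagnostics


def run_session(
    rec: EEGRecording,
    decoders: DecoderSet,
    initial_state: ControllerState | None = None,
    intents: np.ndarray | None = None,
) -> CommandLog:
    """Decode a whole recording into a 1 Hz command stream.

    One command per 1 s stride of 1.5 s windows; deterministic given the
    recording and decoders.  *intents* optionally tags each log entry
    with the scripted ground truth.
    """
    state = initial_state or ControllerState()
    log = CommandLog()
    for window in preprocess.window_stream(rec, intents=intents):
        mode_before = state.mode
        cmd, state, diag = step(window, state, decoders)
        if window.intent is not None:
            diag["intent"] = window.intent
        log.entries.append(LogEntry(onset_s=window.onset_s,
                                    mode_before=mode_before,
                                    command=cmd, diagnostics=diag))
    return log
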