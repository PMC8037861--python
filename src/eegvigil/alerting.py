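"""Alert command conversion, stimulus dispatch, and the monitoring loop.

Detection results map to two commands: an inattention decision becomes
ALERT, an attention decision becomes STAY.  An ALERT fires one event
carrying both a visual and an auditory stimulus simultaneously to every
registered sink; hardware is represented by pluggable sinks (an in-memory
log sink and a terminal sink).  The monitor also checks the acquisition
device's connection once per cycle and requests manual adjustment while it
is poor; a missing status feed is treated as a poor connection (fail-safe).
"""

from __future__ import annotations

import enum
import logging
import sys
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import Decision, DetectionResult, TwoHMMDetector, classify_window

logger = logging.getLogger(__name__)


class Command(enum.Enum):
    ALERT = "alert"
    STAY = "stay"


class Stimulus(enum.Enum):
    VISUAL = "visual"
    AUDITORY = "auditory"


class Connection(enum.Enum):
    OK = "ok"
    POOR = "poor"


@dataclass
class AlertCommand:
    value: Command
    window: tuple[int, int]
    timestamp: float


@dataclass
class AlertEvent:
    timestamp: float
    stimuli: frozenset[Stimulus]
    duration_s: float
    sink_ids: list[str]


def convert_command(result: DetectionResult, timestamp: float = 0.0
                    ) -> AlertCommand:
    """Total deterministic mapping: INATTENTION -> ALERT, ATTENTION -> STAY."""
    value = (Command.ALERT if result.decision is Decision.INATTENTION
             else Command.STAY)
    return AlertCommand(value=value, window=result.window, timestamp=timestamp)


class LogSink:
    """Default sink: records every delivered event in memory."""

    sink_id = "log"

    def __init__(self) -> None:
        self.delivered: list[AlertEvent] = []

    def deliver(self, event: AlertEvent) -> None:
        self.delivered.append(event)


class TerminalSink:
    """Terminal approximation of the flicker + beep stimulus pair."""

    sink_id = "terminal"

    def __init__(self, stream=None) -> None:
        self.stream = stream or sys.stderr

    def deliver(self, event: AlertEvent) -> None:
        # \a = bell (auditory), inverse video flash (visual)
        self.stream.write(f"\a\x1b[7m ALERT t={event.timestamp:.1f}s \x1b[0m\n")


def emit_alert(command: AlertCommand, sinks: Sequence | None = None,
               duration_s: float = 1.0) -> Optional[AlertEvent]:
    """Dispatch an ALERT to all sinks; STAY emits nothing.

    Both stimuli are always delivered together.  A failing sink is logged
    and never interrupts monitoring.
    """
    if command.value is Command.STAY:
        return None
    sinks = list(sinks) if sinks is not None else [LogSink()]
    event = AlertEvent(timestamp=command.timestamp,
                       stimuli=frozenset({Stimulus.VISUAL, Stimulus.AUDITORY}),
                       duration_s=duration_s,
                       sink_ids=[getattr(s, "sink_id", "?") for s in sinks])
    for sink in sinks:
        try:
            sink.deliver(event)
        except Exception:
            logger.exception("stimulus sink %r failed; monitoring continues",
                             getattr(sink, "sink_id", sink))
    return event


def check_connection(feed, cycle: int) -> Connection:
    """Per-cycle device-connection check; an absent feed is POOR (fail-safe)."""
    if feed is None:
        return Connection.POOR
    if callable(feed):
        status = feed(cycle)
    else:
        status = feed[cycle] if cycle < len(feed) else None
    if status is None:
        return Connection.POOR
    if isinstance(status, Connection):
        return status
    return Connection.OK if status else Connection.POOR


@dataclass
class MonitorState:
    """Final state of a monitoring run plus its complete, time-ordered log."""

    cycles: int = 0
    connection: Connection = Connection.OK
    log: list[dict] = field(default_factory=list)
    alerts: list[AlertEvent] = field(default_factory=list)

    @property
    def decisions(self) -> list[dict]:
        return [e for e in self.log if e["kind"] == "decision"]


def run_monitor(features: np.ndarray, detector: TwoHMMDetector, *,
                window_frames: int = 60, step_frames: int = 6,
                frame_rate: float = 6.0,
                connection_feed=True,
                sinks: Sequence | None = None,
                refractory_cycles: int = 0) -> MonitorState:
    """Replay a feature stream through the detect -> convert -> emit loop.

    One cycle advances the window by ``step_frames`` (1 s at defaults):
    check the device connection, then — if it is OK — classify the current
    window, convert the decision to a command, and emit any alert.  Poor
    connections log a manual-adjustment request and skip classification.
    The run is a pure function of its inputs.
    """
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if connection_feed is True:
        connection_feed = lambda cycle: Connection.OK  # noqa: E731
    state = MonitorState()
    sinks = list(sinks) if sinks is not None else [LogSink()]
    t_frames = feats.shape[0]
    if t_frames < window_frames:
        logger.warning("stream of %d frames is shorter than one window; "
                       "empty log", t_frames)
        return state
    last_alert_cycle = -10**9
    for cycle, start in enumerate(range(0, t_frames - window_frames + 1,
                                        step_frames)):
        timestamp = (start + window_frames) / frame_rate
        status = check_connection(connection_feed, cycle)
        state.cycles += 1
        state.connection = status
        if status is Connection.POOR:
            state.log.append({"kind": "connection_request", "cycle": cycle,
                              "timestamp": timestamp,
                              "message": "manual adjustment requested"})
            continue
        window = (start, start + window_frames)
        result = classify_window(detector, feats[start:start + window_frames],
                                 window=window)
        command = convert_command(result, timestamp=timestamp)
        state.log.append({"kind": "decision", "cycle": cycle,
                          "timestamp": timestamp, "window": window,
                          "decision": result.decision.value,
                          "command": command.value.value,
                          "loglik_attention": result.loglik_attention,
                          "loglik_inattention": result.loglik_inattention})
        if command.value is Command.ALERT:
            if cycle - last_alert_cycle <= refractory_cycles and \
                    last_alert_cycle >= 0 and refractory_cycles > 0:
                continue
            event = emit_alert(command, sinks=sinks)
            if event is not None:
                state.alerts.append(event)
                last_alert_cycle = cycle
    return state
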