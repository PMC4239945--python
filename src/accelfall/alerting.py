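"""Post-detection confirmation workflow: stationary phase, alarm, alert record.

After a detector confirms a fall, a *stationary phase* (re-checking
quiescence; duration 0 by default, since the two-phase detectors have
already consumed their observation window) is followed by an audible-alarm
countdown.  The user may cancel during the alarm, returning the system to
monitoring with no alert; if the alarm expires unanswered, exactly one
:class:`AlertRecord` is emitted at ``t_detect + stationary + alarm``.

Location is a pluggable provider (a callable returning ``(lat, lon)`` or
``None``); the default reports no coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

from .detectors import DetectionEvent

logger = logging.getLogger(__name__)

MONITORING = "MONITORING"
STATIONARY = "STATIONARY"
ALARM = "ALARM"
ALERT_EMITTED = "ALERT_EMITTED"


@dataclass(frozen=True)
class AlertRecord:
    """An emitted alert: when, (optionally) where, and for which detection."""

    timestamp: float
    latitude: Optional[float]
    longitude: Optional[float]
    source_event: DetectionEvent


@dataclass
class AlertStateMachine:
    """Fall-confirmation state machine driven by detections, clock ticks, cancels.

    Legal transitions: MONITORING -> STATIONARY -> ALARM -> {ALERT_EMITTED,
    MONITORING (on cancel)}; ALERT_EMITTED behaves like MONITORING for the
    next detection.  Cancellation is only honoured in ALARM.
    """

    stationary_duration: float = 0.0  # s; 0 for the single-phase detectors
    alarm_duration: float = 15.0  # s of acoustic alarm before the alert fires
    location_provider: Optional[Callable[[], Optional[tuple]]] = None
    state: str = MONITORING
    clock: float = 0.0
    _detect_clock: float = field(default=0.0, repr=False)
    _source: Optional[DetectionEvent] = field(default=None, repr=False)

    def detection(self, event: DetectionEvent) -> None:
        if self.state in (STATIONARY, ALARM):
            logger.warning("detection at t=%.3f ignored: already in %s", self.clock, self.state)
            return
        self.state = STATIONARY
        self._detect_clock = self.clock
        self._source = event

    def tick(self, dt: float) -> Optional[AlertRecord]:
        """Advance the clock; may traverse several phase boundaries at once."""
        self.clock += dt
        if self.state == STATIONARY and self.clock >= self._detect_clock + self.stationary_duration:
            self.state = ALARM
        if self.state == ALARM:
            due = self._detect_clock + self.stationary_duration + self.alarm_duration
            if self.clock >= due:
                self.state = ALERT_EMITTED
                loc = self.location_provider() if self.location_provider else None
                lat, lon = loc if loc is not None else (None, None)
                record = AlertRecord(
                    timestamp=due,
                    latitude=lat,
                    longitude=lon,
                    source_event=self._source,
                )
                self._source = None
                return record
        return None

    def cancel(self) -> None:
        if self.state == ALARM:
            self.state = MONITORING
            self._source = None
        else:
            logger.warning("cancel at t=%.3f ignored: state is %s", self.clock, self.state)


def advance(machine: AlertStateMachine, event) -> tuple[AlertStateMachine, Optional[AlertRecord]]:
    """Single-operation surface over the machine.

    ``event`` is ``("detection", DetectionEvent)``, ``("tick", dt)`` or
    ``("cancel",)``.  The machine is advanced in place and returned with the
    alert record, if this input emitted one.
    """
    kind = event[0]
    record = None
    if kind == "detection":
        machine.detection(event[1])
    elif kind == "tick":
        record = machine.tick(event[1])
    elif kind == "cancel":
        machine.cancel()
    else:
        raise ValueError(f"unknown alert input {event!r}")
    return machine, record
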