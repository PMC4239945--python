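"""Scoring protocol: detection/ground-truth matching, FN%/FP%, threshold sweeps.

A simulated fall counts as *detected* when at least one detection triggers
inside its ground-truth interval (extended by a small tolerance, since
confirmation windows legitimately lag the physical fall); FN% per fall
direction is ``100 * missed / simulated``.  Detections matching no fall are
false positives attributed to the enclosing (or nearest) ADL interval, at
most one per interval; FP% is ``100 * alarmed ADL intervals / ADL intervals``.
User-cancelled alarms still count as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .detectors import DetectionEvent, run_detector
from .signal_core import InvalidInputError, InvalidParameterError
from .simulator import LabeledRecording

DEFAULT_TOLERANCE = 2.0  # s past a fall interval within which a trigger still matches


def suggested_tolerance(algorithm: str, params) -> float:
    """Matching tolerance appropriate to a detector's decision latency.

    The two-phase range detector serialises candidates: an impact's own tail
    spoils the first checking window, so the successful (re-)trigger lands up
    to one checking window after the fall.  Its tolerance is therefore the
    default plus ``win_ct``; single-phase detectors trigger on the impact
    itself and keep the default.
    """
    if algorithm == "perfalld":
        return DEFAULT_TOLERANCE + params.win_ct
    return DEFAULT_TOLERANCE


class UndefinedCategoryError(ValueError):
    """A rate was requested for a category with zero events (zero denominator)."""


@dataclass
class ConfusionCounts:
    """Per-category event/detection bookkeeping.

    ``falls`` maps a fall kind to ``(n_events, n_detected)``; ``n_adl_events``
    counts ADL intervals and ``n_false_alarms`` those with at least one
    spurious detection attributed to them.
    """

    falls: dict
    n_adl_events: int
    n_false_alarms: int

    @property
    def n_fall_events(self) -> int:
        return sum(n for n, _ in self.falls.values())

    @property
    def n_fall_detected(self) -> int:
        return sum(d for _, d in self.falls.values())


@dataclass(frozen=True)
class SweepPoint:
    """One point of an FN-vs-FP tradeoff curve."""

    param_value: float
    fn_pct: float
    fp_pct: float


def match_events(
    detections: list[DetectionEvent],
    truth: list,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ConfusionCounts:
    """Match detections to ground-truth ``(t_start, t_end, kind)`` intervals.

    A fall interval is detected iff some detection's ``t_trigger`` lies in
    ``[t_start, t_end + tolerance]``; multiple detections on one interval
    count once.  Detections matching no fall interval mark the enclosing, or
    else the nearest, ADL interval as a false alarm.  The result is invariant
    to the ordering of both inputs.
    """
    if tolerance < 0:
        raise InvalidParameterError("tolerance must be >= 0")
    ordered = sorted(truth, key=lambda e: e[0])
    for (s0, e0, _), (s1, _, _) in zip(ordered, ordered[1:]):
        if s1 < e0:
            raise InvalidInputError(
                f"overlapping truth intervals: [{s0}, {e0}] and starting {s1}"
            )
    fall_iv = [e for e in ordered if e[2].startswith("fall")]
    adl_iv = [e for e in ordered if not e[2].startswith("fall")]

    falls: dict = {}
    detected: dict = {}
    for s, e, kind in fall_iv:
        n, d = falls.get(kind, (0, 0))
        falls[kind] = (n + 1, d)
    alarmed = set()
    for det in detections:
        t = det.t_trigger
        hit = None
        for idx, (s, e, kind) in enumerate(fall_iv):
            if s <= t <= e + tolerance:
                hit = (idx, kind)
                break
        if hit is not None:
            detected.setdefault(hit[0], hit[1])
            continue
        if not adl_iv:
            continue  # nothing to attribute a spurious detection to
        enclosing = [i for i, (s, e, _) in enumerate(adl_iv) if s <= t <= e]
        if enclosing:
            alarmed.add(enclosing[0])
        else:
            dist = [
                (min(abs(t - s), abs(t - e)), i) for i, (s, e, _) in enumerate(adl_iv)
            ]
            alarmed.add(min(dist)[1])
    for kind in detected.values():
        n, d = falls[kind]
        falls[kind] = (n, d + 1)
    return ConfusionCounts(
        falls=falls, n_adl_events=len(adl_iv), n_false_alarms=len(alarmed)
    )


def fn_fp_rates(counts: ConfusionCounts) -> dict:
    """FN% per fall category plus overall, and FP% over ADL events.

    Returns ``{"fn_pct": {kind: pct, ...}, "fn_pct_overall": pct,
    "fp_pct": pct}``.  Raises :class:`UndefinedCategoryError` when a
    denominator is zero.
    """
    if counts.n_fall_events == 0:
        raise UndefinedCategoryError("no simulated falls: FN% undefined")
    if counts.n_adl_events == 0:
        raise UndefinedCategoryError("no ADL events: FP% undefined")
    per_kind = {}
    for kind, (n, d) in sorted(counts.falls.items()):
        if n == 0:
            raise UndefinedCategoryError(f"no events in category {kind}")
        per_kind[kind] = 100.0 * (n - d) / n
    overall = 100.0 * (counts.n_fall_events - counts.n_fall_detected) / counts.n_fall_events
    fp = 100.0 * counts.n_false_alarms / counts.n_adl_events
    return {"fn_pct": per_kind, "fn_pct_overall": overall, "fp_pct": fp}


def evaluate_detector(
    algorithm: str,
    params,
    recording: LabeledRecording,
    tolerance: float = DEFAULT_TOLERANCE,
) -> dict:
    """Detect on a labelled recording and score it in one step."""
    dets = run_detector(algorithm, recording.accel, recording.orient, params)
    return fn_fp_rates(match_events(dets, recording.events, tolerance))


def threshold_sweep(
    algorithm: str,
    params,
    param_name: str,
    values: list,
    recording: LabeledRecording,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[SweepPoint]:
    """Re-run detection and scoring on one fixed dataset for each parameter value."""
    if not values:
        raise InvalidParameterError("values must be non-empty")
    if not hasattr(params, param_name):
        raise InvalidParameterError(
            f"{type(params).__name__} has no parameter {param_name!r}"
        )
    points = []
    for v in values:
        p = replace(params, **{param_name: v})
        rates = evaluate_detector(algorithm, p, recording, tolerance)
        points.append(
            SweepPoint(param_value=float(v), fn_pct=rates["fn_pct_overall"], fp_pct=rates["fp_pct"])
        )
    return points
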