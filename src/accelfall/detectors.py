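"""The four threshold-based fall detectors.

Each algorithm exists in two forms with identical outputs:

* a **batch** operation over a full series (vectorised precomputation plus a
  sequential scan), and
* a **streaming** push-one-sample state machine, the form a phone would run.

The two code paths are deliberately independent (the batch side leans on
pandas rolling windows, the streaming side on hand-rolled monotonic deques)
so that their equivalence is a meaningful cross-check, not a tautology.

Algorithms
----------
basic
    A fall is assumed whenever the total acceleration ``|A_T|`` exceeds a
    single decision threshold (3.5 g in the shipped profile).
fall_index
    Thresholds the Fall Index, the trailing 20-sample root-sum-square of the
    consecutive differences of the three axis signals.
perfalld
    Two channels, total ``|A_T|`` and vertical ``|A_v|`` acceleration.  For a
    channel, when the (max - min) range within a trailing triggering window
    exceeds its triggering threshold, a checking phase starts: the range over
    the subsequent checking window must *not* exceed the checking threshold
    (the body has come to rest).  A fall is declared only when both channels'
    conditions hold.
ifall
    A candidate arises when ``|A_T|`` drops below a lower threshold (free
    fall) and then exceeds an upper threshold (impact) within a crossing
    window.  The candidate is confirmed only if the posture tilts past a
    horizontal angle and stays there until a post-fall observation window
    expires; an upright recovery discards it.

All detectors merge repeat threshold crossings within a refractory period
into a single event, so one physical impact yields one event.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .signal_core import (
    AccelSeries,
    InvalidInputError,
    InvalidParameterError,
    OrientationSeries,
    fall_index,
    magnitude,
    sliding_range,
    tilt_from_reference,
    vertical_acceleration,
    window_samples,
)

ALGORITHMS = ("basic", "fall_index", "perfalld", "ifall")


@dataclass(frozen=True)
class DetectionEvent:
    """A detector's confirmed fall.

    ``t_trigger`` is the time of the threshold crossing that started the
    decision, ``t_confirm`` the time the decision became final (equal to
    ``t_trigger`` for the single-phase detectors), ``score`` the deciding
    scalar (peak ``|A_T|``, peak Fall Index, or triggering window range).
    """

    t_trigger: float
    t_confirm: float
    algorithm: str
    score: float


@dataclass
class BasicParams:
    threshold: float = 3.5  # g
    refractory: float = 2.0  # s

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise InvalidParameterError("threshold must be > 0")


@dataclass
class FallIndexParams:
    """Fall Index detector settings.

    ``mode`` resolves an ambiguity in how the shared 3.5 g limit is applied:
    ``"fi"`` (default) thresholds the Fall Index itself at ``threshold``;
    ``"magnitude_gated"`` thresholds ``|A_T|`` at ``threshold`` but only where
    the Fall Index exceeds ``fi_gate``.
    """

    window: int = 20  # samples
    threshold: float = 3.5
    refractory: float = 2.0
    mode: str = "fi"
    fi_gate: float = 1.0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise InvalidParameterError("window must be >= 2 samples")
        if not self.threshold > 0:
            raise InvalidParameterError("threshold must be > 0")
        if self.mode not in ("fi", "magnitude_gated"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")


@dataclass
class PerFallDParams:
    th_tt: float = 150.0  # total-acceleration triggering threshold
    th_ct: float = 50.0  # total-acceleration checking threshold
    th_tv: float = 6.0  # vertical-acceleration triggering threshold
    th_cv: float = 2.0  # vertical-acceleration checking threshold
    win_tt: float = 4.0  # s
    win_ct: float = 4.0
    win_tv: float = 4.0
    win_cv: float = 4.0
    refractory: float = 2.0

    def __post_init__(self) -> None:
        for name in ("th_tt", "th_ct", "th_tv", "th_cv"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("win_tt", "win_ct", "win_tv", "win_cv"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass
class IFallParams:
    lower: float = 1.0  # g
    upper: float = 3.5  # g
    crossing_window: float = 1.0  # s, lower-then-upper crossings must fit inside
    postfall_window: float = 5.0  # s, wait for upright recovery
    horizontal_angle: float = 60.0  # degrees of tilt beyond which posture is lying
    refractory: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise InvalidParameterError("need 0 < lower < upper")
        if not self.crossing_window > 0 or not self.postfall_window > 0:
            raise InvalidParameterError("windows must be > 0")


# ---------------------------------------------------------------------------
# batch detectors
# ---------------------------------------------------------------------------

def _threshold_scan(
    values: np.ndarray,
    times: np.ndarray,
    threshold: float,
    refractory: float,
    algorithm: str,
) -> list[DetectionEvent]:
    """Events from refractory-merged excursions of ``values`` above ``threshold``.

    A crossing within ``refractory`` seconds of the current event's trigger
    merges into it; the score is the peak value over the merged excursions.
    """
    above = values > threshold
    if not above.any():
        return []
    prev = np.concatenate(([False], above[:-1]))
    crossings = np.flatnonzero(above & ~prev)
    falls = np.flatnonzero(~above)  # excursion i ends before the next False
    events: list[DetectionEvent] = []
    cur_trig = cur_end = None
    n = len(values)

    def run_end(i: int) -> int:
        j = np.searchsorted(falls, i)
        return (falls[j] - 1) if j < len(falls) else (n - 1)

    for i in crossings:
        if cur_trig is not None and times[i] - times[cur_trig] <= refractory:
            cur_end = run_end(i)
            continue
        if cur_trig is not None:
            events.append(
                DetectionEvent(
                    t_trigger=float(times[cur_trig]),
                    t_confirm=float(times[cur_trig]),
                    algorithm=algorithm,
                    score=float(values[cur_trig : cur_end + 1].max()),
                )
            )
        cur_trig, cur_end = i, run_end(i)
    events.append(
        DetectionEvent(
            t_trigger=float(times[cur_trig]),
            t_confirm=float(times[cur_trig]),
            algorithm=algorithm,
            score=float(values[cur_trig : cur_end + 1].max()),
        )
    )
    return events


def detect_basic(accel: AccelSeries, params: BasicParams) -> list[DetectionEvent]:
    """Single-threshold detector on the total acceleration."""
    acc = accel.to_g()
    mag = magnitude(acc)
    return _threshold_scan(mag.values, mag.times, params.threshold, params.refractory, "basic")


def detect_fall_index(accel: AccelSeries, params: FallIndexParams) -> list[DetectionEvent]:
    """Fall Index detector (see :class:`FallIndexParams` for the two modes)."""
    acc = accel.to_g()
    fi = fall_index(acc, params.window)
    if params.mode == "fi":
        return _threshold_scan(
            fi.values, fi.times, params.threshold, params.refractory, "fall_index"
        )
    mag = magnitude(acc)
    gated = np.where(fi.values > params.fi_gate, mag.values, 0.0)
    return _threshold_scan(
        gated, mag.times, params.threshold, params.refractory, "fall_index"
    )


def detect_perfalld(
    accel: AccelSeries, orient: OrientationSeries, params: PerFallDParams
) -> list[DetectionEvent]:
    """Two-phase, two-channel range detector.

    State machine: while idle, either channel whose trailing-window range
    exceeds its triggering threshold opens a candidate; the other channel must
    trigger before the first channel's checking window expires.  A channel's
    check passes iff the range over the checking window after its trigger does
    not exceed its checking threshold; the event is emitted when the later
    check window closes and both checks passed.  A pending candidate blocks
    new triggers (serialisation), and data ending mid-check yields no event.
    """
    if accel.n != orient.n:
        raise InvalidInputError("acceleration and orientation must be aligned")
    acc = accel.to_g()
    mag = magnitude(acc)
    av = vertical_acceleration(acc, orient)
    fs = acc.fs
    n_ct = window_samples(params.win_ct, fs)
    n_cv = window_samples(params.win_cv, fs)
    rt = sliding_range(mag, params.win_tt).values
    rv = sliding_range(av, params.win_tv).values
    times = mag.times
    magv, avv = mag.values, av.values

    events: list[DetectionEvent] = []
    pend_t = pend_v = None  # trigger sample indices per channel
    pending = False
    last_trig_time = -math.inf
    for i in range(acc.n):
        if not pending:
            if times[i] - last_trig_time <= params.refractory:
                continue
            trig_t = rt[i] > params.th_tt
            trig_v = rv[i] > params.th_tv
            if trig_t or trig_v:
                pend_t = i if trig_t else None
                pend_v = i if trig_v else None
                pending = True
            continue
        # pending: late trigger on the missing channel first
        if pend_t is None and rt[i] > params.th_tt:
            pend_t = i
        if pend_v is None and rv[i] > params.th_tv:
            pend_v = i
        if pend_t is None or pend_v is None:
            deadline = (pend_t + n_ct) if pend_t is not None else (pend_v + n_cv)
            if i >= deadline:
                pending, pend_t, pend_v = False, None, None
            continue
        complete = max(pend_t + n_ct, pend_v + n_cv)
        if i == complete:
            chk_t = magv[pend_t + 1 : pend_t + n_ct + 1]
            chk_v = avv[pend_v + 1 : pend_v + n_cv + 1]
            ok_t = (chk_t.max() - chk_t.min()) <= params.th_ct
            ok_v = (chk_v.max() - chk_v.min()) <= params.th_cv
            if ok_t and ok_v:
                trig_i = max(pend_t, pend_v)
                events.append(
                    DetectionEvent(
                        t_trigger=float(times[trig_i]),
                        t_confirm=float(times[i]),
                        algorithm="perfalld",
                        score=float(rt[pend_t]),
                    )
                )
                last_trig_time = times[trig_i]
            pending, pend_t, pend_v = False, None, None
    return events


def detect_ifall(
    accel: AccelSeries, orient: OrientationSeries, params: IFallParams
) -> list[DetectionEvent]:
    """Free-fall-dip / impact-spike detector with a post-fall posture check.

    A candidate opens when ``|A_T|`` exceeds ``upper`` within
    ``crossing_window`` seconds of a sample below ``lower``.  Over the
    post-fall window the posture (tilt of the vertical-projection axis from
    the recording's initial pose) must pass ``horizontal_angle`` and stay
    beyond it until the window expires; dropping back upright after lying
    began, or never lying at all, discards the candidate.
    """
    if accel.n != orient.n:
        raise InvalidInputError("acceleration and orientation must be aligned")
    acc = accel.to_g()
    mag = magnitude(acc)
    tilt = tilt_from_reference(orient)
    angle = math.radians(params.horizontal_angle)
    n_post = window_samples(params.postfall_window, acc.fs)
    times = mag.times
    magv = mag.values

    events: list[DetectionEvent] = []
    low_time = None  # time of last sample below `lower`
    run_max = -math.inf  # max |A_T| since that sample
    pending = False
    u_idx = 0
    cand_score = 0.0
    lying = False
    last_trig_time = -math.inf
    for i in range(acc.n):
        t = times[i]
        if magv[i] < params.lower:
            low_time = t
            run_max = magv[i]
        else:
            run_max = max(run_max, magv[i])
        if not pending:
            if (
                magv[i] > params.upper
                and low_time is not None
                and low_time < t
                and (t - low_time) <= params.crossing_window
                and (t - last_trig_time) > params.refractory
            ):
                pending, u_idx, cand_score, lying = True, i, run_max, False
            continue
        if tilt[i] > angle:
            lying = True
        elif lying:  # upright posture recurred: suppress
            pending = False
            continue
        if i == u_idx + n_post:
            if lying:
                events.append(
                    DetectionEvent(
                        t_trigger=float(times[u_idx]),
                        t_confirm=float(t),
                        algorithm="ifall",
                        score=float(cand_score),
                    )
                )
                last_trig_time = times[u_idx]
            pending = False
    return events


def run_detector(
    algorithm: str,
    accel: AccelSeries,
    orient: OrientationSeries | None,
    params,
) -> list[DetectionEvent]:
    """Dispatch to a batch detector by name; orientation-free detectors ignore it."""
    if algorithm == "basic":
        return detect_basic(accel, params)
    if algorithm == "fall_index":
        return detect_fall_index(accel, params)
    if algorithm == "perfalld":
        if orient is None:
            raise InvalidInputError("perfalld requires an orientation series")
        return detect_perfalld(accel, orient, params)
    if algorithm == "ifall":
        if orient is None:
            raise InvalidInputError("ifall requires an orientation series")
        return detect_ifall(accel, orient, params)
    raise InvalidParameterError(
        f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
    )


# ---------------------------------------------------------------------------
# streaming detectors
# ---------------------------------------------------------------------------

class _MonotonicRange:
    """Trailing-window (max - min) over the last ``m`` pushed values, O(1) amortised."""

    __slots__ = ("m", "_i", "_maxq", "_minq")

    def __init__(self, m: int) -> None:
        self.m = m
        self._i = -1
        self._maxq: deque = deque()  # (index, value), decreasing values
        self._minq: deque = deque()  # (index, value), increasing values

    def push(self, value: float) -> float:
        self._i += 1
        lo = self._i - self.m + 1
        q = self._maxq
        while q and q[-1][1] <= value:
            q.pop()
        q.append((self._i, value))
        while q[0][0] < lo:
            q.popleft()
        q = self._minq
        while q and q[-1][1] >= value:
            q.pop()
        q.append((self._i, value))
        while q[0][0] < lo:
            q.popleft()
        return self._maxq[0][1] - self._minq[0][1]


class _StreamBase:
    """Shared sample bookkeeping: time-order validation and index counting."""

    algorithm = "?"

    def __init__(self, fs: float) -> None:
        if not fs > 0:
            raise InvalidParameterError("fs must be > 0")
        self.fs = fs
        self._last_t = -math.inf
        self._i = -1

    def _admit(self, t: float) -> int:
        if t <= self._last_t:
            raise InvalidInputError(
                f"out-of-order timestamp {t} after {self._last_t}"
            )
        self._last_t = t
        self._i += 1
        return self._i

    def push(self, t, ax, ay, az, pitch=None, roll=None):
        raise NotImplementedError

    def finish(self) -> list[DetectionEvent]:
        """Flush any event that is complete but unemitted at end of data."""
        return []


class _ThresholdStream(_StreamBase):
    """Streaming refractory-merged excursion detector over a scalar signal."""

    def __init__(self, fs: float, threshold: float, refractory: float) -> None:
        super().__init__(fs)
        self.threshold = threshold
        self.refractory = refractory
        self._prev_above = False
        self._trig_t = None
        self._score = -math.inf

    def _value(self, ax: float, ay: float, az: float) -> float:
        raise NotImplementedError

    def push(self, t, ax, ay, az, pitch=None, roll=None):
        self._admit(t)
        v = self._value(ax, ay, az)
        above = v > self.threshold
        out = None
        if (
            self._trig_t is not None
            and not above
            and t - self._trig_t > self.refractory
        ):
            out = self._emit()
        if above and not self._prev_above:
            if self._trig_t is not None and t - self._trig_t > self.refractory:
                out = self._emit()
            if self._trig_t is None:
                self._trig_t, self._score = t, v
        if above and self._trig_t is not None:
            self._score = max(self._score, v)
        self._prev_above = above
        return out

    def _emit(self) -> DetectionEvent:
        ev = DetectionEvent(
            t_trigger=self._trig_t,
            t_confirm=self._trig_t,
            algorithm=self.algorithm,
            score=self._score,
        )
        self._trig_t, self._score = None, -math.inf
        return ev

    def finish(self) -> list[DetectionEvent]:
        return [self._emit()] if self._trig_t is not None else []


class BasicStream(_ThresholdStream):
    algorithm = "basic"

    def __init__(self, params: BasicParams, fs: float) -> None:
        super().__init__(fs, params.threshold, params.refractory)

    def _value(self, ax, ay, az):
        return math.sqrt(ax * ax + ay * ay + az * az)


class FallIndexStream(_ThresholdStream):
    algorithm = "fall_index"

    def __init__(self, params: FallIndexParams, fs: float) -> None:
        super().__init__(fs, params.threshold, params.refractory)
        self.params = params
        self._window: deque = deque()  # last `window` squared-step values
        self._sum = 0.0
        self._prev = None

    def _value(self, ax, ay, az):
        if self._prev is None:
            d2 = 0.0
        else:
            px, py, pz = self._prev
            d2 = (ax - px) ** 2 + (ay - py) ** 2 + (az - pz) ** 2
        self._prev = (ax, ay, az)
        self._window.append(d2)
        self._sum += d2
        if len(self._window) > self.params.window:
            self._sum -= self._window.popleft()
        fi = math.sqrt(max(self._sum, 0.0))
        if self.params.mode == "fi":
            return fi
        mag = math.sqrt(ax * ax + ay * ay + az * az)
        return mag if fi > self.params.fi_gate else 0.0


class PerFallDStream(_StreamBase):
    algorithm = "perfalld"

    def __init__(self, params: PerFallDParams, fs: float) -> None:
        super().__init__(fs)
        self.p = params
        self._rng_t = _MonotonicRange(window_samples(params.win_tt, fs))
        self._rng_v = _MonotonicRange(window_samples(params.win_tv, fs))
        self._n_ct = window_samples(params.win_ct, fs)
        self._n_cv = window_samples(params.win_cv, fs)
        self._pending = False
        self._pend_t = self._pend_v = None
        self._pend_t_time = self._pend_v_time = 0.0
        self._trig_range_t = 0.0
        self._chk_t = [math.inf, -math.inf]  # min, max of check window (total)
        self._chk_v = [math.inf, -math.inf]
        self._last_trig_time = -math.inf

    def push(self, t, ax, ay, az, pitch=None, roll=None):
        i = self._admit(t)
        mag = math.sqrt(ax * ax + ay * ay + az * az)
        av = abs(
            ax * math.sin(roll)
            + ay * math.sin(pitch)
            - az * math.cos(pitch) * math.cos(roll)
        )
        rt = self._rng_t.push(mag)
        rv = self._rng_v.push(av)
        p = self.p
        if not self._pending:
            if t - self._last_trig_time <= p.refractory:
                return None
            trig_t, trig_v = rt > p.th_tt, rv > p.th_tv
            if trig_t or trig_v:
                self._pending = True
                self._pend_t = i if trig_t else None
                self._pend_v = i if trig_v else None
                self._pend_t_time = self._pend_v_time = t
                if trig_t:
                    self._trig_range_t = rt
                self._chk_t = [math.inf, -math.inf]
                self._chk_v = [math.inf, -math.inf]
            return None
        if self._pend_t is None and rt > p.th_tt:
            self._pend_t = i
            self._pend_t_time = t
            self._trig_range_t = rt
        if self._pend_v is None and rv > p.th_tv:
            self._pend_v = i
            self._pend_v_time = t
        # accumulate check-window extrema per channel
        if self._pend_t is not None and self._pend_t < i <= self._pend_t + self._n_ct:
            if mag < self._chk_t[0]:
                self._chk_t[0] = mag
            if mag > self._chk_t[1]:
                self._chk_t[1] = mag
        if self._pend_v is not None and self._pend_v < i <= self._pend_v + self._n_cv:
            if av < self._chk_v[0]:
                self._chk_v[0] = av
            if av > self._chk_v[1]:
                self._chk_v[1] = av
        if self._pend_t is None or self._pend_v is None:
            deadline = (
                self._pend_t + self._n_ct
                if self._pend_t is not None
                else self._pend_v + self._n_cv
            )
            if i >= deadline:
                self._pending, self._pend_t, self._pend_v = False, None, None
            return None
        complete = max(self._pend_t + self._n_ct, self._pend_v + self._n_cv)
        if i == complete:
            ok_t = (self._chk_t[1] - self._chk_t[0]) <= p.th_ct
            ok_v = (self._chk_v[1] - self._chk_v[0]) <= p.th_cv
            t_trig = max(self._pend_t_time, self._pend_v_time)
            self._pending, self._pend_t, self._pend_v = False, None, None
            if ok_t and ok_v:
                self._last_trig_time = t_trig
                return DetectionEvent(
                    t_trigger=t_trig,
                    t_confirm=t,
                    algorithm="perfalld",
                    score=self._trig_range_t,
                )
        return None


class IFallStream(_StreamBase):
    algorithm = "ifall"

    def __init__(self, params: IFallParams, fs: float) -> None:
        super().__init__(fs)
        self.p = params
        self._angle = math.radians(params.horizontal_angle)
        self._n_post = window_samples(params.postfall_window, fs)
        self._ref = None  # reference vertical-projection axis (unit 3-vector)
        self._low_time = None
        self._run_max = -math.inf
        self._pending = False
        self._u_idx = 0
        self._u_time = 0.0
        self._cand_score = 0.0
        self._lying = False
        self._last_trig_time = -math.inf

    def _tilt(self, pitch: float, roll: float) -> float:
        sy, cy = math.sin(pitch), math.cos(pitch)
        sz, cz = math.sin(roll), math.cos(roll)
        v = (sz, sy, -cy * cz)
        norm = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
        v = (v[0] / norm, v[1] / norm, v[2] / norm)
        if self._ref is None:
            self._ref = v
        r = self._ref
        dot = v[0] * r[0] + v[1] * r[1] + v[2] * r[2]
        return math.acos(min(1.0, max(-1.0, dot)))

    def push(self, t, ax, ay, az, pitch=None, roll=None):
        i = self._admit(t)
        mag = math.sqrt(ax * ax + ay * ay + az * az)
        tilt = self._tilt(pitch, roll)
        p = self.p
        if mag < p.lower:
            self._low_time = t
            self._run_max = mag
        else:
            self._run_max = max(self._run_max, mag)
        if not self._pending:
            if (
                mag > p.upper
                and self._low_time is not None
                and self._low_time < t
                and (t - self._low_time) <= p.crossing_window
                and (t - self._last_trig_time) > p.refractory
            ):
                self._pending = True
                self._u_idx, self._u_time = i, t
                self._cand_score = self._run_max
                self._lying = False
            return None
        if tilt > self._angle:
            self._lying = True
        elif self._lying:
            self._pending = False
            return None
        if i == self._u_idx + self._n_post:
            pending_was_lying = self._lying
            self._pending = False
            if pending_was_lying:
                self._last_trig_time = self._u_time
                return DetectionEvent(
                    t_trigger=self._u_time,
                    t_confirm=t,
                    algorithm="ifall",
                    score=self._cand_score,
                )
        return None


_STREAMS = {
    "basic": BasicStream,
    "fall_index": FallIndexStream,
    "perfalld": PerFallDStream,
    "ifall": IFallStream,
}


def make_stream(algorithm: str, params, fs: float) -> _StreamBase:
    """Streaming detector factory mirroring :func:`run_detector`."""
    try:
        cls = _STREAMS[algorithm]
    except KeyError:
        raise InvalidParameterError(
            f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
        ) from None
    return cls(params, fs)


def stream_push(state: _StreamBase, sample, orientation_sample=None):
    """Push one sample into a streaming detector.

    ``sample`` is ``(t, ax, ay, az)`` in g; ``orientation_sample`` is
    ``(pitch, roll)`` in radians for the detectors that need it.  Returns the
    completed :class:`DetectionEvent`, if this sample finalised one.
    """
    t, ax, ay, az = sample
    if orientation_sample is None:
        return state.push(t, ax, ay, az)
    pitch, roll = orientation_sample
    return state.push(t, ax, ay, az, pitch, roll)


def stream_detect(
    algorithm: str,
    accel: AccelSeries,
    orient: OrientationSeries | None,
    params,
) -> list[DetectionEvent]:
    """Run a full series through the streaming interface (convenience/testing)."""
    acc = accel.to_g()
    state = make_stream(algorithm, params, acc.fs)
    times = acc.times
    events: list[DetectionEvent] = []
    needs_orient = algorithm in ("perfalld", "ifall")
    if needs_orient and orient is None:
        raise InvalidInputError(f"{algorithm} requires an orientation series")
    ax, ay, az = acc.ax, acc.ay, acc.az
    if needs_orient:
        pitch, roll = orient.pitch, orient.roll
        for k in range(acc.n):
            ev = state.push(times[k], ax[k], ay[k], az[k], pitch[k], roll[k])
            if ev is not None:
                events.append(ev)
    else:
        for k in range(acc.n):
            ev = state.push(times[k], ax[k], ay[k], az[k])
            if ev is not None:
                events.append(ev)
    events.extend(state.finish())
    return events
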