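"""Raw accelerometry containers and the acceleration-derived scalar signals.

Everything downstream (the four detectors, the simulator, the evaluation
protocol) consumes the three quantities defined here:

* total acceleration ``|A_T| = sqrt(ax^2 + ay^2 + az^2)``,
* the Fall Index, the root of the summed squared consecutive-sample
  differences of the three axes over a trailing 20-sample window,
* vertical acceleration ``|A_v| = |ax sin(roll) + ay sin(pitch)
  - az cos(pitch) cos(roll)|``, the projection of the reading onto the
  absolute vertical as determined by the device's pitch/roll.

The canonical internal unit is g (1 g = 9.80665 m/s^2); all windows are
trailing (causal) windows ending at the current sample, matching real-time
operation on a phone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STANDARD_GRAVITY = 9.80665  # m/s^2 per g

#: Accepted unit tags for acceleration series.
UNIT_G = "g"
UNIT_MS2 = "m/s2"


class InvalidInputError(ValueError):
    """A series or sample violates an input contract (empty, mismatched, ...)."""


class InvalidParameterError(ValueError):
    """A parameter violates its contract (window too short, bad threshold, ...)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class AccelSeries:
    """Uniformly sampled tri-axial acceleration.

    Timestamps are implicit: sample ``i`` is at ``t0 + i / fs``.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz (> 0).
    ax, ay, az : array-like
        Per-sample acceleration along the device x, y, z axes.
    unit : {"g", "m/s2"}
        Unit of the stored components.
    t0 : float
        Start time in seconds.
    """

    fs: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    unit: str = UNIT_G
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ax = _as_float_array(self.ax, "ax")
        self.ay = _as_float_array(self.ay, "ay")
        self.az = _as_float_array(self.az, "az")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise InvalidInputError(
                "component arrays must have equal length: "
                f"{len(self.ax)}, {len(self.ay)}, {len(self.az)}"
            )
        if len(self.ax) < 1:
            raise InvalidInputError("series must contain at least one sample")
        if not self.fs > 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.unit not in (UNIT_G, UNIT_MS2):
            raise InvalidParameterError(f"unit must be 'g' or 'm/s2', got {self.unit!r}")

    @property
    def n(self) -> int:
        return len(self.ax)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs

    def to_g(self) -> "AccelSeries":
        """Return the series expressed in g (no copy if already in g)."""
        if self.unit == UNIT_G:
            return self
        return replace(
            self,
            ax=self.ax / STANDARD_GRAVITY,
            ay=self.ay / STANDARD_GRAVITY,
            az=self.az / STANDARD_GRAVITY,
            unit=UNIT_G,
        )

    def components(self) -> np.ndarray:
        """(n, 3) matrix of the axis components."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class OrientationSeries:
    """Per-sample device pitch/roll in radians, sharing its companion's timeline.

    ``pitch`` is the rotation angle about the device y axis, ``roll`` about the
    device z axis, the two angles entering the vertical-acceleration formula.
    """

    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.pitch = _as_float_array(self.pitch, "pitch")
        self.roll = _as_float_array(self.roll, "roll")
        if len(self.pitch) != len(self.roll):
            raise InvalidInputError(
                f"pitch/roll length mismatch: {len(self.pitch)} vs {len(self.roll)}"
            )
        if not (np.isfinite(self.pitch).all() and np.isfinite(self.roll).all()):
            raise InvalidInputError("pitch/roll angles must be finite")

    @property
    def n(self) -> int:
        return len(self.pitch)


@dataclass
class ScalarSeries:
    """One scalar per sample on the same implicit timeline as its source."""

    fs: float
    values: np.ndarray
    t0: float = 0.0
    unit: str = UNIT_G

    def __post_init__(self) -> None:
        self.values = _as_float_array(self.values, "values")
        if not self.fs > 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


def window_samples(duration: float, fs: float) -> int:
    """Number of samples in a trailing window of ``duration`` seconds at ``fs`` Hz.

    Raises :class:`InvalidParameterError` if the window is shorter than one
    sample period.
    """
    if not duration > 0:
        raise InvalidParameterError(f"window duration must be positive, got {duration}")
    m = int(round(duration * fs))
    if m < 1:
        raise InvalidParameterError(
            f"window of {duration} s is shorter than one sample period at {fs} Hz"
        )
    return m


# ---------------------------------------------------------------------------
# derived scalar signals
# ---------------------------------------------------------------------------

def magnitude(accel: AccelSeries) -> ScalarSeries:
    """Total acceleration ``|A_T|``: the per-sample Euclidean norm of (ax, ay, az)."""
    vals = np.sqrt(accel.ax**2 + accel.ay**2 + accel.az**2)
    return ScalarSeries(fs=accel.fs, values=vals, t0=accel.t0, unit=accel.unit)


def vertical_acceleration(accel: AccelSeries, orient: OrientationSeries) -> ScalarSeries:
    """Vertical acceleration ``|A_v|`` from pitch/roll.

    ``|A_v| = |ax sin(roll) + ay sin(pitch) - az cos(pitch) cos(roll)|``
    """
    if accel.n != orient.n:
        raise InvalidInputError(
            f"acceleration ({accel.n}) and orientation ({orient.n}) lengths differ"
        )
    sy, sz = np.sin(orient.pitch), np.sin(orient.roll)
    cy, cz = np.cos(orient.pitch), np.cos(orient.roll)
    vals = np.abs(accel.ax * sz + accel.ay * sy - accel.az * cy * cz)
    return ScalarSeries(fs=accel.fs, values=vals, t0=accel.t0, unit=accel.unit)


def vertical_acceleration_sample(
    ax: float, ay: float, az: float, pitch: float, roll: float
) -> float:
    """Scalar single-sample form of :func:`vertical_acceleration` (streaming use)."""
    import math

    return abs(
        ax * math.sin(roll)
        + ay * math.sin(pitch)
        - az * math.cos(pitch) * math.cos(roll)
    )


def fall_index(accel: AccelSeries, window: int = 20) -> ScalarSeries:
    """Fall Index: trailing root-sum-square of consecutive-sample differences.

    ``FI_i = sqrt( sum_{k in {x,y,z}} sum_{j=i-window+1}^{i}
    ((A_k)_j - (A_k)_{j-1})^2 )``.

    During the first ``window - 1`` samples the sum runs over the differences
    available so far (partial window), so the output is aligned with the input
    and has the same length; ``FI_0 = 0``.
    """
    if window < 2:
        raise InvalidParameterError(f"window must be >= 2 samples, got {window}")
    comp = accel.components()
    # d2[j] = squared step into sample j, summed over axes; d2[0] = 0 so a plain
    # trailing rolling sum over j in [i-window+1, i] realises the partial warm-up.
    d2 = np.zeros(accel.n)
    if accel.n > 1:
        d2[1:] = (np.diff(comp, axis=0) ** 2).sum(axis=1)
    sums = pd.Series(d2).rolling(window, min_periods=1).sum().to_numpy()
    return ScalarSeries(fs=accel.fs, values=np.sqrt(sums), t0=accel.t0, unit=accel.unit)


def sliding_range(series: ScalarSeries, window: float) -> ScalarSeries:
    """Per-sample (max - min) of the values within the trailing window (seconds)."""
    m = window_samples(window, series.fs)
    s = pd.Series(series.values)
    rng = (s.rolling(m, min_periods=1).max() - s.rolling(m, min_periods=1).min())
    return ScalarSeries(fs=series.fs, values=rng.to_numpy(), t0=series.t0, unit=series.unit)


# ---------------------------------------------------------------------------
# orientation from gravity
# ---------------------------------------------------------------------------

def angles_from_gravity_direction(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pitch/roll whose vertical-projection formula exactly recovers ``u``.

    Given unit gravity-direction readings ``u`` (shape (n, 3)), returns angles
    (pitch, roll) such that ``u . v(pitch, roll) = 1`` with
    ``v = (sin roll, sin pitch, -cos pitch cos roll)``, i.e. the
    vertical-acceleration formula evaluates to exactly 1 g for a static pose.

    The system is underdetermined (two angles, one pose constraint); pitch is
    fixed as ``arcsin(uy)`` and roll solves the remaining trigonometric
    equation, taking the branch of smallest magnitude.  The reference pose
    ``u = (0, 0, -1)`` maps to pitch = roll = 0.
    """
    u = np.asarray(u, dtype=float)
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    pitch = np.arcsin(np.clip(uy, -1.0, 1.0))
    c = np.cos(pitch)
    # Solve ux*sin(roll) - uz*c*cos(roll) = 1 - uy^2  (== ux^2 + uz^2).
    a, b = ux, -uz * c
    target = 1.0 - uy**2
    r = np.hypot(a, b)
    phi = np.arctan2(b, a)
    with np.errstate(invalid="ignore", divide="ignore"):
        asn = np.arcsin(np.clip(np.where(r > 0, target / np.maximum(r, 1e-300), 0.0), -1.0, 1.0))
    cand1 = _wrap_angle(asn - phi)
    cand2 = _wrap_angle(np.pi - asn - phi)
    roll = np.where(np.abs(cand1) <= np.abs(cand2), cand1, cand2)
    roll = np.where(r > 1e-12, roll, 0.0)
    return pitch, roll


def _wrap_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - theta, 2.0 * np.pi)


def vertical_axis_vector(pitch: np.ndarray, roll: np.ndarray) -> np.ndarray:
    """(n, 3) projection vector ``v = (sin roll, sin pitch, -cos pitch cos roll)``.

    The dot product of an acceleration sample with ``v`` is the signed vertical
    acceleration; note ``|v| >= 1`` in general (it is unit only when pitch or
    roll vanishes).
    """
    pitch = np.atleast_1d(np.asarray(pitch, dtype=float))
    roll = np.atleast_1d(np.asarray(roll, dtype=float))
    return np.column_stack(
        [np.sin(roll), np.sin(pitch), -np.cos(pitch) * np.cos(roll)]
    )


def orientation_from_gravity(accel: AccelSeries, smooth: float = 0.5) -> OrientationSeries:
    """Estimate pitch/roll from the low-pass-filtered gravity direction.

    A gyroscope-free substitute: the acceleration is smoothed with a
    first-order exponential filter of time constant ``smooth`` seconds
    (0 disables smoothing), normalised to a unit gravity direction, and
    inverted to angles with :func:`angles_from_gravity_direction`.  During a
    static segment the resulting angles make the vertical-acceleration
    formula return 1 g exactly.
    """
    if smooth < 0:
        raise InvalidParameterError(f"smooth must be >= 0, got {smooth}")
    acc = accel.to_g()
    comp = acc.components()
    if smooth == 0:
        g_est = comp
    else:
        dt = 1.0 / acc.fs
        alpha = 1.0 - np.exp(-dt / smooth)
        g_est = (
            pd.DataFrame(comp).ewm(alpha=alpha, adjust=False).mean().to_numpy()
        )
    norms = np.linalg.norm(g_est, axis=1)
    safe = np.maximum(norms, 1e-12)
    u = g_est / safe[:, None]
    # Degenerate (near-zero gravity estimate, deep free-fall): hold the last
    # valid direction rather than emit garbage angles.
    bad = norms < 1e-6
    if bad.any():
        u = u.copy()
        last = np.array([0.0, 0.0, -1.0])
        for i in range(len(u)):
            if bad[i]:
                u[i] = last
            else:
                last = u[i]
    pitch, roll = angles_from_gravity_direction(u)
    return OrientationSeries(pitch=pitch, roll=roll)


def tilt_from_reference(orient: OrientationSeries, ref_index: int = 0) -> np.ndarray:
    """Per-sample tilt (radians) of the projection axis relative to a reference pose.

    Used by the post-fall posture check: the angle between the (normalised)
    vertical-projection vector at each sample and at ``ref_index``.
    """
    v = vertical_axis_vector(orient.pitch, orient.roll)
    v = v / np.linalg.norm(v, axis=1)[:, None]
    ref = v[ref_index]
    cos = np.clip(v @ ref, -1.0, 1.0)
    return np.arccos(cos)
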