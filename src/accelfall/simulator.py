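"""Seeded generator of labelled fall / activities-of-daily-living accelerometry.

Stands in for volunteer recordings: simulated falls in three directions
(forward, lateral, backward) at different speeds, interleaved with ADLs
(jogging, walking, standing, sitting, answering the phone), for a device worn
at the waist or in a trouser pocket (thigh).

Every fall follows the four-phase signature the threshold detectors
presuppose:

1. pre-fall quiet (|A_T| ~ 1 g, 2-4 s),
2. a free-fall dip (|A_T| descending to 0.1-0.4 g over ~0.3-0.5 s),
3. an impact spike (half-sine pulse peaking at 2.5-6 g for intensity 1,
   0.1-0.2 s, axis mix set by the fall direction),
4. lying aftermath (damped ringing, then rest at 1 g with the posture tilted
   >= 75 degrees from the pre-fall pose, >= 10 s).

The mounting convention is: waist wear puts the device y axis vertical and x
anterior (z lateral); thigh wear applies a random fixed rotation per recording
and a 1.4x noise multiplier.  Sensor noise is white Gaussian per axis,
sigma = 0.03 g at rest, scaled mildly by activity; the handful of impact-pulse
samples carry the designed profile exactly (noise is negligible against a
multi-g transient).  All randomness flows through one `numpy.random.default_rng`
per call, so a fixed seed reproduces a recording bit for bit on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_core import (
    AccelSeries,
    InvalidParameterError,
    OrientationSeries,
    angles_from_gravity_direction,
)

FALL_KINDS = ("fall_forward", "fall_lateral", "fall_backward")
ADL_KINDS = ("walk", "jog", "stand", "sit", "answer_phone")
POSITIONS = ("waist", "thigh")

#: upright gravity-reading direction in the canonical (waist) device frame:
#: y vertical, so gravity points along -y.
_UPRIGHT = np.array([0.0, -1.0, 0.0])

_QUIET_SIGMA = 0.03  # g, per-axis noise at rest
_THIGH_NOISE_MULT = 1.4


@dataclass(frozen=True)
class MovementSpec:
    """One movement in a session: a fall direction or an ADL kind."""

    kind: str
    duration: float | None = None  # None: kind-appropriate duration is drawn
    intensity: float = 1.0  # dimensionless speed/vigour scale in [0.5, 2]
    position: str = "waist"

    def __post_init__(self) -> None:
        if self.kind not in FALL_KINDS + ADL_KINDS:
            raise InvalidParameterError(
                f"unknown movement kind {self.kind!r}; "
                f"choose from {FALL_KINDS + ADL_KINDS}"
            )
        if self.duration is not None and not self.duration > 0:
            raise InvalidParameterError("duration must be > 0")
        if self.position not in POSITIONS:
            raise InvalidParameterError(f"position must be one of {POSITIONS}")


@dataclass
class LabeledRecording:
    """A synthetic session with ground-truth event intervals."""

    accel: AccelSeries
    orient: OrientationSeries
    events: list  # (t_start, t_end, kind) tuples, non-overlapping
    seed: int

    def fall_intervals(self) -> list:
        return [e for e in self.events if e[2].startswith("fall")]

    def adl_intervals(self) -> list:
        return [e for e in self.events if not e[2].startswith("fall")]


# ---------------------------------------------------------------------------
# small geometry helpers
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _rotate_path(u0: np.ndarray, axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """(n, 3) path of ``u0`` rotated about ``axis`` by per-sample ``angles``."""
    c = np.cos(angles)[:, None]
    s = np.sin(angles)[:, None]
    cross = np.cross(axis, u0)
    dot = float(np.dot(axis, u0))
    return u0 * c + cross * s + axis * dot * (1.0 - c)


def _slerp(u0: np.ndarray, u1: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors, w in [0, 1] per sample."""
    dot = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    theta = np.arccos(dot)
    if theta < 1e-9:
        return np.tile(u0, (len(w), 1))
    s = np.sin(theta)
    return (np.sin((1.0 - w) * theta)[:, None] * u0 + np.sin(w * theta)[:, None] * u1) / s


def _perpendicular(rng: np.random.Generator, u: np.ndarray) -> np.ndarray:
    """A random unit vector perpendicular to ``u``."""
    while True:
        v = rng.standard_normal(3)
        v -= u * np.dot(v, u)
        n = np.linalg.norm(v)
        if n > 1e-6:
            return v / n


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (unit-quaternion construction)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _nsamp(duration: float, fs: float) -> int:
    return max(1, int(round(duration * fs)))


# ---------------------------------------------------------------------------
# segment generators (canonical waist frame, starting upright)
# ---------------------------------------------------------------------------

def _gen_fall(rng, direction: str, intensity: float, fs: float, noise_mult: float):
    """Accel rows (g, noisy), posture rows (unit), and the ground-truth interval."""
    q_dur = rng.uniform(2.0, 4.0)
    ff_dur = rng.uniform(0.3, 0.5) / intensity
    imp_dur = rng.uniform(0.1, 0.2)
    aft_dur = rng.uniform(10.0, 12.0)
    dip = rng.uniform(0.1, 0.4)
    peak = rng.uniform(2.5, 6.0) * min(intensity, 1.5)
    lie_angle = np.radians(rng.uniform(80.0, 100.0))

    if direction == "fall_forward":
        rot_axis, imp_axis = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
    elif direction == "fall_backward":
        rot_axis, imp_axis = np.array([0.0, 0.0, -1.0]), np.array([-1.0, 0.0, 0.0])
    else:  # lateral, random side
        side = 1.0 if rng.random() < 0.5 else -1.0
        rot_axis = np.array([side, 0.0, 0.0])
        imp_axis = np.array([0.0, 0.0, side])
    # small off-axis mix so the impact is dominant on, not confined to, its axis
    jitter = 0.2 * rng.standard_normal(3)
    imp_dir = imp_axis + jitter - imp_axis * np.dot(jitter, imp_axis) * 0.5
    imp_dir /= np.linalg.norm(imp_dir)

    nq, nff, nimp = _nsamp(q_dur, fs), _nsamp(ff_dur, fs), _nsamp(imp_dur, fs)
    naft = _nsamp(aft_dur, fs)
    n = nq + nff + nimp + naft
    t = np.arange(n) / fs
    t_ff = nq / fs
    t_imp_end = (nq + nff + nimp) / fs
    t_lie = t_imp_end + 1.0  # posture settles one second into the aftermath

    # posture: upright until free fall starts, then smooth rotation to lying
    prog = _smoothstep((t - t_ff) / (t_lie - t_ff))
    posture = _rotate_path(_UPRIGHT, rot_axis, lie_angle * prog)

    # designed magnitude profile
    m = np.ones(n)
    m[nq : nq + nff] = np.linspace(1.0, dip, nff)
    k = np.arange(nimp)
    pulse = dip + (peak - dip) * np.sin(np.pi * (k + 0.5) / nimp)
    pulse[np.argmax(pulse)] = peak  # the peak sample carries the drawn value exactly
    m[nq + nff : nq + nff + nimp] = pulse

    # signal direction: posture, blended toward the impact axis during the pulse
    d = posture.copy()
    w = np.sin(np.pi * (k + 0.5) / nimp)[:, None]
    sl = slice(nq + nff, nq + nff + nimp)
    blend = (1.0 - w) * posture[sl] + w * imp_dir
    blend /= np.linalg.norm(blend, axis=1)[:, None]
    d[sl] = blend

    acc = m[:, None] * d
    # aftermath: damped ringing along the impact axis on top of gravity
    ta = t[nq + nff + nimp :] - t_imp_end
    ring = 0.6 * min(intensity, 1.5) * np.exp(-ta / 0.25) * np.cos(2 * np.pi * 6.0 * ta)
    acc[nq + nff + nimp :] += ring[:, None] * imp_dir

    noise = rng.normal(0.0, _QUIET_SIGMA * noise_mult, size=(n, 3))
    noise[sl] = 0.0  # impact pulse dominates; keep its designed amplitude exact
    acc += noise

    events = [(t_ff, t_imp_end + 1.0, direction)]
    return acc, posture, events


def _halfsine(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.sin(np.pi * (k + 0.5) / n)


def _gen_adl(rng, kind: str, intensity: float, fs: float, noise_mult: float,
             duration: float | None):
    u0 = _UPRIGHT
    if kind == "walk":
        dur = duration if duration is not None else rng.uniform(8.0, 15.0)
        n = _nsamp(dur, fs)
        t = np.arange(n) / fs
        m = 1.0 + 0.25 * intensity * np.sin(2 * np.pi * 2.0 * t)
        posture = np.tile(u0, (n, 1))
        acc = m[:, None] * posture
        sigma = 0.04
    elif kind == "jog":
        dur = duration if duration is not None else rng.uniform(8.0, 15.0)
        n = _nsamp(dur, fs)
        t = np.arange(n) / fs
        m = 1.0 + 0.8 * intensity * np.sin(2 * np.pi * 2.8 * t)
        # occasional heel-strike spikes, capped so |A_T| stays below 3 g
        stride = 1.0 / 2.8
        n_strides = int(dur / stride)
        nb = max(2, _nsamp(0.08, fs))
        for s in range(n_strides):
            if rng.random() < 0.3:
                amp = min(rng.uniform(0.3, 0.9), 2.9 - (1.0 + 0.8 * intensity))
                i0 = int(s * stride * fs)
                if i0 + nb <= n and amp > 0:
                    m[i0 : i0 + nb] += amp * _halfsine(nb)
        posture = np.tile(u0, (n, 1))
        acc = m[:, None] * posture
        sigma = 0.05
    elif kind == "stand":
        dur = duration if duration is not None else rng.uniform(5.0, 10.0)
        n = _nsamp(dur, fs)
        posture = np.tile(u0, (n, 1))
        acc = posture.copy()
        sigma = _QUIET_SIGMA
    elif kind == "sit":
        dur = duration if duration is not None else rng.uniform(6.0, 10.0)
        n = _nsamp(dur, fs)
        t = np.arange(n) / fs
        t_sit = 0.3 * dur
        # seat-contact transient, then a small (<30 degree) recline
        nb = max(2, _nsamp(0.3, fs))
        i0 = int(t_sit * fs)
        m = np.ones(n)
        amp = rng.uniform(0.5, 1.0)  # peak |A_T| in 1.5-2 g
        if i0 + nb <= n:
            m[i0 : i0 + nb] += amp * _halfsine(nb)
        tilt = np.radians(rng.uniform(10.0, 25.0))
        axis = _perpendicular(rng, u0)
        prog = _smoothstep((t - t_sit) / 1.0)
        posture = _rotate_path(u0, axis, tilt * prog)
        acc = m[:, None] * posture
        sigma = _QUIET_SIGMA
    elif kind == "answer_phone":
        dur = duration if duration is not None else rng.uniform(6.0, 10.0)
        n = _nsamp(dur, fs)
        t = np.arange(n) / fs
        angle = np.radians(rng.uniform(30.0, 60.0))
        axis = _perpendicular(rng, u0)
        ramp = rng.uniform(1.0, 1.5)
        up = _smoothstep((t - 0.25 * dur) / ramp)
        down = _smoothstep((t - 0.75 * dur) / ramp)
        posture = _rotate_path(u0, axis, angle * (up - down))
        acc = posture.copy()
        sigma = 0.04
    else:  # pragma: no cover - guarded by MovementSpec
        raise InvalidParameterError(f"unknown ADL kind {kind!r}")

    acc = acc + rng.normal(0.0, sigma * noise_mult, size=acc.shape)
    dur_actual = len(acc) / fs
    return acc, posture, [(0.0, dur_actual, kind)]


def _gen_bridge(rng, pose_from: np.ndarray, fs: float, noise_mult: float):
    """Quiet 1-3 s bridge rotating the posture smoothly back upright."""
    dur = rng.uniform(1.0, 3.0)
    n = _nsamp(dur, fs)
    w = _smoothstep(np.arange(n) / max(n - 1, 1))
    posture = _slerp(pose_from, _UPRIGHT, w)
    acc = posture + rng.normal(0.0, _QUIET_SIGMA * noise_mult, size=(n, 3))
    return acc, posture


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _package(acc, posture, events, fs, seed, position, rng) -> LabeledRecording:
    if position == "thigh":
        rot = _random_rotation(rng)
        acc = acc @ rot.T
        posture = posture @ rot.T
    pitch, roll = angles_from_gravity_direction(posture)
    accel = AccelSeries(fs=fs, ax=acc[:, 0], ay=acc[:, 1], az=acc[:, 2], unit="g")
    orient = OrientationSeries(pitch=pitch, roll=roll)
    return LabeledRecording(accel=accel, orient=orient, events=events, seed=seed)


def simulate_fall(
    direction: str = "fall_forward",
    intensity: float = 1.0,
    position: str = "waist",
    fs: float = 50.0,
    seed: int = 0,
) -> LabeledRecording:
    """One simulated fall segment (quiet / free-fall / impact / lying aftermath).

    ``direction`` may be given with or without the ``fall_`` prefix.
    """
    if not direction.startswith("fall_"):
        direction = "fall_" + direction
    if direction not in FALL_KINDS:
        raise InvalidParameterError(f"unknown fall direction {direction!r}")
    if not fs > 0:
        raise InvalidParameterError("fs must be > 0")
    rng = np.random.default_rng(seed)
    noise_mult = _THIGH_NOISE_MULT if position == "thigh" else 1.0
    acc, posture, events = _gen_fall(rng, direction, intensity, fs, noise_mult)
    return _package(acc, posture, events, fs, seed, position, rng)


def simulate_adl(
    kind: str,
    intensity: float = 1.0,
    position: str = "waist",
    fs: float = 50.0,
    seed: int = 0,
    duration: float | None = None,
) -> LabeledRecording:
    """One simulated activity-of-daily-living segment, labelled non-fall."""
    if kind not in ADL_KINDS:
        raise InvalidParameterError(
            f"unknown ADL kind {kind!r}; choose from {ADL_KINDS}"
        )
    if not fs > 0:
        raise InvalidParameterError("fs must be > 0")
    rng = np.random.default_rng(seed)
    noise_mult = _THIGH_NOISE_MULT if position == "thigh" else 1.0
    acc, posture, events = _gen_adl(rng, kind, intensity, fs, noise_mult, duration)
    return _package(acc, posture, events, fs, seed, position, rng)


def compose_session(
    specs: list[MovementSpec],
    fs: float = 50.0,
    seed: int = 0,
) -> LabeledRecording:
    """Concatenate movements into one session with quiet 1-3 s bridges.

    Each bridge rotates the posture smoothly back upright, so orientation is
    continuous across joins; ground-truth intervals keep per-segment labels at
    absolute session times.  The mounting position of the first spec governs
    the whole session.
    """
    if not specs:
        raise InvalidParameterError("specs must be non-empty")
    if not fs > 0:
        raise InvalidParameterError("fs must be > 0")
    rng = np.random.default_rng(seed)
    position = specs[0].position
    noise_mult = _THIGH_NOISE_MULT if position == "thigh" else 1.0

    acc_parts, posture_parts, events = [], [], []
    pose = _UPRIGHT
    offset = 0.0
    for spec in specs:
        bacc, bpost = _gen_bridge(rng, pose, fs, noise_mult)
        acc_parts.append(bacc)
        posture_parts.append(bpost)
        offset += len(bacc) / fs
        if spec.kind in FALL_KINDS:
            sacc, spost, sevents = _gen_fall(rng, spec.kind, spec.intensity, fs, noise_mult)
        else:
            sacc, spost, sevents = _gen_adl(
                rng, spec.kind, spec.intensity, fs, noise_mult, spec.duration
            )
        acc_parts.append(sacc)
        posture_parts.append(spost)
        events.extend((offset + s, offset + e, kind) for s, e, kind in sevents)
        offset += len(sacc) / fs
        pose = spost[-1]

    acc = np.vstack(acc_parts)
    posture = np.vstack(posture_parts)
    return _package(acc, posture, events, fs, seed, position, rng)


def default_session_specs(
    n_falls: int = 25,
    n_adls: int = 25,
    position: str = "waist",
    seed: int = 0,
) -> list[MovementSpec]:
    """A balanced, shuffled movement list emulating one volunteer's test run.

    Falls cycle through the three directions at mildly varying intensity
    ("different speeds"); ADLs cycle through the five kinds.
    """
    rng = np.random.default_rng(seed)
    specs = [
        MovementSpec(
            kind=FALL_KINDS[i % 3],
            intensity=float(rng.uniform(0.8, 1.3)),
            position=position,
        )
        for i in range(n_falls)
    ] + [
        MovementSpec(
            kind=ADL_KINDS[i % 5],
            intensity=float(rng.uniform(0.8, 1.2)),
            position=position,
        )
        for i in range(n_adls)
    ]
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]
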