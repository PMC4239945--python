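"""Shared builders for constructed signals used across the test modules."""

import numpy as np
import pytest

from accelfall import AccelSeries, OrientationSeries


def make_accel(ax, ay, az, fs=50.0, unit="g", t0=0.0) -> AccelSeries:
    ax = np.atleast_1d(np.asarray(ax, dtype=float))
    ay = np.atleast_1d(np.asarray(ay, dtype=float))
    az = np.atleast_1d(np.asarray(az, dtype=float))
    return AccelSeries(fs=fs, ax=ax, ay=ay, az=az, unit=unit, t0=t0)


def flat_orientation(n: int, pitch=0.0, roll=0.0) -> OrientationSeries:
    return OrientationSeries(pitch=np.full(n, float(pitch)), roll=np.full(n, float(roll)))


def quiet_signal(duration_s: float, fs=50.0, sigma=0.0, seed=0) -> AccelSeries:
    """Upright rest: 1 g along -z plus optional white noise."""
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    ax = rng.normal(0.0, sigma, n) if sigma else np.zeros(n)
    ay = rng.normal(0.0, sigma, n) if sigma else np.zeros(n)
    az = -1.0 + (rng.normal(0.0, sigma, n) if sigma else 0.0)
    return make_accel(ax, ay, az if np.ndim(az) else np.full(n, az), fs=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
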