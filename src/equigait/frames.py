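"""Frame-of-reference rotations for pocket-phone IMU signals.

Three frames are used:

* **device** — the phone's own axes, arbitrary per ride;
* **world** — x = east, y = north, z = up (right-handed); reached from the
  device frame through the phone's orientation quaternion;
* **horse** — x = front–back (positive forward), y = left–right (positive
  left), z vertical; reached from the world frame by a yaw rotation through
  the horse's heading, derived from consecutive 1 Hz GPS fixes and smoothed
  circularly over a 1 s window.

Quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and represent the
device→world rotation of vectors. Headings are degrees clockwise from
geographic north in ``[0, 360)``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .sensor_io import GpsFix, SensorTrace


class NormalizationError(ValueError):
    """A quaternion that should be unit-norm is not."""


class UndefinedHeadingError(ValueError):
    """Heading is undefined (zero displacement between fixes)."""


class FrameError(ValueError):
    """A trace is in the wrong frame or heading does not cover it."""


@dataclasses.dataclass
class HeadingSeries:
    """Heading samples: degrees clockwise from north in [0, 360)."""

    t: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.t.shape != self.theta.shape:
            raise ValueError("t and theta must have equal shapes")
        if self.theta.size and (np.any(self.theta < 0) or np.any(self.theta >= 360)):
            raise ValueError("theta must lie in [0, 360)")

    def __len__(self) -> int:
        return len(self.t)

    def at(self, t: np.ndarray) -> np.ndarray:
        """Heading at times ``t``, held piecewise-constant between samples."""
        if len(self.t) == 0:
            raise FrameError("empty heading series")
        idx = np.searchsorted(self.t, np.asarray(t, float) + 1e-12, side="right") - 1
        idx = np.clip(idx, 0, len(self.t) - 1)
        return self.theta[idx]


def apply_quaternion(v: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by unit quaternion(s) ``q`` (q v q*).

    ``v`` may be (3,) or (n, 3); ``q`` may be (4,) or (n, 4), scalar-first.
    Non-unit quaternions are rejected, not silently normalised.
    """
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    q2 = np.atleast_2d(q)
    norms = np.linalg.norm(q2, axis=1)
    if not np.all(np.abs(norms - 1.0) <= 1e-6):
        raise NormalizationError("quaternion norm deviates from 1 by more than 1e-6")
    w, x, y, z = q2[:, 0], q2[:, 1], q2[:, 2], q2[:, 3]
    u = q2[:, 1:]
    # q v q* = v + 2w (u x v) + 2 u x (u x v)
    uv = np.cross(u, v2)
    uuv = np.cross(u, uv)
    out = v2 + 2.0 * w[:, None] * uv + 2.0 * uuv
    return out[0] if single else out


def quaternion_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def device_to_world(trace: SensorTrace) -> SensorTrace:
    """Rotate a device-frame trace to the world frame via its quaternions."""
    if trace.frame != "device":
        raise FrameError(f"expected device-frame trace, got {trace.frame!r}")
    if trace.quaternions is None:
        raise FrameError("trace has no orientation quaternions")
    acc = np.column_stack([trace.channels["ax"], trace.channels["ay"], trace.channels["az"]])
    gyr = np.column_stack([trace.channels["gx"], trace.channels["gy"], trace.channels["gz"]])
    acc_w = apply_quaternion(acc, trace.quaternions)
    gyr_w = apply_quaternion(gyr, trace.quaternions)
    channels = {
        "ax": acc_w[:, 0], "ay": acc_w[:, 1], "az": acc_w[:, 2],
        "gx": gyr_w[:, 0], "gy": gyr_w[:, 1], "gz": gyr_w[:, 2],
    }
    return SensorTrace(t=trace.t, channels=channels, rate=trace.rate, frame="world")


def gps_bearing(a: GpsFix, b: GpsFix) -> float:
    """Bearing of the displacement a→b, degrees clockwise from north.

    Uses the local equirectangular approximation
    ``dx = cos(lat)·dlon, dy = dlat, theta = atan2(dx, dy)``.
    """
    if b.t <= a.t:
        raise ValueError("fixes must be time-ordered (a.t < b.t)")
    lat0 = np.deg2rad(0.5 * (a.lat + b.lat))
    dx = np.cos(lat0) * (b.lon - a.lon)
    dy = b.lat - a.lat
    if dx == 0.0 and dy == 0.0:
        raise UndefinedHeadingError("zero displacement between fixes")
    theta = np.rad2deg(np.arctan2(dx, dy))
    return float(theta % 360.0)


def unwrap_degrees(seq: Sequence[float]) -> np.ndarray:
    """Unwrap a degree sequence so successive differences are ≤ 180 in size.

    Each element whose absolute difference from the (already corrected)
    predecessor exceeds 180° is shifted by the multiple of 360° that brings
    the difference within ±180°; every output element is congruent to its
    input mod 360.
    """
    seq = np.asarray(seq, dtype=float)
    out = seq.copy()
    for i in range(1, len(out)):
        d = out[i] - out[i - 1]
        if abs(d) > 180.0:
            out[i] -= 360.0 * np.round(d / 360.0)
    return out


def heading_from_gps(fixes: Sequence[GpsFix]) -> HeadingSeries:
    """Raw heading from consecutive GPS fixes.

    The bearing of each fix pair is stamped at the later fix's time; pairs
    with zero displacement hold the previous heading. Fixes before the first
    defined heading are dropped.
    """
    t: list[float] = []
    theta: list[float] = []
    prev: float | None = None
    for a, b in zip(fixes[:-1], fixes[1:]):
        try:
            prev = gps_bearing(a, b)
        except UndefinedHeadingError:
            if prev is None:
                continue
        t.append(b.t)
        theta.append(prev)
    if not t:
        raise UndefinedHeadingError("no nonzero displacement in GPS track")
    return HeadingSeries(t=np.array(t), theta=np.array(theta))


def smooth_heading(h: HeadingSeries, window: float = 1.0) -> HeadingSeries:
    """Circularly smooth a heading series with a centered moving average.

    The series is unwrapped, averaged over samples within ±window/2 of each
    timestamp, and wrapped back to [0, 360).
    """
    if len(h) == 0:
        raise ValueError("empty heading series")
    unwrapped = unwrap_degrees(h.theta)
    out = np.empty_like(unwrapped)
    half = window / 2.0
    for i, ti in enumerate(h.t):
        mask = np.abs(h.t - ti) <= half + 1e-12
        out[i] = unwrapped[mask].mean()
    return HeadingSeries(t=h.t.copy(), theta=out % 360.0)


def world_to_horse(trace: SensorTrace, h: HeadingSeries) -> SensorTrace:
    """Rotate a world-frame trace into the horse frame by yaw through heading.

    Per sample, with heading θ (clockwise from north, held piecewise-constant
    between heading samples):

    * front–back  x_h = e·sinθ + n·cosθ
    * left–right  y_h = −e·cosθ + n·sinθ
    * vertical    z_h = z (unchanged)

    applied identically to acceleration and angular velocity. The horizontal
    vector norm is preserved.
    """
    if trace.frame != "world":
        raise FrameError(f"expected world-frame trace, got {trace.frame!r}")
    theta = np.deg2rad(h.at(trace.t))
    s, c = np.sin(theta), np.cos(theta)
    channels: dict[str, np.ndarray] = {}
    for ex, ey, ez in (("ax", "ay", "az"), ("gx", "gy", "gz")):
        e, n = trace.channels[ex], trace.channels[ey]
        channels[ex] = e * s + n * c
        channels[ey] = -e * c + n * s
        channels[ez] = trace.channels[ez]
    return SensorTrace(t=trace.t, channels=channels, rate=trace.rate, frame="horse")
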