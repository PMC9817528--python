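"""Reading, writing and resampling of phone sensor logs.

All logs are plain CSV with a ``.`` decimal separator and comma delimiter:

* IMU log: header ``t,ax,ay,az,gx,gy,gz,qw,qx,qy,qz`` — time in seconds from
  ride start, acceleration in m/s², angular velocity in deg/s, and an
  optional device→world unit quaternion (scalar-first). Gravity is not
  removed from the acceleration channels.
* GPS log: header ``t,lat,lon,speed`` at nominally 1 Hz; ``speed`` optional.
* Label log: header ``t,label``, one row per hoof-on event.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gaits import TS_LABELS, VocabularyError

IMU_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
QUAT_COLUMNS = ("qw", "qx", "qy", "qz")

#: Device-frame channel names in canonical order.
IMU_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")


class FormatError(ValueError):
    """A log file is missing a mandatory column."""


class IntegrityError(ValueError):
    """A log file violates an ordering or consistency invariant."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested operation."""


@dataclasses.dataclass
class GpsFix:
    """A single GPS fix: time (s), latitude/longitude (deg), speed (m/s)."""

    t: float
    lat: float
    lon: float
    speed: float | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclasses.dataclass
class LabelEvent:
    """One gait-label event, emitted at a hoof-on instant."""

    t: float
    ts_label: str

    def __post_init__(self) -> None:
        if self.ts_label not in TS_LABELS:
            raise VocabularyError(f"unknown TS label: {self.ts_label!r}")


@dataclasses.dataclass
class SensorTrace:
    """A multichannel sensor record with shared timestamps.

    Parameters
    ----------
    t:
        Sample times in seconds, strictly increasing.
    channels:
        Mapping channel name -> 1-D sample array, all the same length as ``t``.
    rate:
        Nominal sampling rate in Hz, or ``None`` for irregular stamps.
    frame:
        Frame of reference the vector channels live in: ``"device"``,
        ``"world"`` or ``"horse"``.
    quaternions:
        Optional (n, 4) array of scalar-first device→world unit quaternions,
        one per sample. Only meaningful for device-frame traces.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    rate: float | None = None
    frame: str = "device"
    quaternions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if not np.all(np.isfinite(self.t)):
            raise IntegrityError("non-finite timestamps")
        diffs = np.diff(self.t)
        bad = np.nonzero(diffs <= 0)[0]
        if bad.size:
            raise IntegrityError(
                f"non-monotone timestamps at index {int(bad[0]) + 1}"
            )
        n = len(self.t)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, arr in self.channels.items():
            if arr.shape != (n,):
                raise IntegrityError(f"channel {name!r} length {arr.shape} != {n}")
        if self.frame not in ("device", "world", "horse"):
            raise ValueError(f"unknown frame: {self.frame!r}")
        if self.quaternions is not None:
            q = np.asarray(self.quaternions, dtype=float)
            if q.shape != (n, 4):
                raise IntegrityError("quaternion array must be (n, 4)")
            norms = np.linalg.norm(q, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise IntegrityError("quaternions must have unit norm within 1e-6")
            self.quaternions = q

    def __len__(self) -> int:
        return len(self.t)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def stack(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Return channels stacked as a (n_channels, n_samples) array."""
        names = tuple(names) if names is not None else self.channel_names
        return np.stack([self.channels[n] for n in names])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def read_sensor_log(path: str | Path) -> tuple[SensorTrace, list[GpsFix]]:
    """Read an IMU log (and its sibling GPS log if present).

    The IMU file at ``path`` must carry the columns
    ``t,ax,ay,az,gx,gy,gz``; quaternion columns are optional and their
    absence yields a quaternion-free trace. If a file named
    ``<stem>_gps.csv`` (or ``<stem with '_imu' replaced by '_gps'>.csv``)
    exists next to the IMU file, its fixes are returned too.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in IMU_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path.name}")
    has_quat = all(c in df.columns for c in QUAT_COLUMNS)
    quat = df[list(QUAT_COLUMNS)].to_numpy(float) if has_quat else None
    trace = SensorTrace(
        t=df["t"].to_numpy(float),
        channels={c: df[c].to_numpy(float) for c in IMU_CHANNELS},
        rate=_infer_rate(df["t"].to_numpy(float)),
        frame="device",
        quaternions=quat,
    )
    gps = read_gps_log(_gps_sibling(path)) if _gps_sibling(path).exists() else []
    return trace, gps


def _gps_sibling(imu_path: Path) -> Path:
    stem = imu_path.stem
    if stem.endswith("_imu"):
        return imu_path.with_name(stem[: -len("_imu")] + "_gps" + imu_path.suffix)
    return imu_path.with_name(stem + "_gps" + imu_path.suffix)


def _infer_rate(t: np.ndarray, tol: float = 1e-6) -> float | None:
    if len(t) < 2:
        return None
    dt = np.diff(t)
    if np.all(np.abs(dt - dt[0]) < tol) and dt[0] > 0:
        return 1.0 / float(dt[0])
    return None


def read_gps_log(path: str | Path) -> list[GpsFix]:
    """Read a GPS log ``t,lat,lon[,speed]``."""
    df = pd.read_csv(path)
    for col in ("t", "lat", "lon"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {Path(path).name}")
    speeds = df["speed"] if "speed" in df.columns else None
    fixes = []
    for i in range(len(df)):
        fixes.append(
            GpsFix(
                t=float(df["t"].iloc[i]),
                lat=float(df["lat"].iloc[i]),
                lon=float(df["lon"].iloc[i]),
                speed=float(speeds.iloc[i]) if speeds is not None else None,
            )
        )
    return fixes


def read_label_log(path: str | Path) -> list[LabelEvent]:
    """Read a gait-label event log ``t,label``.

    Unknown label strings raise :class:`~equigait.gaits.VocabularyError`;
    out-of-order timestamps raise :class:`IntegrityError`.
    """
    df = pd.read_csv(path)
    for col in ("t", "label"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {Path(path).name}")
    t = df["t"].to_numpy(float)
    bad = np.nonzero(np.diff(t) < 0)[0]
    if bad.size:
        raise IntegrityError(f"non-monotone timestamps at index {int(bad[0]) + 1}")
    return [LabelEvent(float(ti), str(lab)) for ti, lab in zip(t, df["label"])]


def write_sensor_log(trace: SensorTrace, path: str | Path) -> None:
    """Write a device-frame trace as an IMU CSV (full float precision)."""
    cols: dict[str, np.ndarray] = {"t": trace.t}
    for name in IMU_CHANNELS:
        cols[name] = trace.channels[name]
    if trace.quaternions is not None:
        for j, name in enumerate(QUAT_COLUMNS):
            cols[name] = trace.quaternions[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_gps_log(fixes: Sequence[GpsFix], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": [f.t for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
            "speed": [f.speed if f.speed is not None else np.nan for f in fixes],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def write_label_log(events: Sequence[LabelEvent], path: str | Path) -> None:
    pd.DataFrame(
        {"t": [e.t for e in events], "label": [e.ts_label for e in events]}
    ).to_csv(path, index=False, float_format="%.17g")


def resample_trace(trace: SensorTrace, rate: float) -> SensorTrace:
    """Resample a trace to a uniform rate by per-channel linear interpolation.

    The output grid starts at the trace's first timestamp and spans its time
    range at ``1/rate`` spacing. Quaternions, when present, are carried over
    by nearest-previous sample (they are orientations, not vector channels,
    and linear interpolation would denormalise them).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(trace) < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    t0, t1 = float(trace.t[0]), float(trace.t[-1])
    n = int(np.floor((t1 - t0) * rate + 1e-9)) + 1
    grid = t0 + np.arange(n) / rate
    channels = {
        name: np.interp(grid, trace.t, arr) for name, arr in trace.channels.items()
    }
    quats = None
    if trace.quaternions is not None:
        idx = np.searchsorted(trace.t, grid + 1e-12, side="right") - 1
        idx = np.clip(idx, 0, len(trace) - 1)
        quats = trace.quaternions[idx]
    return SensorTrace(t=grid, channels=channels, rate=rate, frame=trace.frame, quaternions=quats)
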