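"""Labelled timelines, segmentation and horse-level dataset splits.

Variable-rate label events (one per hoof-on) become a piecewise-constant
:class:`LabeledTimeline`; fixed-duration windows are cut from a uniformly
sampled trace with 90% overlap, discarding anything within an exclusion
radius of a gait switch; segments carry horse/rider/ride provenance so
splits can be made at the horse level.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .gaits import DISCARDED, Gait, map_ts_label
from .sensor_io import GpsFix, InsufficientDataError, LabelEvent, SensorTrace

#: Dense segment step used inside flying-pace regions, in seconds.
FLYING_PACE_STEP = 0.020


@dataclasses.dataclass
class LabeledTimeline:
    """Piecewise-constant gait label over time.

    ``labels[i]`` holds on ``[breakpoints[i], breakpoints[i+1])``; the last
    label holds from ``breakpoints[-1]`` onward (unbounded). Adjacent
    intervals always carry different labels.
    """

    breakpoints: np.ndarray
    labels: list  # Gait or DISCARDED per interval

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if len(self.breakpoints) != len(self.labels):
            raise ValueError("breakpoints and labels must have equal length")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        for a, b in zip(self.labels[:-1], self.labels[1:]):
            if a == b:
                raise ValueError("adjacent intervals must differ in label")

    def label_at(self, t: float):
        """Label at time ``t`` (None before the first breakpoint)."""
        i = int(np.searchsorted(self.breakpoints, t + 1e-12, side="right")) - 1
        return None if i < 0 else self.labels[i]

    @property
    def switch_times(self) -> np.ndarray:
        """Times at which the label changes (all breakpoints after the first)."""
        return self.breakpoints[1:]


@dataclasses.dataclass
class Segment:
    """One fixed-duration training window."""

    x: np.ndarray  # (n_channels, n_samples)
    y: Gait
    horse_id: int
    rider_id: int
    ride_id: int
    t_start: float


@dataclasses.dataclass
class SplitSpec:
    """Horse-level test split plus a seeded 85/15 train/validation split."""

    test_horses: frozenset[int] = frozenset({1, 2, 8, 9, 11})
    val_fraction: float = 0.15
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        self.test_horses = frozenset(self.test_horses)
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")


class MissingChannelError(ValueError):
    """A requested feature channel has no source data."""


def build_timeline(events: Sequence[LabelEvent]) -> LabeledTimeline:
    """Build a piecewise-constant timeline from label events.

    Each event's mapped gait holds from its timestamp until the next event;
    runs of equal mapped labels are merged.
    """
    if not events:
        raise InsufficientDataError("no label events")
    breakpoints: list[float] = []
    labels: list = []
    for ev in events:
        lab = map_ts_label(ev.ts_label)
        if labels and labels[-1] == lab:
            continue
        breakpoints.append(ev.t)
        labels.append(lab)
    return LabeledTimeline(np.array(breakpoints), labels)


def generate_segments(
    trace: SensorTrace,
    tl: LabeledTimeline,
    window: float,
    *,
    overlap: float = 0.9,
    exclusion: float = 2.0,
    horse_id: int = 0,
    rider_id: int = 0,
    ride_id: int = 0,
    channel_names: Sequence[str] | None = None,
) -> list[Segment]:
    """Cut overlapping fixed-duration segments from a uniform trace.

    Candidate start times advance by ``(1 − overlap)·window``, rounded to a
    whole number of samples — except inside flying-pace intervals, where the
    step is 20 ms regardless of window length. A candidate ``[s, s+window]``
    is kept only when it lies entirely inside one gait interval and no gait
    switch lies within ``±exclusion`` seconds of any part of it. Intervals
    labelled discarded yield nothing. A window longer than the trace yields
    an empty list.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if trace.rate is None:
        raise ValueError("trace must be uniformly sampled")
    rate = trace.rate
    n_win = int(round(window * rate))
    if n_win > len(trace):
        return []
    switches = tl.switch_times
    x_all = trace.stack(channel_names)

    # the 1e-6 nudge keeps e.g. (1-0.9)*window*rate from landing at 7.4999...
    step_default = max(1, int(round((1.0 - overlap) * window * rate + 1e-6)))
    step_pace = max(1, int(round(FLYING_PACE_STEP * rate + 1e-6)))

    segments: list[Segment] = []
    i = 0
    n = len(trace)
    while i + n_win <= n:
        s = float(trace.t[i])
        e = s + window
        t_last = float(trace.t[i + n_win - 1])
        label = tl.label_at(s)
        # Exclusion boundaries are open: a segment whose edge sits exactly
        # `exclusion` away from a switch is kept.
        keep = (
            label is not None
            and label != DISCARDED
            and tl.label_at(t_last) == label
            and not np.any((switches > s - exclusion) & (switches < e + exclusion))
        )
        if keep:
            segments.append(
                Segment(
                    x=x_all[:, i : i + n_win].copy(),
                    y=label,
                    horse_id=horse_id,
                    rider_id=rider_id,
                    ride_id=ride_id,
                    t_start=s,
                )
            )
        step = step_pace if label == Gait.FLYING_PACE else step_default
        i += step
    return segments


def build_feature_channels(
    trace: SensorTrace,
    gps: Sequence[GpsFix] | None,
    use: set[str],
) -> SensorTrace:
    """Assemble the model input channels from a trace and optional GPS.

    ``use`` is a subset of ``{"accel", "gyro", "speed"}``; the output carries
    3 channels per inertial group plus 1 for speed (GPS speed held constant
    between fixes, sampled on the trace grid), so the channel count is one
    of 3, 6 or 7.
    """
    allowed = {"accel", "gyro", "speed"}
    if not use or not use <= allowed:
        raise ValueError(f"use must be a nonempty subset of {allowed}")
    channels: dict[str, np.ndarray] = {}
    if "accel" in use:
        for name in ("ax", "ay", "az"):
            channels[name] = trace.channels[name]
    if "gyro" in use:
        for name in ("gx", "gy", "gz"):
            channels[name] = trace.channels[name]
    if "speed" in use:
        if not gps:
            raise MissingChannelError("speed requested but no GPS fixes given")
        t_fix = np.array([f.t for f in gps])
        v_fix = np.array(
            [f.speed if f.speed is not None else np.nan for f in gps]
        )
        if np.any(np.isnan(v_fix)):
            raise MissingChannelError("speed requested but GPS fixes lack speed")
        idx = np.searchsorted(t_fix, trace.t + 1e-12, side="right") - 1
        idx = np.clip(idx, 0, len(t_fix) - 1)
        channels["speed"] = v_fix[idx]
    return SensorTrace(t=trace.t, channels=channels, rate=trace.rate, frame=trace.frame)


def split_dataset(
    segments: Sequence[Segment], spec: SplitSpec
) -> dict[str, list[Segment]]:
    """Split segments into train/val/test sets.

    Test = every segment whose horse is in ``spec.test_horses`` (a listed
    horse absent from the data produces a warning, not an error). The rest
    are shuffled with ``spec.shuffle_seed`` and split
    ``(1 − val_fraction)/val_fraction`` into train/validation at the segment
    level.
    """
    import warnings

    present = {s.horse_id for s in segments}
    for h in sorted(spec.test_horses - present):
        warnings.warn(f"test horse {h} absent from data", stacklevel=2)
    test = [s for s in segments if s.horse_id in spec.test_horses]
    rest = [s for s in segments if s.horse_id not in spec.test_horses]
    rng = np.random.default_rng(spec.shuffle_seed)
    order = rng.permutation(len(rest))
    n_val = int(round(spec.val_fraction * len(rest)))
    val = [rest[i] for i in order[:n_val]]
    train = [rest[i] for i in order[n_val:]]
    return {"train": train, "val": val, "test": test}
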