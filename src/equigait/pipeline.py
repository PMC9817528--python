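"""End-to-end conveniences: raw logs → frame-rotated traces → segments."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .dataset import Segment, build_feature_channels, build_timeline, generate_segments
from .frames import (
    HeadingSeries,
    device_to_world,
    heading_from_gps,
    smooth_heading,
    world_to_horse,
)
from .sensor_io import GpsFix, LabelEvent, SensorTrace, resample_trace


def prepare_trace(
    trace: SensorTrace,
    gps: Sequence[GpsFix] | None = None,
    frame: str = "horse",
    rate: float | None = 50.0,
    heading: HeadingSeries | None = None,
) -> SensorTrace:
    """Rotate a device-frame trace to the requested frame and resample.

    For the horse frame the heading comes from the GPS track (smoothed over
    1 s) unless an explicit series is given.
    """
    if rate is not None and trace.rate != rate:
        trace = resample_trace(trace, rate)
    if frame == "device":
        return trace
    world = device_to_world(trace)
    if frame == "world":
        return world
    if frame != "horse":
        raise ValueError(f"unknown frame {frame!r}")
    if heading is None:
        if not gps:
            raise ValueError("horse frame needs GPS fixes or a heading series")
        heading = smooth_heading(heading_from_gps(list(gps)))
    return world_to_horse(world, heading)


def segments_from_ride(
    trace: SensorTrace,
    gps: Sequence[GpsFix] | None,
    label_events: Sequence[LabelEvent],
    *,
    frame: str = "horse",
    window: float = 1.5,
    overlap: float = 0.9,
    exclusion: float = 2.0,
    channels: set[str] = frozenset({"accel", "gyro"}),
    rate: float | None = 50.0,
    horse_id: int = 0,
    rider_id: int = 0,
    ride_id: int = 0,
    heading: HeadingSeries | None = None,
) -> list[Segment]:
    """Full preprocessing of one ride into labelled training segments."""
    prepared = prepare_trace(trace, gps, frame=frame, rate=rate, heading=heading)
    feats = build_feature_channels(prepared, list(gps) if gps else None, set(channels))
    timeline = build_timeline(list(label_events))
    return generate_segments(
        feats,
        timeline,
        window,
        overlap=overlap,
        exclusion=exclusion,
        horse_id=horse_id,
        rider_id=rider_id,
        ride_id=ride_id,
    )
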