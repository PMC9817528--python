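"""Agreement protocol between the limb-sensor labeller and a judge panel.

A panel of judges clicks gait labels while watching ride video; each click
holds until the next (click-and-hold semantics). Every 250 ms the modal
label across judges is taken — a tie means no majority (code −2). The
limb-sensor ("TS") event log is summarised on a 1 s sliding window with a
0.5 s step, the modal event label per window stamped at the window centre,
with times shifted so the series starts at 0 s. Pairing each TS timeline
point with the aggregated judge label at that instant yields test cases;
cases with truth −2 (disputed) or −1 (not yet classified) are discarded,
and symmetric exclusion radii around transitions of either series remove
cases where transition-timing leeway is warranted.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .gaits import JudgeLabel, ts_label_to_judge_code
from .sensor_io import InsufficientDataError, LabelEvent


class CoverageError(ValueError):
    """The two series share no observation window."""


@dataclasses.dataclass
class JudgeStream:
    """One judge's time-ordered (t, label) clicks, each held until the next."""

    judge_id: int
    events: list[tuple[float, JudgeLabel]]

    def __post_init__(self) -> None:
        t = [e[0] for e in self.events]
        if any(b < a for a, b in zip(t, t[1:])):
            raise ValueError("judge events must be time-ordered")

    def label_at(self, t: float) -> JudgeLabel:
        """Held label at time ``t`` (−1 before the first click)."""
        lab = JudgeLabel.NOT_CLASSIFIED
        for ti, li in self.events:
            if ti <= t + 1e-12:
                lab = li
            else:
                break
        return lab


@dataclasses.dataclass
class StepSeries:
    """A piecewise-constant integer-label series sampled on a regular grid."""

    t: np.ndarray
    labels: np.ndarray  # integer codes per grid point

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def label_at(self, t: float) -> int:
        idx = int(np.searchsorted(self.t, t + 1e-12, side="right")) - 1
        idx = max(0, min(idx, len(self.t) - 1))
        return int(self.labels[idx])

    @property
    def change_points(self) -> np.ndarray:
        """Times at which the label changes (the time of the new value)."""
        d = np.nonzero(np.diff(self.labels) != 0)[0]
        return self.t[d + 1]


@dataclasses.dataclass
class TestCase:
    t: float
    predicted: int  # TS label in judge coding
    truth: int  # aggregated judge label


def aggregate_judges(
    streams: Sequence[JudgeStream],
    t_start: float,
    t_end: float,
    tick: float = 0.25,
) -> StepSeries:
    """Aggregate judge streams on a regular tick grid by strict plurality.

    At each tick, every judge's held label is sampled; the strictly most
    common label wins, and any tie for most common yields −2 (no
    majority). Judges still at −1 (no click yet) vote −1, so the series
    starts at −1 before the first classifications.
    """
    if not streams:
        raise ValueError("need at least one judge stream")
    n = int(np.floor((t_end - t_start) / tick + 1e-9)) + 1
    grid = t_start + np.arange(n) * tick
    out = np.empty(n, dtype=np.int64)
    for i, t in enumerate(grid):
        votes = [int(s.label_at(t)) for s in streams]
        vals, counts = np.unique(votes, return_counts=True)
        best = counts.max()
        winners = vals[counts == best]
        out[i] = int(winners[0]) if len(winners) == 1 else int(JudgeLabel.NO_MAJORITY)
    return StepSeries(t=grid, labels=out)


def ts_timeline(
    events: Sequence[LabelEvent], window: float = 1.0, step: float = 0.5
) -> StepSeries:
    """Summarise TS label events on a sliding window.

    Windows are centred at ``t0 + k·step`` (``t0`` = first event time); per
    window the modal event label wins (ties go to the label of the most
    recent tied event). The first event's timestamp is subtracted, so the
    output series runs 0, step, 2·step, … seconds.
    """
    if not events:
        raise InsufficientDataError("no label events")
    t0 = events[0].t
    t = np.array([e.t for e in events]) - t0
    codes = np.array([int(ts_label_to_judge_code(e.ts_label)) for e in events])
    half = window / 2.0
    n = int(np.floor(t[-1] / step + 1e-9)) + 1
    grid = np.arange(n) * step
    out = np.empty(n, dtype=np.int64)
    last_val = codes[0]
    for i, c in enumerate(grid):
        mask = (t >= c - half - 1e-12) & (t <= c + half + 1e-12)
        if not mask.any():
            out[i] = last_val  # hold through an empty window (e.g. halt gap)
            continue
        w_codes = codes[mask]
        vals, counts = np.unique(w_codes, return_counts=True)
        winners = vals[counts == counts.max()]
        if len(winners) == 1:
            out[i] = winners[0]
        else:
            # most recent event among tied labels decides
            in_win = np.nonzero(mask)[0]
            for j in in_win[::-1]:
                if codes[j] in winners:
                    out[i] = codes[j]
                    break
        last_val = out[i]
    return StepSeries(t=grid, labels=out)


def pair_test_cases(
    ts_series: StepSeries, judge_series: StepSeries
) -> list[TestCase]:
    """One test case per TS timeline point inside the judges' window.

    Cases whose truth is −2 (disputed) or −1 (not classified) are dropped.
    """
    lo = max(ts_series.t[0], judge_series.t[0])
    hi = min(ts_series.t[-1], judge_series.t[-1])
    if hi < lo:
        raise CoverageError("TS and judge series do not overlap in time")
    cases = []
    for t, pred in zip(ts_series.t, ts_series.labels):
        if t < lo - 1e-9 or t > hi + 1e-9:
            continue
        truth = judge_series.label_at(float(t))
        if truth in (int(JudgeLabel.NO_MAJORITY), int(JudgeLabel.NOT_CLASSIFIED)):
            continue
        cases.append(TestCase(t=float(t), predicted=int(pred), truth=truth))
    return cases


def apply_exclusions(
    cases: Sequence[TestCase],
    ts_transitions: np.ndarray,
    judge_transitions: np.ndarray,
    ts_ms: float,
    judge_ms: float,
) -> list[TestCase]:
    """Drop cases within the exclusion radius of either series' transitions."""
    if ts_ms < 0 or judge_ms < 0:
        raise ValueError("exclusion radii must be nonnegative")
    ts_r, judge_r = ts_ms / 1000.0, judge_ms / 1000.0
    ts_transitions = np.asarray(ts_transitions, dtype=float)
    judge_transitions = np.asarray(judge_transitions, dtype=float)
    out = []
    for case in cases:
        near_ts = ts_r > 0 and ts_transitions.size and (
            np.min(np.abs(ts_transitions - case.t)) <= ts_r + 1e-9
        )
        near_judge = judge_r > 0 and judge_transitions.size and (
            np.min(np.abs(judge_transitions - case.t)) <= judge_r + 1e-9
        )
        if not near_ts and not near_judge:
            out.append(case)
    return out


def accuracy(cases: Sequence[TestCase]) -> float:
    if not cases:
        raise ValueError("no valid test cases")
    return float(np.mean([c.predicted == c.truth for c in cases]))


def agreement_table(
    cases: Sequence[TestCase],
    ts_series: StepSeries,
    judge_series: StepSeries,
    ts_grid: Sequence[float],
    judge_grid: Sequence[float],
) -> list[dict]:
    """Accuracy-vs-exclusion grid.

    One row per (ts_ms, judge_ms) pair with the surviving case count and
    the correct/valid fraction.
    """
    if not len(ts_grid) or not len(judge_grid):
        raise ValueError("grids must be nonempty")
    ts_tr = ts_series.change_points
    judge_tr = judge_series.change_points
    rows = []
    for ts_ms in ts_grid:
        for judge_ms in judge_grid:
            kept = apply_exclusions(cases, ts_tr, judge_tr, ts_ms, judge_ms)
            rows.append(
                {
                    "ts_ms": float(ts_ms),
                    "judge_ms": float(judge_ms),
                    "n_cases": len(kept),
                    "accuracy": accuracy(kept) if kept else float("nan"),
                }
            )
    return rows
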