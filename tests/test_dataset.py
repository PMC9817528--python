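import numpy as np
import pytest

import equigait as eg
from equigait.dataset import MissingChannelError
from equigait.gaits import DISCARDED, VocabularyError
from equigait.sensor_io import InsufficientDataError

from conftest import flat_trace


class TestLabelMap:
    @pytest.mark.parametrize(
        "ts,expected",
        [
            ("Walk", eg.Gait.WALK),
            ("Trot", eg.Gait.TROT),
            ("Tölt", eg.Gait.TOLT),
            ("L Canter", eg.Gait.CANTER),
            ("R Canter", eg.Gait.CANTER),
            ("L Cross Canter", eg.Gait.CANTER),
            ("R Cross Canter", eg.Gait.CANTER),
            ("Flying Pace", eg.Gait.FLYING_PACE),
            ("Standing", DISCARDED),
        ],
    )
    def test_mapping(self, ts, expected):
        assert eg.map_ts_label(ts) == expected

    def test_unknown_rejected(self):
        with pytest.raises(VocabularyError):
            eg.map_ts_label("Gallop")


class TestBuildTimeline:
    def test_run_length_merge(self):
        events = [
            eg.LabelEvent(0.0, "Walk"),
            eg.LabelEvent(0.2, "Walk"),
            eg.LabelEvent(0.4, "Tölt"),
        ]
        tl = eg.build_timeline(events)
        assert np.allclose(tl.breakpoints, [0.0, 0.4])
        assert tl.labels == [eg.Gait.WALK, eg.Gait.TOLT]
        assert tl.label_at(0.39) == eg.Gait.WALK
        assert tl.label_at(0.4) == eg.Gait.TOLT

    def test_single_event_unbounded(self):
        tl = eg.build_timeline([eg.LabelEvent(1.0, "Trot")])
        assert tl.label_at(100.0) == eg.Gait.TROT
        assert tl.label_at(0.5) is None

    def test_alternating_labels_count(self):
        events = [
            eg.LabelEvent(0.25 * i, "Walk" if i % 2 == 0 else "Tölt")
            for i in range(8)
        ]
        tl = eg.build_timeline(events)
        assert len(tl.labels) == 8

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            eg.build_timeline([])


def brute_force_starts(trace, tl, window, step_samples, exclusion):
    """Independent enumeration of valid segment starts."""
    rate = trace.rate
    n_win = int(round(window * rate))
    keeps = []
    for i in range(0, len(trace) - n_win + 1):
        s = float(trace.t[i])
        e = s + window
        labs = {tl.label_at(float(trace.t[j])) for j in range(i, i + n_win)}
        if len(labs) != 1:
            continue
        lab = labs.pop()
        if lab is None or lab == DISCARDED:
            continue
        if any(s - exclusion < sw < e + exclusion for sw in tl.switch_times):
            continue
        keeps.append((i, s, lab))
    return keeps


class TestGenerateSegments:
    def test_single_gait_57_segments(self):
        trace = flat_trace(10.0, 100.0)
        tl = eg.LabeledTimeline([0.0], [eg.Gait.WALK])
        segs = eg.generate_segments(trace, tl, 1.5, overlap=0.9, exclusion=2.0)
        starts = [s.t_start for s in segs]
        assert len(segs) == 57
        assert starts[0] == pytest.approx(0.0)
        assert starts[1] == pytest.approx(0.15)
        assert starts[-1] == pytest.approx(8.40)

    def test_switch_with_exclusion_42_segments(self):
        trace = flat_trace(10.0, 50.0)
        tl = eg.LabeledTimeline([0.0, 5.0], [eg.Gait.WALK, eg.Gait.TROT])
        segs = eg.generate_segments(trace, tl, 1.0, overlap=0.9, exclusion=2.0)
        starts = np.array([s.t_start for s in segs])
        assert len(segs) == 42
        assert (starts <= 2.0).sum() == 21
        assert (starts >= 7.0).sum() == 21

    def test_window_longer_than_trace(self):
        trace = flat_trace(1.0, 50.0)
        tl = eg.LabeledTimeline([0.0], [eg.Gait.WALK])
        assert eg.generate_segments(trace, tl, 1.5) == []

    def test_flying_pace_dense_stepping(self):
        trace = flat_trace(10.0, 50.0)
        tl = eg.LabeledTimeline([0.0], [eg.Gait.FLYING_PACE])
        segs = eg.generate_segments(trace, tl, 1.5, overlap=0.9, exclusion=2.0)
        steps = np.diff([s.t_start for s in segs])
        assert np.allclose(steps, 0.020, atol=1e-9)

    def test_discarded_intervals_yield_nothing(self):
        trace = flat_trace(10.0, 50.0)
        tl = eg.LabeledTimeline([0.0], [DISCARDED])
        assert eg.generate_segments(trace, tl, 1.0) == []

    def test_no_segment_straddles_a_switch(self):
        rng = np.random.default_rng(5)
        trace = flat_trace(30.0, 50.0)
        bps = np.sort(rng.uniform(0.0, 30.0, 5))
        bps[0] = 0.0
        gaits = [eg.Gait(int(g)) for g in rng.integers(0, 5, 5)]
        labels, keep_bp = [], []
        for b, g in zip(bps, gaits):
            if not labels or labels[-1] != g:
                labels.append(g)
                keep_bp.append(b)
        tl = eg.LabeledTimeline(np.array(keep_bp), labels)
        segs = eg.generate_segments(trace, tl, 1.0, overlap=0.9, exclusion=0.5)
        for s in segs:
            inside = trace.t[(trace.t >= s.t_start) & (trace.t < s.t_start + 1.0)]
            assert {tl.label_at(float(x)) for x in inside} == {s.y}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_brute_force(self, seed):
        """Segment counts agree with an independent enumerator that
        walks the same start grid."""
        rng = np.random.default_rng(seed)
        trace = flat_trace(20.0, 50.0)
        n_iv = rng.integers(2, 5)
        bps = np.concatenate([[0.0], np.sort(rng.uniform(1.0, 19.0, n_iv - 1))])
        gaits = []
        for _ in range(n_iv):
            g = eg.Gait(int(rng.integers(0, 4)))  # no flying pace: single grid
            while gaits and gaits[-1] == g:
                g = eg.Gait(int(rng.integers(0, 4)))
            gaits.append(g)
        tl = eg.LabeledTimeline(bps, gaits)
        window, exclusion = 1.0, 1.0
        segs = eg.generate_segments(trace, tl, window, overlap=0.9, exclusion=exclusion)
        brute = brute_force_starts(trace, tl, window, 5, exclusion)
        brute_on_grid = [b for b in brute if b[0] % 5 == 0]
        assert len(segs) == len(brute_on_grid)
        assert np.allclose(
            [s.t_start for s in segs], [b[1] for b in brute_on_grid]
        )

    def test_consecutive_starts_step_tenth_of_window(self):
        trace = flat_trace(10.0, 100.0)
        tl = eg.LabeledTimeline([0.0], [eg.Gait.TROT])
        segs = eg.generate_segments(trace, tl, 2.0, overlap=0.9)
        steps = np.diff([s.t_start for s in segs])
        assert np.allclose(steps, 0.2, atol=1.0 / trace.rate)


class TestFeatureChannels:
    @pytest.mark.parametrize(
        "use,ni",
        [({"accel"}, 3), ({"accel", "gyro"}, 6), ({"accel", "gyro", "speed"}, 7)],
    )
    def test_channel_counts(self, quiet_ride, use, ni):
        out = eg.build_feature_channels(
            quiet_ride.horse_truth, quiet_ride.gps, use
        )
        assert len(out.channel_names) == ni

    def test_speed_without_gps_rejected(self, quiet_ride):
        with pytest.raises(MissingChannelError):
            eg.build_feature_channels(quiet_ride.horse_truth, None, {"speed"})

    def test_speed_held_between_fixes(self, quiet_ride):
        out = eg.build_feature_channels(
            quiet_ride.horse_truth, quiet_ride.gps, {"accel", "speed"}
        )
        speeds = {f.speed for f in quiet_ride.gps}
        assert set(np.unique(out.channels["speed"])) <= speeds


class TestSplitDataset:
    def _segments(self, n=1000, horses=range(3, 8)):
        rng = np.random.default_rng(0)
        segs = []
        for i in range(n):
            segs.append(
                eg.Segment(
                    x=np.zeros((1, 2)),
                    y=eg.Gait.WALK,
                    horse_id=int(rng.choice(list(horses))),
                    rider_id=0,
                    ride_id=i,
                    t_start=0.0,
                )
            )
        return segs

    def test_85_15_arithmetic(self):
        segs = self._segments()
        with pytest.warns(UserWarning):  # listed test horses absent
            split = eg.split_dataset(segs, eg.SplitSpec(shuffle_seed=1))
        assert len(split["train"]) == 850
        assert len(split["val"]) == 150
        assert split["test"] == []

    def test_default_test_horses(self):
        segs = self._segments(horses=range(1, 18))
        split = eg.split_dataset(segs, eg.SplitSpec(shuffle_seed=1))
        assert {s.horse_id for s in split["test"]} == {1, 2, 8, 9, 11}
        assert not ({1, 2, 8, 9, 11} & {s.horse_id for s in split["train"]})

    def test_same_seed_same_split(self):
        segs = self._segments(horses=range(1, 18))
        a = eg.split_dataset(segs, eg.SplitSpec(shuffle_seed=7))
        b = eg.split_dataset(segs, eg.SplitSpec(shuffle_seed=7))
        assert [s.ride_id for s in a["train"]] == [s.ride_id for s in b["train"]]
        assert [s.ride_id for s in a["val"]] == [s.ride_id for s in b["val"]]
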