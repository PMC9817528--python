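import numpy as np
import pytest

import equigait as eg
from equigait.simulate import LIMBS, _hann_bumps


class TestProfiles:
    def test_beat_counts(self):
        profiles = eg.default_profiles()
        beats = {g: p.n_beats for g, p in profiles.items()}
        assert beats[eg.Gait.WALK] == 4
        assert beats[eg.Gait.TOLT] == 4
        assert beats[eg.Gait.TROT] == 2
        assert beats[eg.Gait.FLYING_PACE] == 2
        assert beats[eg.Gait.CANTER] == 3

    def test_tolt_reaches_two_and_a_half_strides_per_second(self):
        assert eg.default_profiles()[eg.Gait.TOLT].stride_freq[1] == 2.5

    def test_profiles_pairwise_distinguishable(self):
        """Beat count, phase pattern, limb pairing, cadence and duty jointly
        separate the five gaits (walk and tölt share the four-beat lateral
        sequence and differ in cadence and duty)."""
        profiles = eg.default_profiles()
        signatures = set()
        for p in profiles.values():
            pairs = tuple(
                sorted(
                    tuple(sorted(l for l, ph in zip(LIMBS, p.footfall_phases) if ph == u))
                    for u in set(p.footfall_phases)
                )
            )
            signatures.add(
                (
                    p.n_beats,
                    tuple(sorted(p.footfall_phases)),
                    pairs,
                    p.suspension,
                    p.duty,
                    p.stride_freq,
                )
            )
        assert len(signatures) == 5


class TestFootfallSchedule:
    def test_walk_two_seconds_eight_hoof_ons(self):
        prof = eg.default_profiles()[eg.Gait.WALK]
        sched = eg.footfall_schedule(prof, 2.0, 1.0)
        n_on = sum(len(v) for v in sched.values())
        assert n_on == 8

    def test_trot_diagonal_pairs_simultaneous(self):
        prof = eg.default_profiles()[eg.Gait.TROT]
        sched = eg.footfall_schedule(prof, 3.0, 1.5)
        lh = [on for on, _ in sched["LH"]]
        rf = [on for on, _ in sched["RF"]]
        assert np.allclose(lh, rf)

    def test_fast_tolt_ten_events_per_second(self):
        prof = eg.default_profiles()[eg.Gait.TOLT]
        sched = eg.footfall_schedule(prof, 10.0, 2.5)
        n_on = sum(len(v) for v in sched.values())
        assert n_on / 10.0 == pytest.approx(10.0, rel=0.05)

    def test_events_within_duration(self):
        prof = eg.default_profiles()[eg.Gait.CANTER]
        sched = eg.footfall_schedule(prof, 5.0, 1.7)
        for events in sched.values():
            for on, off in events:
                assert 0.0 <= on <= 5.0
                assert on < off <= 5.0 + prof.duty / 1.7


class TestSynthImu:
    def test_identity_orientation_heading_zero_equals_truth(self):
        plan = eg.RidePlan(
            bouts=[eg.Bout(eg.Gait.TROT, 5.0, heading0=0.0)],
            device_quaternion=np.array([1.0, 0, 0, 0]),
            noise_accel=0.0,
            noise_gyro=0.0,
            seed=0,
        )
        dev, truth, _, _ = eg.synth_imu(plan)
        # heading 0: world x=east=-left, y=north=front; device=world here.
        assert np.allclose(dev.channels["az"], truth.channels["az"], atol=1e-12)
        assert np.allclose(dev.channels["ay"], truth.channels["ax"], atol=1e-12)
        assert np.allclose(dev.channels["ax"], -truth.channels["ay"], atol=1e-12)

    @pytest.mark.parametrize(
        "gait,freq",
        [
            (eg.Gait.WALK, 1.0),
            (eg.Gait.TOLT, 2.0),
            (eg.Gait.TROT, 1.5),
            (eg.Gait.FLYING_PACE, 2.0),
            (eg.Gait.CANTER, 1.6),
        ],
    )
    def test_vertical_spectral_peak_at_beat_frequency(self, gait, freq):
        plan = eg.RidePlan(
            bouts=[eg.Bout(gait, 20.0, stride_freq=freq)],
            noise_accel=0.0,
            noise_gyro=0.0,
            seed=1,
        )
        _, truth, _, _ = eg.synth_imu(plan)
        z = truth.channels["az"] - truth.channels["az"].mean()
        freqs = np.fft.rfftfreq(len(z), 1.0 / plan.rate)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(z)))]
        expected = freq * eg.default_profiles()[gait].n_beats
        assert abs(peak - expected) <= freqs[1] + 1e-9

    def test_fixed_seed_identical_traces(self):
        plan = eg.RidePlan(bouts=[eg.Bout(eg.Gait.WALK, 5.0)], seed=7)
        a = eg.synth_imu(plan)[0]
        b = eg.synth_imu(plan)[0]
        for name in a.channel_names:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_pace_has_stronger_lateral_signal_than_trot(self):
        """Lateral limb pairs reinforce side-to-side sway; diagonal pairs
        cancel it."""
        def lateral_power(gait):
            plan = eg.RidePlan(
                bouts=[eg.Bout(gait, 10.0)], noise_accel=0.0, noise_gyro=0.0, seed=2
            )
            _, truth, _, _ = eg.synth_imu(plan)
            return np.var(truth.channels["ay"])

        assert lateral_power(eg.Gait.FLYING_PACE) > 5 * lateral_power(eg.Gait.TROT)


class TestSynthGps:
    def test_straight_north_bearings(self):
        plan = eg.RidePlan(bouts=[eg.Bout(eg.Gait.WALK, 10.0, heading0=0.0)], seed=0)
        fixes = eg.synth_gps(plan)
        for a, b in zip(fixes[:-1], fixes[1:]):
            theta = eg.gps_bearing(a, b)
            assert min(theta, 360 - theta) < 1.0

    def test_turning_ride_sweeps_heading(self):
        plan = eg.RidePlan(
            bouts=[eg.Bout(eg.Gait.CANTER, 36.0, heading0=0.0, turn_rate=10.0)],
            seed=0,
        )
        fixes = eg.synth_gps(plan)
        bearings = [eg.gps_bearing(a, b) for a, b in zip(fixes[:-1], fixes[1:])]
        # one full lap: bearings cover all quadrants
        quadrants = {int(b // 90) for b in bearings}
        assert quadrants == {0, 1, 2, 3}

    def test_fix_spacing_matches_speed(self):
        plan = eg.RidePlan(
            bouts=[eg.Bout(eg.Gait.WALK, 10.0, speed=4.0, heading0=30.0)], seed=0
        )
        fixes = eg.synth_gps(plan)
        for a, b in zip(fixes[:-1], fixes[1:]):
            # haversine distance
            lat1, lat2 = np.deg2rad(a.lat), np.deg2rad(b.lat)
            dlat = lat2 - lat1
            dlon = np.deg2rad(b.lon - a.lon)
            h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
            d = 2 * 6371000.0 * np.arcsin(np.sqrt(h))
            assert d == pytest.approx(4.0, rel=0.01)


class TestSimulateRide:
    def test_walk_only_plan_all_walk_events(self):
        plan = eg.RidePlan(bouts=[eg.Bout(eg.Gait.WALK, 5.0)], seed=0)
        bundle = eg.simulate_ride(plan)
        assert {e.ts_label for e in bundle.label_events} == {"Walk"}

    def test_bundle_write_round_trips(self, tmp_path, quiet_ride):
        paths = quiet_ride.write(tmp_path)
        trace, gps = eg.read_sensor_log(paths["imu"])
        events = eg.read_label_log(paths["labels"])
        assert len(trace) == len(quiet_ride.device_trace)
        assert len(gps) == len(quiet_ride.gps)
        assert len(events) == len(quiet_ride.label_events)

    def test_corpus17_structure(self):
        bundles = eg.corpus17(seed=1)
        assert len(bundles) == 17
        horses = {b.plan.horse_id for b in bundles}
        assert horses == set(range(1, 18))
        pace_only = [b for b in bundles if b.plan.horse_id in (10, 11)]
        for b in pace_only:
            assert all(bout.gait == eg.Gait.FLYING_PACE for bout in b.plan.bouts)
        riders = {b.plan.rider_id for b in bundles}
        assert len(riders) == 14

    def test_hann_bump_unit_peak(self):
        t = np.arange(0, 1, 0.001)
        out = _hann_bumps(t, np.array([0.2]), 0.1)
        assert out.max() == pytest.approx(1.0, abs=1e-3)
        assert np.all(out[t < 0.2] == 0)
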