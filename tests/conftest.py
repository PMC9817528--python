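import numpy as np
import pytest

import equigait as eg


@pytest.fixture(scope="session")
def quiet_ride():
    """A short noise-free single-gait ride used across modules."""
    plan = eg.RidePlan(
        bouts=[eg.Bout(eg.Gait.TOLT, 10.0, heading0=45.0, turn_rate=5.0)],
        noise_accel=0.0,
        noise_gyro=0.0,
        seed=3,
    )
    return eg.simulate_ride(plan)


@pytest.fixture(scope="session")
def multi_bout_ride():
    """A three-gait ride with default sensor noise."""
    plan = eg.RidePlan(
        bouts=[
            eg.Bout(eg.Gait.WALK, 12.0, heading0=0.0, turn_rate=3.0),
            eg.Bout(eg.Gait.TOLT, 12.0, heading0=36.0, turn_rate=-4.0),
            eg.Bout(eg.Gait.TROT, 12.0, heading0=300.0, turn_rate=6.0),
        ],
        seed=7,
    )
    return eg.simulate_ride(plan)


def flat_trace(duration=10.0, rate=100.0, channels=("ax",)):
    t = np.arange(0.0, duration + 1e-9, 1.0 / rate)
    return eg.SensorTrace(
        t=t,
        channels={c: np.zeros_like(t) for c in channels},
        rate=rate,
        frame="horse",
    )
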