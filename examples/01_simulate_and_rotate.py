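"""Simulate a ride and rotate it between frames of reference.

Builds a noise-free tölt ride with a turning heading, rotates the
device-frame trace to the world frame via the stored orientation
quaternion and onward to the horse frame via the true heading, and
compares against the simulator's horse-frame ground truth.
"""

import numpy as np

import equigait as eg

plan = eg.RidePlan(
    bouts=[eg.Bout(eg.Gait.TOLT, 20.0, heading0=45.0, turn_rate=6.0, stride_freq=2.0)],
    noise_accel=0.0,
    noise_gyro=0.0,
    seed=3,
)
bundle = eg.simulate_ride(plan)

world = eg.device_to_world(bundle.device_trace)
horse = eg.world_to_horse(world, bundle.heading)

print("channel   round-trip RMSE (m/s^2 or deg/s)")
for name in horse.channel_names:
    err = horse.channels[name] - bundle.horse_truth.channels[name]
    print(f"  {name}      {np.sqrt(np.mean(err**2)):.2e}")

z = horse.channels["az"] - horse.channels["az"].mean()
freqs = np.fft.rfftfreq(len(z), 1.0 / plan.rate)
peak = freqs[np.argmax(np.abs(np.fft.rfft(z)))]
print(f"\nvertical-channel spectral peak: {peak:.2f} Hz")
print("= stride frequency (2.0/s) x 4 beats of the tolt:")
print("the rotation chain recovers the gait-periodic structure exactly.")
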