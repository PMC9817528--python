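# equigait

Five-gait classification for Icelandic horses from a smartphone in the
rider's pocket.

Icelandic horses perform two gaits beyond walk, trot and canter: the
four-beat ambling **tölt** and the two-beat lateral **flying pace**.
Recognising all five from wearable sensors normally requires limb-mounted
hardware; this package implements the full pipeline for doing it with
nothing but the phone's accelerometer, gyroscope, orientation quaternion
and 1 Hz GPS, labelled by a limb-sensor system that emits a gait label at
every hoof-on. It is aimed at equine-biomechanics and activity-recognition
researchers who want a complete, testable reference implementation —
including a ride simulator, so every stage runs without any real
recordings.

## The pipeline

1. **Frames** (`equigait.frames`) — device-frame signals are rotated to the
   world frame (x east, y north, z up) with the phone's Hamilton
   scalar-first quaternion `q` (`v' = q v q*`), then into the horse's frame
   (x front–back, y left–right, z vertical) by a yaw rotation through the
   heading θ ∈ [0°, 360°), derived from consecutive GPS fixes via
   `θ = atan2(cos(lat)·Δlon, Δlat)` and circularly smoothed over 1 s
   (unwrap → moving average → wrap).
2. **Dataset** (`equigait.dataset`) — label events become a
   piecewise-constant timeline; 1.5 s windows with 90% overlap are cut at
   50 Hz, discarding anything within 2 s of a gait switch (flying-pace
   regions are stepped every 20 ms to counter class imbalance); splits are
   made at the horse level.
3. **Models** (`equigait.models`) — four sequence classifiers over the
   `ni × T` channel windows (`ni ∈ {3, 6, 7}`): LSTM (200 units), Bi-LSTM
   (400), GRU (200), and a four-layer dilated 1-D CNN (kernel 3, dilations
   12/8/4/1, channels `ni`→16→32→64→128), each topped by a 128-unit linear
   layer and a 5-class softmax. Training: Adam, cross-entropy, batch 64,
   ≤ 20 epochs, early stopping on validation loss. The networks and their
   backprop are implemented in numpy inside the package (`equigait._nn`).
4. **Smoothing** (`equigait.smoothing`) — the sequential probability
   stream h_t is refined by exponential weight decay,
   `z_0 = h_0, z_t = (z_{t−1} + h_t)/2`, hardened by `g_t = argmax z_t`,
   and cleaned by a centred width-7 majority vote with ties going to g_t.
5. **Metrics** (`equigait.metrics`) — micro accuracy (confusion-matrix
   trace over total), per-gait one-vs-all accuracy, macro averages over
   *present* gaits only, and leave-one-horse-out cross-validation.
6. **Agreement** (`equigait.agreement`) — the labelling system itself is
   validated against a four-judge panel: judge clicks aggregated every
   250 ms by strict plurality (ties → "no majority"), the label-event log
   summarised on a 1 s/0.5 s sliding window, prediction–truth test cases
   paired, and agreement tabulated against transition-exclusion radii.
7. **Simulator** (`equigait.simulate`) — per-gait footfall schedules
   (four-beat walk/tölt, diagonal-pair trot, lateral-pair pace, three-beat
   canter) drive a horse-frame impulse signal model that is rotated through
   heading and a random device orientation, with GPS tracks, label events
   and lagging judge streams to match.

## Worked example

`python examples/02_segment_and_train.py` simulates three horses riding
walk/tölt/trot, rotates everything to the horse frame, cuts segments and
trains a small CNN, holding out horse 3 entirely:

```
408 training segments, 204 held-out segments (horse 3)
trained 8 epochs, final train loss 0.0001
held-out micro accuracy on the unseen horse: 1.000
(each segment is a 6 x 75 window: 3 accel + 3 gyro channels at 50 Hz)
```

The held-out accuracy is computed on a horse the model never saw, the
measure that matters for generalisation across animals.
`python examples/04_judge_agreement.py` prints the agreement table of the
labeller against a lagging judge panel:

```
TS excl (ms)  judge excl (ms)  cases  agreement
         0               0    248  98.39%
      1000            1000    222  100.00%
      2000            2000    204  100.00%
```

Disagreements concentrate at gait transitions (judge reaction lag), so
excluding a neighbourhood of each transition raises agreement — the same
shape the protocol produces on real rides. The other examples cover frame
rotation (`01`), probability smoothing (`03`) and leave-one-horse-out
cross-validation (`05`).

There is also a thin CLI: `equigait sim | prep | train | eval | cv | agree`
(see `equigait --help`).

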