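# Methods

## Problem and model

The package classifies the five gaits of the Icelandic horse — walk, trot,
tölt, canter, flying pace — from inertial signals recorded by a phone in
the rider's pocket. The classifier sees short fixed-duration windows of
the 50 Hz accelerometer and gyroscope signal in a chosen frame of
reference and outputs a probability vector over the five gaits; temporal
post-processing then exploits the fact that gaits persist for seconds, not
tens of milliseconds.

### Frames of reference

Pocket orientation is arbitrary, so raw device axes are uninformative
across rides. Two rotations fix this:

* **world frame** — rotate each sample by the phone's orientation
  quaternion (Hamilton convention, scalar first, device→world). Axes:
  x east, y north, z up. This isolates vertical motion on z but leaves
  the horizontal axes tied to geography, not to the horse.
* **horse frame** — additionally yaw-rotate the horizontal components
  through the travel heading so x is front–back and y left–right. Heading
  comes from consecutive 1 Hz GPS fixes using a local equirectangular
  bearing, is unwrapped (an element differing from its corrected
  predecessor by more than 180° is shifted by the appropriate multiple of
  360°), averaged over a centred 1 s window, and wrapped back to [0°, 360°).
  Between fixes the heading is held constant (zero-order hold); the 1 s
  smoothing makes finer interpolation immaterial at riding turn rates.

Both the quaternion and the GPS bearing are referenced to geographic
north here; a real phone's quaternion may be anchored to magnetic north,
which would offset headings by the local declination. Since the horse
frame only needs a *consistent* horizontal reference, a constant offset
is harmless for classification.

Angular velocity is rotated with the same rotations as acceleration —
it transforms as a vector under rotation. Gravity is not removed; the
constant 9.81 m/s² on the vertical axis is information the per-channel
standardisation absorbs.

### Segmentation

Label events arrive at 4–10 Hz (one per hoof-on). They define a
piecewise-constant label timeline; runs of equal mapped labels merge, and
the stationary label maps to "discarded". Windows of length `window`
(default 1.5 s) advance by `(1 − overlap)·window` (default 10% of the
window), snapped to whole samples; inside flying-pace intervals the step
is 20 ms regardless of window length, densifying the rarest class. A
window is kept only if it lies wholly inside one labelled interval and no
label switch falls strictly within ±2 s of any part of it — transitions
carry unreliable labels on both sides. Exclusion boundaries are open: a
window whose edge sits exactly at the radius is kept, which makes the
counting arithmetic exact on grid-aligned fixtures.

### Classifiers

Four architectures, all mapping an `ni × T` window to 5 logits through a
shared head (128-unit linear layer, ReLU, 5-way softmax):

| arch | body | feature fed to head |
|---|---|---|
| `lstm` | 1 LSTM layer, 200 units | last hidden state |
| `bilstm` | 2 LSTM directions, 200 each (400 total) | concatenated final states |
| `gru` | 1 GRU layer, 200 units | last hidden state |
| `cnn1d` | 4 dilated convs, kernel 3, dilations 12/8/4/1, channels ni→16→32→64→128 | global average over time |

Design points the architecture descriptions leave open, decided here:
the Bi-LSTM's "400 units" is read as 200 per direction, keeping parameter
parity with the LSTM; recurrent bodies feed the head their final time-step
state; the CNN feeds a global average; inputs are z-scored per channel
with training-set statistics, since m/s² and deg/s scales differ by an
order of magnitude and fixed-scale inputs would otherwise dominate the
gradients.

Training: Adam (step size 1e-3, default moments), cross-entropy, batch
size 64, at most 20 epochs, early stopping monitoring validation loss
with patience 3 and best-checkpoint restore. A "small" profile (64 units
per direction, 10 epochs) exists for desk-scale runs; the default profile
matches the full-size architectures.

The networks, their backprop-through-time and Adam are implemented in
numpy inside the package (`equigait._nn`), in float32 with seeded
initialisation, so a fixed seed reproduces weights bitwise. Gradients are
verified against central finite differences in the test suite.

### Temporal smoothing

Sequential per-window probabilities h_t are refined by

    z_0 = h_0,   z_t = (z_{t−1} + h_t) / 2,

equivalently an exponentially decaying convex combination with weights
(1/2, 1/4, …) over the past — so z stays on the simplex. Hard labels
g_t = argmax z_t (ties to the lowest gait code) then pass through a
centred width-7 majority vote; ties keep g_t, and windows truncate at the
sequence edges rather than inventing padding labels. The vote uses future
windows, so it is an offline smoother.

### Metrics

Micro accuracy is the confusion-matrix trace over its total. Per-gait
accuracy is one-vs-all: the gait against everything else, counting true
negatives. Macro averages are unweighted means **over present entries
only** — a horse that contributed zero seconds of a gait is excluded from
that gait's macro column even if an accuracy number is formally
computable from false positives. This exclusion is what makes the
published per-horse table's trot macro come out at 0.82 rather than the
naive all-rows mean of 0.76.

Leave-one-horse-out cross-validation trains one model per held-out horse
per repeat (fresh seeds `seed, seed+1, …`), pools the repeats' confusion
matrices per horse, and reports per-horse micro and one-vs-all values,
per-gait macro columns, and their mean.

### Judge-agreement protocol

The labelling system is validated against a panel of four judges who
click gait labels while watching ride video, each click holding until the
next. Every 250 ms the judges' held labels are polled; a strict plurality
wins and any tie yields "no majority" (−2) — a tie *is* the absence of a
majority. The labeller's event log is summarised by a 1 s sliding window
with a 0.5 s step centred on each output instant, taking the modal event
label (ties resolved toward the most recent tied event), with the first
event's timestamp subtracted so the series starts at 0 s. Each labeller
timeline point inside the judges' observation window becomes a test case
against the aggregated label at that instant; −2/−1 truths are dropped.
Exclusion radii around the change points of either series then remove
cases where transition-timing leeway is warranted, and agreement is
tabulated over a radius grid. Halt remains a class here, and left/right
canter stay distinct — the agreement vocabulary is deliberately finer
than the five training classes.

## The simulator

No public recordings exist for this task, so the package ships a
generative stand-in. Per gait, a footfall template gives each limb's
hoof-on phase in the stride cycle:

| gait | beats | phases (LH, LF, RH, RF) | duty | stride/s | suspension |
|---|---|---|---|---|---|
| walk | 4 | 0, .25, .5, .75 | 0.60 | 0.8–1.1 | no |
| tölt | 4 | 0, .25, .5, .75 | 0.45 | 1.8–2.5 | no |
| trot | 2 | 0, .5, .5, 0 (diagonal pairs) | 0.40 | 1.3–1.6 | yes |
| canter | 3 | 0, .3, .3, .6 (left lead) | 0.40 | 1.5–1.9 | yes |
| flying pace | 2 | 0, 0, .5, .5 (lateral pairs) | 0.35 | 1.8–2.2 | yes |

Each hoof-on contributes a raised-cosine acceleration bump in the horse
frame — vertical (positive), lateral (signed by limb side; right-lead
canter flips the signs), longitudinal (hind positive, front negative) —
on top of 9.81 m/s² of gravity; the trunk adds roll/pitch gyro sinusoids
at the stride and beat frequencies, and yaw follows the negated turn
rate. Bump width is half the beat interval (capped at 0.12 s), which
keeps the vertical channel's dominant spectral line at the beat frequency
(stride frequency × beat count) — the feature hierarchy a classifier
exploits: beat rate, beat count, lateral symmetry (diagonal pairs cancel
laterally, lateral pairs reinforce), and amplitude.

The horse-frame truth is rotated through the heading profile into the
world frame and through the inverse of a per-ride random orientation
quaternion into the device frame; Gaussian noise (0.3 m/s², 2 deg/s by
default) is added device-side only. GPS fixes integrate the
heading/speed profile and are converted with the same equirectangular
model the bearing computation inverts, so bearings recover headings to
well under 1° on straight bouts. Label events fire at every hoof-on with
the bout's label (canter bouts alternate left/right lead); judge streams
react to each true transition with a seeded 0.2–0.6 s lag, optionally
with one judge clicking a wrong label briefly after each transition to
create disputed ticks.

**What the simulator does not model:** soft-tissue and clothing dynamics
between horse and pocket, rider technique (sitting/rising/two-point),
terrain, sensor bias/drift, timestamp jitter, and "between-gait"
movements such as pacey tölt. Synthetic gaits are therefore *more*
separable than real ones: passing recovery tests demonstrates that the
pipeline is correct and information-preserving, not that real-world
accuracy will match.

### The synthetic corpus

`corpus17` emulates the study corpus's shape: 17 horses, 14 riders, each
horse's per-gait bout durations proportional to its published gait-second
mix (two horses ride flying pace only; one horse has no trot), with
random headings and turn rates of ±12 deg/s so world-frame horizontal
axes decorrelate from the horse's axes. Durations are scaled by 0.04
(floored at 8 s per bout, the minimum that yields any segment at window
1.5 s and exclusion 2 s) so the corpus simulates, segments and trains in
minutes on one CPU; the scale is a package choice to keep the
demonstration desk-sized, and it is exposed as a parameter.

## Numerical choices and edge cases

* Non-unit quaternions are rejected (not silently normalised); tolerance
  1e-6 on the norm.
* Resampling is plain per-channel linear interpolation without an
  anti-aliasing filter — downsampling from phone rates to 50 Hz has
  little effect on gait content, and linearity makes the operation
  exactly testable (lines resample exactly; it is idempotent).
  Quaternions are carried by nearest-previous sample, since linear
  interpolation would denormalise them.
* Zero GPS displacement leaves heading undefined; the previous heading is
  held, and a ride with no displacement at all is an error.
* Argmax ties break toward the lowest gait code; majority-vote ties keep
  the centre label; timeline lookups at exact breakpoints take the new
  interval.
* Segment step rounding adds a 1e-6 s guard before rounding to whole
  samples so that proportional steps landing exactly on half-samples
  (e.g. 7.5 samples at 50 Hz) round up deterministically instead of
  depending on float representation error.
* The 85/15 train/validation split is per-segment, not per-ride, and
  unstratified; with 90% overlap this leaks correlated windows between
  train and validation. It is kept deliberately as the protocol's known
  optimistic-validation property; the *test* split is always by horse.
* All randomness flows through seeded numpy Generators; `loho_cv`
  repeats use consecutive seeds and pool confusion matrices before
  computing accuracies.

## Known limitations

* World-frame orientation from the phone is taken as given; no
  sensor-fusion fallback exists when the quaternion is absent.
* The agreement module polls judges' held labels at tick instants rather
  than integrating click durations within the tick; with 250 ms ticks and
  sub-second reaction lags the difference is one tick at most.
* Real-data headline accuracies are not reproducible here — the synthetic
  corpus shows parameter recovery and the horse-frame advantage
  directionally, at desk scale.
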