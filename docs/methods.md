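# Methods

## The estimation and classification pipeline

`imuquat` implements per-sample behavior classification for a
torso-mounted 6-axis IMU (triaxial accelerometer in g, triaxial
gyroscope in rad/s). The pipeline has three stages:

1. **Orientation estimation** (`orientation.py`). At the start of a
   recording bout, assumed taken at rest, the accelerometer reads
   gravity. The inclination of the sensor's up-axis is
   `θ(0) = arccos(acc_z(0) / ‖acc(0)‖)` (the reading is unit-normalized
   and the ratio clamped to [−1, 1] to absorb noise), the horizontal
   rotation axis is `V(0) = (−acc_y(0), acc_x(0), 0)`, and the initial
   unit quaternion is `q(0) = [cos(θ/2), sin(θ/2)·V/‖V‖]` — the
   twist-free rotation taking the vertical onto the measured gravity
   direction. Each subsequent sample advances the orientation by a
   first-order step: the measured body rate is conjugated into the
   reference frame, `Ω(t) = q(t−1) ⊗ (ω(t)/f) ⊗ q(t−1)^{-1}`, the
   incremental rotation `Φ(t) = [1, Ω(t)/2]` is composed on the left,
   and the product is renormalized (the raw first-order increment is
   non-unit; without renormalization the norm grows monotonically).
   There is no accelerometer or magnetometer feedback after t = 0, so
   gyro noise and bias integrate into drift; the package measures this
   drift on synthetic data rather than correcting it (no complementary
   or Madgwick/Mahony filtering — deliberately out of scope).

2. **Feature views** (`features.py`). Two competing per-sample views:
   `raw6` (the six sensor channels verbatim) and `quat4` (the four
   estimated quaternion components). Both preserve row order, so one
   stratified fold assignment is shared and the comparison is paired.

3. **Classification** (`classifiers.py`, `evaluation.py`). A
   from-scratch Gaussian naive Bayes (class priors from frequencies;
   per-class per-feature means and population variances; variance
   floored at `1e−9 ×` the largest feature variance; log-space
   posteriors; ties to class order) is compared against scikit-learn's
   RBF SVM (`C = 10, gamma = 1`, z-scored on the training folds), KNN
   (`K = round(√n_train)`, z-scored) and a depth-5 decision tree, under
   stratified 10-fold cross-validation scored by per-class
   precision/recall/F with the 0/0 → 0 convention and unweighted macro
   averaging over classes and folds.

### Conventions

Quaternions are scalar-first `(w, x, y, z)` with the Hamilton product
in right-handed frames. The accelerometer at rest reads +1 g along its
up-axis. Gyroscope data are rad/s internally; the CSV reader converts
deg/s on request. The inclination uses `arccos(+acc_z/‖acc‖)`: with
the +1 g up-axis convention this is the sign that makes the rotation
axis formula and the gravity-alignment property
(`q(0)^{-1} ⊗ acc ⊗ q(0) ∝ ẑ`) consistent. Degenerate readings map to
fixed conventions: gravity along +z → identity; along −z → half-turn
about x. The `K = round(√n_train)` neighbor rule replaces the
degenerate "K equal to the training-set size" (which would always
predict the majority class) and is configurable.

## The synthetic benchmark generator

No public dataset accompanies the dog-activity protocol this package
implements, so `simulate.py` is a first-class module that emulates the
acquisition setting: six behavior classes (standing, walking, running,
sitting, lying, resting), 1 Hz sampling, 9,000 samples per class
(54,000 total), organized as one-minute bouts (150 per class).

Each behavior is a posture-plus-gait model producing a ground-truth
orientation trajectory, from which the sensors are synthesized
self-consistently: the gyroscope reads the exact body-frame angular
velocity of the trajectory plus a constant per-bout bias and white
noise; the accelerometer reads gravity rotated into the body frame
(exactly 1 g at rest) plus a body-motion acceleration term, a per-bout
mounting offset, and white sensor noise. The estimator's only error
sources are therefore noise, bias and discretization.

Modeling choices, each an emulation of the physical setting:

* **Postures.** Sitting tilts the chest up by 45° (its behavioral
  definition); resting lies on the left or right side (±90° roll,
  side drawn per bout); lying is prone with a slight nose-down pitch;
  standing is upright; walking and running carry gait-specific
  pitch-and-roll lean of the torso (load shift and harness pull),
  which makes the class signatures oblique in the (pitch, roll) plane
  rather than axis-aligned. A constant mounting tilt (0.30 rad pitch,
  0.20 rad roll) applies to all classes: a harness pocket never sits
  perfectly level on a dog's back. Per-bout posture jitter (Gaussian,
  0.015–0.035 rad) models bout-to-bout variation in pose.
* **Gait.** Each moving class oscillates in pitch/roll/yaw
  (60/25/15% of the peak rate) with a twelve-component broadband
  motion spectrum anchored at the nominal stride rate (0.731 Hz
  standing sway, 1.291 Hz walking, 2.237 Hz running), with random
  phases per bout. Body motion on a harness is broadband — stride
  fundamental, harmonics, head-bob, rattle — and superposing many
  equal-share components approximates a stationary Gaussian process;
  fractional parts of the component frequencies are kept away from
  integer resonance with the 1 Hz sampling, so the aliased samples
  form a near-Gaussian, weakly correlated wobble rather than a
  degenerate few-valued pattern.
* **Bouts start from momentary rest.** The body-motion acceleration
  ramps in over the first 2 s of each bout, so the first accelerometer
  sample reads (near-)pure gravity — the state-of-rest assumption the
  orientation initialization requires. The ground-truth trajectory is
  anchored so its initial orientation is the same twist-free minimal
  rotation the estimator uses (a choice of body frame, not of motion).
* **Noise defaults** (chosen once as plausible for an MPU-6050-class
  consumer IMU on a harness): accelerometer white noise 0.012 g,
  per-bout accelerometer mounting offset 0.01 g, gyro white noise
  0.002 rad/s, per-bout gyro bias 0.0003 rad/s; body-motion
  acceleration 0.004 g (resting) up to 0.45 g (running).

### What the generator does and does not emulate

The generator reproduces the *structure* of the original experiment —
balanced six-class data at 1 Hz with gravity-dominated accelerometry
and gait-dependent angular rates — and is calibrated so the benchmark
is qualitatively meaningful: resting is trivially separable (F = 1 for
every classifier), walking and standing are the hardest classes, the
quaternion view outperforms the raw view for every classifier, and
the Gaussian naive Bayes outscores the tree and KNN on quaternion
features. One caveat is intrinsic to the evaluation protocol: because
folds are drawn per sample, observations from the same bout appear in
both training and test sets, and bout-level structure (posture
jitter, sensor bias, the serial correlation any integrated orientation
estimate carries) slightly favors local learners — on this benchmark
the RBF SVM ends a few tenths of a macro-F point above the naive
Bayes on the quaternion view, and the gap largely disappears under
bout-grouped folds. The generator does **not** model real dog
biomechanics: no breed/body-size effects, no transitions between
behaviors within a bout, no heavy-tailed impact accelerations, and
label noise from video annotation is absent. Passing benchmarks
therefore validate the pipeline's implementation and the direction of
the view comparison under controlled conditions; they are not evidence
about accuracy on real animals.

## Numerical choices and degenerate inputs

* Unit-norm tolerance 1e−6 for inputs to vector rotation; all emitted
  quaternions renormalized to 1e−9.
* Zero angular-rate steps return the previous quaternion bit-exactly
  (no renormalization), making zero motion a true fixed point.
* Geodesic distance uses the absolute inner product, so antipodal
  quaternions (the same rotation) are at distance zero.
* GNB posteriors are computed in log space with `logsumexp`
  normalization; the variance floor prevents infinite densities on
  constant features (e.g. quaternion components of a motionless
  class).
* Stratified folds come from scikit-learn's `StratifiedKFold` with
  shuffling; every randomized component takes an explicit seed, and
  the generator spawns independent per-bout seeds from the master
  seed, so identical configurations are bit-reproducible.
* 0/0 precision/recall/F are defined as 0 with a warning; fold metrics
  are averaged unweighted across folds (macro-of-means equals
  mean-of-macros); pooled-confusion scoring is available behind a
  flag.

## Problem sizes

The default benchmark (54,000 samples, two views, four classifiers,
10-fold CV) runs in a few minutes on one CPU; the dominant cost is the
RBF SVM on the raw view (~2–3 min for its ten folds). Estimator
validation uses 10 s of 100 Hz data per behavior (mean geodesic
tracking error < 0.01 rad noise-free) and one-minute 1 Hz bouts for
drift measurement, where the small-rotation assumption is deliberately
violated and the error is reported, not bounded tightly.

## Known limitations

* Gyro-only integration drifts without bound at low sampling rates;
  the 1 Hz benchmark works because bouts are short (60 s) and
  re-anchor on a fresh gravity reading.
* Heading (yaw twist about gravity) is unobservable from the
  accelerometer; the estimator fixes it by convention at t = 0 and
  tracks changes only through the gyroscope.
* Per-sample cross-validation splits allow samples from the same bout
  to appear in both training and test folds — the same protocol as the
  original experiment, but optimistic relative to leave-one-animal-out
  evaluation.
* The SVM/KNN/DT harnesses use fixed hyperparameters from the
  protocol; `grid_search_svm` exists but is off by default.
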