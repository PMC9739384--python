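# imuquat

Quaternion-based sensor fusion and activity classification for
wearable 6-axis IMUs, built around a canine behavior-recognition
setting: a harness-mounted accelerometer + gyroscope (MPU-6050 class)
samples a dog's torso at 1 Hz, and the task is to classify six
behaviors — standing, walking, running, sitting, lying, resting — from
each per-second sample.

The package's central question: does estimating the body **orientation
quaternion** from the raw streams and classifying on its four
components beat classifying on the six raw sensor channels directly?

## What it does

* **Orientation estimation** from raw accelerometer + gyroscope
  streams. With the sensor at rest, gravity fixes the initial attitude:
  the inclination is θ(0) = arccos(acc_z(0)/‖acc(0)‖), the horizontal
  axis V(0) = (−acc_y(0), acc_x(0), 0), and
  q(0) = [cos(θ(0)/2), sin(θ(0)/2)·V(0)/‖V(0)‖]. Each gyroscope sample
  then advances the attitude by a first-order step:

      Ω(t) = q(t−1) ⊗ (ω(t)/f) ⊗ q(t−1)⁻¹
      Φ(t) = [1, Ω(t)/2]
      q(t) = Φ(t) ⊗ q(t−1),   renormalized

  (scalar-first Hamilton convention; f is the sampling frequency).
* **A synthetic benchmark generator**: labeled six-behavior IMU bouts
  with exact ground-truth orientation, emulating the acquisition
  setting (1 Hz, 9,000 samples per class, 54,000 total). See
  `docs/methods.md` for the behavior models and what they do and do
  not emulate.
* **Two feature views** over the same data — `raw6` (sensor channels)
  and `quat4` (estimated quaternion components) — sharing one
  stratified fold assignment.
* **Four classifiers** under 10-fold cross-validation: a from-scratch
  Gaussian naive Bayes (per-class Gaussian likelihoods
  P(x_i|c) = N(x_i; mean_{i,c}, sigma²_{i,c}) under feature
  independence), and scikit-learn-backed RBF SVM (C = 10, γ = 1), KNN
  (K = round(√n_train)) and depth-5 decision tree.
* **Evaluation**: per-class precision, recall and F-score
  (F = 2PR/(P+R)), confusion matrices, and macro averages over classes
  and folds.

## Worked example

```python
import imuquat as iq

# 54,000 labeled samples at 1 Hz with ground-truth orientation
dataset = iq.generate_dataset(iq.GeneratorConfig(seed=0))

# the central experiment: 4 classifiers x 2 views, shared 10-fold split
report = iq.compare_views(dataset, specs=iq.default_specs(), k=10, seed=0)
print(report.to_text())
for kind, delta in report.deltas.items():
    print(f"{kind}: quaternion-view macro-F gain {delta:+.3f}")
```

The same run from the shell:

```sh
imuquat compare --seed 0 --out results/
```

prints a per-classifier grid of per-class precision/recall/F for both
views and writes `comparison.csv`, per-fold logs and confusion
matrices. On the default benchmark (seed 0) the headline macro
F-scores are:

| classifier | quaternion view | raw view | gain |
|-----------|-----------------|----------|------|
| GNB       | 0.99            | 0.92     | +0.07 |
| SVM (RBF) | 0.99            | 0.92     | +0.07 |
| KNN       | 0.98            | 0.89     | +0.09 |
| DT        | 0.98            | 0.84     | +0.14 |

Reading the grid: the resting class is classified perfectly by every
classifier in both views (a motionless animal on its side is
unmistakable), walking and standing are the hardest classes, and every
classifier gains substantially from the quaternion view. The
from-scratch Gaussian naive Bayes outscores the tree and KNN on
quaternion features and ties the SVM to two decimals (at full
precision the SVM is ahead by a few tenths of a point — under
per-sample folds a large-sample RBF SVM can exploit within-bout
correlation that a naive Bayes model ignores). Exact decimals for
your machine are whatever the commands above print — the benchmark is
fully seeded and reproducible.

Smaller building blocks are available individually:

```sh
imuquat simulate --samples-per-class 9000 --seed 0 --out data/
imuquat estimate data/traces.csv quats.csv          # raw -> quaternions
imuquat featurize data/traces.csv feats.csv --view quat4
imuquat evaluate feats.csv --classifier gnb --k 10
```

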