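"""Synthetic labeled 6-axis IMU traces with ground-truth orientation.

The generator emulates a torso-mounted 6-axis IMU (MPU-6050 class) on a
medium-sized dog sampled at a collar-logger rate of 1 Hz, producing six
behavior classes — standing, walking, running, sitting, lying, resting —
with exactly balanced counts. No public dog dataset accompanies the
classification protocol this package implements, so the simulator is a
first-class module standing in for field recordings.

Each behavior is a posture-plus-gait model:

* a base posture (pitch/roll of the torso: upright for standing, about
  45° chest-up for sitting, rolled onto one side for resting, ...), on
  top of a constant harness mounting tilt shared by all behaviors;
* a broadband gait oscillation — a twelve-component spectrum anchored
  at the nominal stride rate — whose peak angular rate characterizes
  the motion (slow sway when standing, moderate rates when walking,
  fast high-amplitude shaking when running);
* per-trace posture jitter (each bout settles into a slightly
  different pose) and random oscillation phases.

From the resulting ground-truth orientation track ``q(t)`` the sensors
are synthesized self-consistently:

* the gyroscope reads the exact body-frame angular velocity of the
  truth trajectory, plus a constant per-trace bias and white noise —
  so an orientation estimator's only error sources are noise, bias and
  discretization;
* the accelerometer reads gravity rotated into the body frame (1 g at
  rest), plus a Gaussian body-motion term and white sensor noise.

Everything is driven by a single integer seed; identical configuration
and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import quaternions as quat
from .exceptions import ConfigurationError, InvalidInputError
from .orientation import ImuTrace, OrientationTrack, initial_quaternion

__all__ = [
    "BEHAVIORS",
    "BehaviorModel",
    "GeneratorConfig",
    "LabeledDataset",
    "default_behaviors",
    "generate_trace",
    "generate_dataset",
]

#: Canonical class order of the six-behavior ethogram.
BEHAVIORS = ("standing", "walking", "running", "sitting", "lying", "resting")

# Fraction of the peak angular rate allotted to the pitch / roll / yaw
# oscillation axes. Quadruped gait moves the torso mostly in pitch.
_AXIS_WEIGHTS = np.array([0.60, 0.25, 0.15])

# Seconds over which the body-motion acceleration ramps in at the start
# of a bout (bouts begin from momentary rest).
_REST_START_SECONDS = 2.0

# Number of spectral components in a behavior's motion spectrum. Body
# motion on a harness is broadband (stride fundamental, harmonics,
# head-bob, rattle); superposing many equal-share random-phase
# sinusoids approximates a stationary Gaussian process (spectral
# simulation), which also keeps the 1 Hz-aliased samples near-Gaussian.
_N_COMPONENTS = 12

_GOLDEN = 0.6180339887498949


def _component_frequencies(g: float, k: int = _N_COMPONENTS):
    """Spread component frequencies for nominal stride rate ``g``.

    Fractional parts are kept in [0.2, 0.8] (away from integer
    resonance with 1 Hz sampling) and equidistributed via the golden
    ratio, so no two components alias onto the same sampled frequency.
    """
    base = np.floor(g)
    offsets = 0.2 + 0.6 * np.modf((g + np.arange(k)) * _GOLDEN)[0]
    return base + np.arange(k) + offsets


@dataclass(frozen=True)
class BehaviorModel:
    """Posture and gait parameters of one behavior class.

    Parameters
    ----------
    label : str
        Behavior name.
    base_pitch, base_roll : float
        Mean torso attitude in rad. Sitting tilts the chest up by about
        45°; resting rolls the torso onto a side (±90°).
    gyro_amplitude : float
        Peak angular rate of the gait oscillation, rad/s.
    gyro_frequency : float
        Stride/sway frequency in Hz.
    motion_accel_std : float
        Std of the body-acceleration term added to the accelerometer, g.
    posture_jitter_std : float
        Std of the per-trace posture offset, rad.
    random_side : bool
        If true, the sign of ``base_roll`` is drawn per trace (an animal
        resting on either its right or its left side).
    gait_frequencies : tuple of float, optional
        Explicit oscillation component frequencies (Hz); by default a
        broadband spectrum is derived from ``gyro_frequency``.
    """

    label: str
    base_pitch: float = 0.0
    base_roll: float = 0.0
    gyro_amplitude: float = 0.0
    gyro_frequency: float = 0.0
    motion_accel_std: float = 0.0
    posture_jitter_std: float = 0.0
    random_side: bool = False
    gait_frequencies: Optional[Tuple[float, ...]] = None

    def validate(self) -> None:
        if self.gyro_amplitude < 0 or self.gyro_frequency < 0:
            raise InvalidInputError(f"{self.label}: amplitudes/frequencies must be >= 0")
        if self.motion_accel_std < 0 or self.posture_jitter_std < 0:
            raise InvalidInputError(f"{self.label}: noise std-devs must be >= 0")


def default_behaviors() -> Dict[str, BehaviorModel]:
    """Default six-class ethogram models.

    The postures follow the behavioral definitions (upright standing,
    sitting at about 45°, prone lying, lateral resting) and the motion
    levels are graded so the classes carry distinct posture / rate
    signatures: resting is near-still and trivially separable, running
    has the fastest, largest-amplitude shaking, and walking sits in
    between, overlapping its neighbors the most.
    """
    return {
        "standing": BehaviorModel(
            "standing", base_pitch=0.0, base_roll=0.0,
            gyro_amplitude=0.64, gyro_frequency=0.731,
            motion_accel_std=0.18, posture_jitter_std=0.025,
        ),
        "walking": BehaviorModel(
            "walking", base_pitch=0.22, base_roll=0.15,
            gyro_amplitude=1.15, gyro_frequency=1.291,
            motion_accel_std=0.32, posture_jitter_std=0.03,
        ),
        "running": BehaviorModel(
            "running", base_pitch=-0.60, base_roll=-0.30,
            gyro_amplitude=1.70, gyro_frequency=2.237,
            motion_accel_std=0.45, posture_jitter_std=0.035,
        ),
        "sitting": BehaviorModel(
            "sitting", base_pitch=float(np.pi / 4), base_roll=0.0,
            gyro_amplitude=0.11, gyro_frequency=0.389,
            motion_accel_std=0.015, posture_jitter_std=0.025,
        ),
        "lying": BehaviorModel(
            "lying", base_pitch=-0.28, base_roll=-0.22,
            gyro_amplitude=0.06, gyro_frequency=0.293,
            motion_accel_std=0.008, posture_jitter_std=0.02,
        ),
        "resting": BehaviorModel(
            "resting", base_roll=float(np.pi / 2),
            gyro_amplitude=0.02, gyro_frequency=0.197,
            motion_accel_std=0.004, posture_jitter_std=0.015, random_side=True,
        ),
    }


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic benchmark dataset.

    Defaults reproduce the study conditions of the classification
    protocol: 1 Hz sampling and 9,000 samples per class (54,000 total),
    organized as one-minute behavior bouts so every trace re-anchors
    its orientation estimate on a fresh accelerometer reading.
    """

    behaviors: Dict[str, BehaviorModel] = field(default_factory=default_behaviors)
    f: float = 1.0
    samples_per_class: int = 9000
    trace_length: int = 60
    mount_pitch: float = 0.30
    mount_roll: float = 0.20
    acc_noise_std: float = 0.012
    acc_bias_std: float = 0.01
    gyro_noise_std: float = 0.002
    gyro_bias_std: float = 0.0003
    seed: int = 0

    def validate(self) -> None:
        if self.samples_per_class <= 0:
            raise ConfigurationError("samples_per_class must be positive")
        if self.f <= 0:
            raise ConfigurationError("sampling frequency must be positive")
        if self.trace_length <= 0:
            raise ConfigurationError("trace_length must be positive")
        if min(self.acc_noise_std, self.acc_bias_std, self.gyro_noise_std, self.gyro_bias_std) < 0:
            raise ConfigurationError("noise std-devs must be >= 0")
        missing = [b for b in BEHAVIORS if b not in self.behaviors]
        if missing:
            raise ConfigurationError(f"missing behavior models: {missing}")
        for model in self.behaviors.values():
            model.validate()


@dataclass
class LabeledDataset:
    """Labeled traces plus their ground-truth orientation tracks."""

    traces: List[ImuTrace]
    ground_truth: List[OrientationTrack]
    config: GeneratorConfig

    @property
    def n_samples(self) -> int:
        return sum(len(tr) for tr in self.traces)

    def class_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for tr in self.traces:
            counts[tr.label] = counts.get(tr.label, 0) + len(tr)
        return counts


def _angle_profiles(
    model: BehaviorModel,
    n: int,
    f: float,
    rng: np.random.Generator,
    mount_pitch: float = 0.0,
    mount_roll: float = 0.0,
):
    """Euler-angle trajectories (yaw ψ, pitch θ, roll φ) and their rates.

    Each axis oscillates with three gait components (by default the
    fundamental and its second and third harmonics; a behavior may give
    explicit component frequencies — stride, head-bob and breathing
    move the torso at unrelated rates), with independent random phases
    per trace. Oscillations are anchored so every bout starts exactly
    at its base posture: acquisition bouts begin from the momentary
    rest state the orientation initialization assumes.
    """
    t = np.arange(n) / f
    g = model.gyro_frequency
    freqs = (
        np.asarray(model.gait_frequencies, dtype=float)
        if model.gait_frequencies is not None
        else _component_frequencies(g)
    )
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(len(freqs), 3))
    jitter = rng.normal(0.0, model.posture_jitter_std, size=2)
    side = rng.choice(np.array([-1.0, 1.0]))  # drawn always, for a stable call order
    if not model.random_side:
        side = 1.0

    angles = [np.zeros(n), np.zeros(n), np.zeros(n)]  # pitch, roll, yaw
    rates = [np.zeros(n), np.zeros(n), np.zeros(n)]
    if g > 0 and model.gyro_amplitude > 0:
        share = 1.0 / len(freqs)
        for h, g_h in enumerate(freqs):
            omega_h = 2.0 * np.pi * g_h
            for axis in range(3):
                rate_amp = _AXIS_WEIGHTS[axis] * share * model.gyro_amplitude
                amp = rate_amp / omega_h
                ph = phases[h, axis]
                angles[axis] = angles[axis] + amp * (np.sin(omega_h * t + ph) - np.sin(ph))
                rates[axis] = rates[axis] + rate_amp * np.cos(omega_h * t + ph)

    # The mount offsets model the harness pocket sitting at an angle on
    # the torso: a constant tilt added to every behavior's posture.
    theta = mount_pitch + model.base_pitch + jitter[0] + angles[0]
    phi = mount_roll + side * model.base_roll + jitter[1] + angles[1]
    # Yaw also starts at zero: heading is unobservable from gravity, so
    # the estimator's initial quaternion carries no twist.
    psi = angles[2]
    return t, (psi, theta, phi), (rates[2], rates[0], rates[1])


def _euler_quaternions(psi, theta, phi) -> np.ndarray:
    """Batch quaternion ``qz(ψ) ⊗ qy(θ) ⊗ qx(φ)``."""
    zero = np.zeros_like(psi)
    qz = np.stack([np.cos(psi / 2), zero, zero, np.sin(psi / 2)], axis=-1)
    qy = np.stack([np.cos(theta / 2), zero, np.sin(theta / 2), zero], axis=-1)
    qx = np.stack([np.cos(phi / 2), np.sin(phi / 2), zero, zero], axis=-1)
    return quat.multiply(quat.multiply(qz, qy), qx)


def generate_trace(
    model: BehaviorModel,
    n: int,
    f: float,
    seed,
    acc_noise_std: float = 0.0,
    acc_bias_std: float = 0.0,
    gyro_noise_std: float = 0.0,
    gyro_bias_std: float = 0.0,
    mount_pitch: float = 0.0,
    mount_roll: float = 0.0,
) -> Tuple[ImuTrace, OrientationTrack]:
    """Simulate one behavior bout.

    Returns the 6-axis trace and the ground-truth orientation track.
    The noise-free gyroscope is the exact body-frame angular velocity
    of the truth trajectory: for ``q(t) = qz(ψ) ⊗ qy(θ) ⊗ qx(φ)`` the
    reference-frame angular velocity is

    ``Ω = ψ̇ ẑ + R_z(ψ) θ̇ ŷ + R_z(ψ) R_y(θ) φ̇ x̂``

    and the gyro reads ``q^{-1} Ω q``. The accelerometer reads gravity
    in the body frame, ``q ẑ q^{-1}`` (so ``‖acc‖ = 1`` g exactly at
    rest with zero noise), plus the motion and sensor noise terms.
    """
    if n <= 0:
        raise InvalidInputError("trace length must be positive")
    if f <= 0:
        raise InvalidInputError("sampling frequency must be positive")
    model.validate()
    rng = np.random.default_rng(seed)

    t, (psi, theta, phi), (dpsi, dtheta, dphi) = _angle_profiles(
        model, n, f, rng, mount_pitch=mount_pitch, mount_roll=mount_roll
    )
    q = _euler_quaternions(psi, theta, phi)

    # Anchor the body frame so the bout's initial orientation is the
    # twist-free minimal rotation aligning vertical with the measured
    # gravity — the same convention the orientation estimator uses. A
    # constant right-multiplied correction leaves the reference-frame
    # angular velocity untouched (it redefines the sensor axes, not the
    # motion), so the gyro below stays exact.
    gravity0 = quat.rotate_vector(q[0], np.array([0.0, 0.0, 1.0]))
    correction = quat.multiply(quat.conjugate(q[0]), initial_quaternion(gravity0))
    q = quat.multiply(q, correction)

    # Reference-frame angular velocity of the truth trajectory.
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cos_p, sin_p = np.cos(psi), np.sin(psi)
    omega_ref = np.stack(
        [
            -dtheta * sin_p + dphi * cos_p * cos_t,
            dtheta * cos_p + dphi * sin_p * cos_t,
            dpsi - dphi * sin_t,
        ],
        axis=-1,
    )
    gyro_clean = quat.rotate_vector(quat.conjugate(q), omega_ref)

    gravity_body = quat.rotate_vector(q, np.array([0.0, 0.0, 1.0]))

    gyro_bias = rng.normal(0.0, gyro_bias_std, size=3)
    gyro = gyro_clean + gyro_bias + rng.normal(0.0, gyro_noise_std, size=(n, 3))
    # A loose harness settles slightly differently every bout: the
    # accelerometer carries a constant per-trace mounting offset.
    acc_bias = rng.normal(0.0, acc_bias_std, size=3)
    # Bouts start from momentary rest: the body-motion acceleration term
    # ramps in over the first seconds, so the first accelerometer sample
    # reads (near-)pure gravity, as the orientation initializer assumes.
    ramp = np.clip(t / _REST_START_SECONDS, 0.0, 1.0)[:, np.newaxis]
    acc = (
        gravity_body
        + acc_bias
        + ramp * rng.normal(0.0, model.motion_accel_std, size=(n, 3))
        + rng.normal(0.0, acc_noise_std, size=(n, 3))
    )

    trace = ImuTrace(t=t, acc=acc, gyro=gyro, f=f, label=model.label)
    truth = OrientationTrack(quaternions=q, theta0=float(np.abs(theta[0])))
    return trace, truth


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Generate the full balanced six-class dataset.

    Each class contributes exactly ``samples_per_class`` samples split
    into bouts of ``trace_length`` samples (a final shorter bout covers
    any remainder). Per-trace seeds are spawned deterministically from
    ``config.seed``.
    """
    config.validate()
    lengths = [config.trace_length] * (config.samples_per_class // config.trace_length)
    if config.samples_per_class % config.trace_length:
        lengths.append(config.samples_per_class % config.trace_length)

    root = np.random.SeedSequence(config.seed)
    children = iter(root.spawn(len(BEHAVIORS) * len(lengths)))

    traces: List[ImuTrace] = []
    truths: List[OrientationTrack] = []
    for name in BEHAVIORS:
        model = config.behaviors[name]
        for n in lengths:
            trace, truth = generate_trace(
                model,
                n,
                config.f,
                next(children),
                acc_noise_std=config.acc_noise_std,
                acc_bias_std=config.acc_bias_std,
                gyro_noise_std=config.gyro_noise_std,
                gyro_bias_std=config.gyro_bias_std,
                mount_pitch=config.mount_pitch,
                mount_roll=config.mount_roll,
            )
            traces.append(trace)
            truths.append(truth)
    return LabeledDataset(traces=traces, ground_truth=truths, config=config)
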