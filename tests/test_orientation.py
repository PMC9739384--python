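"""Orientation initialization and gyro-integration against closed forms."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imuquat import quaternions as Q
from imuquat.exceptions import InvalidInputError
from imuquat.orientation import (
    ImuTrace,
    estimate_orientation,
    initial_inclination,
    initial_quaternion,
    initial_rotation_axis,
    integrate_step,
)
from imuquat.simulate import default_behaviors, generate_trace

from conftest import rest_trace


class TestInitialInclination:
    @pytest.mark.parametrize(
        "acc0, expected",
        [
            ((0, 0, 1), 0.0),
            ((1, 0, 0), np.pi / 2),
            ((0, 0.6, 0.8), np.arccos(0.8)),
            ((0, 0, -1), np.pi),
            ((0, 0, 2.0), 0.0),  # non-unit reading is normalized first
        ],
    )
    def test_known_angles(self, acc0, expected):
        assert abs(initial_inclination(acc0) - expected) < 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            initial_inclination((0, 0, 0))


class TestInitialRotationAxis:
    @pytest.mark.parametrize(
        "acc0, expected",
        [
            ((0, 0, 1), (0, 0, 0)),
            ((1, 0, 0), (0, 1, 0)),
            ((0.3, -0.4, 0.87), (0.4, 0.3, 0)),
        ],
    )
    def test_component_formula(self, acc0, expected):
        np.testing.assert_allclose(initial_rotation_axis(acc0), expected, atol=1e-12)

    def test_z_component_always_zero(self, rng):
        for acc in rng.normal(size=(100, 3)):
            assert initial_rotation_axis(acc)[2] == 0.0


class TestInitialQuaternion:
    def test_upright_gives_identity(self):
        np.testing.assert_allclose(initial_quaternion((0, 0, 1)), Q.IDENTITY, atol=1e-12)

    def test_horizontal_gives_quarter_turn_about_y(self):
        expected = np.array([np.cos(np.pi / 4), 0, np.sin(np.pi / 4), 0])
        np.testing.assert_allclose(initial_quaternion((1, 0, 0)), expected, atol=1e-12)

    def test_upside_down_half_turn_about_x(self):
        np.testing.assert_allclose(
            initial_quaternion((0, 0, -1)), np.array([0, 1, 0, 0]), atol=1e-12
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            initial_quaternion((0, 0, 0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_aligns_gravity_with_vertical(self, seed):
        # rotating the measured gravity direction by q(0)^-1 recovers z
        acc0 = np.random.default_rng(seed).normal(size=3)
        if np.linalg.norm(acc0) < 1e-6:
            return
        q0 = initial_quaternion(acc0)
        assert abs(Q.norm(q0) - 1.0) < 1e-9
        back = Q.rotate_vector(Q.inverse(q0), acc0 / np.linalg.norm(acc0))
        np.testing.assert_allclose(back, [0, 0, 1], atol=1e-9)


class TestIntegrateStep:
    def test_zero_rate_is_fixed_point(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        np.testing.assert_allclose(integrate_step(q, (0, 0, 0), 1.0), q, atol=1e-12)

    def test_small_rotation_matches_axis_angle(self):
        got = integrate_step(Q.IDENTITY, (0, 0, 0.02), 1.0)
        exact = np.array([np.cos(0.01), 0, 0, np.sin(0.01)])
        np.testing.assert_allclose(got, exact, atol=1e-4)

    def test_constant_rate_thousand_steps(self):
        # 0.1 rad/s about z at 100 Hz for 1000 steps -> 1 rad about z
        q = Q.IDENTITY.copy()
        for _ in range(1000):
            q = integrate_step(q, (0, 0, 0.1), 100.0)
        angle = 2 * np.arctan2(np.linalg.norm(q[1:]), q[0])
        assert abs(angle - 1.0) < 1e-3
        np.testing.assert_allclose(q[1:3], [0, 0], atol=1e-9)

    def test_result_is_unit_norm(self):
        q = integrate_step(Q.IDENTITY, (3.0, -2.0, 1.0), 1.0)
        assert abs(Q.norm(q) - 1.0) < 1e-9

    def test_invalid_frequency_rejected(self):
        with pytest.raises(InvalidInputError):
            integrate_step(Q.IDENTITY, (0, 0, 0.1), 0.0)

    def test_error_shrinks_quadratically_with_step(self):
        # halving the step size should shrink the per-run error ~4x
        omega, total = np.array([0.9, -0.4, 0.3]), 2.0
        errors = []
        for f in (50.0, 100.0, 200.0):
            n = int(total * f)
            q = Q.IDENTITY.copy()
            for _ in range(n):
                q = integrate_step(q, omega, f)
            exact = Q.from_axis_angle(omega / np.linalg.norm(omega), np.linalg.norm(omega) * total)
            errors.append(Q.geodesic_distance(q, exact))
        assert errors[0] > 2.5 * errors[1] > 2.5 * 2.5 * errors[2]


class TestEstimateOrientation:
    def test_rest_trace_gives_identities(self, upright_rest_trace):
        track = estimate_orientation(upright_rest_trace)
        assert len(track) == len(upright_rest_trace)
        np.testing.assert_allclose(
            track.quaternions, np.tile(Q.IDENTITY, (len(track), 1)), atol=1e-12
        )

    def test_zero_gyro_holds_initial_orientation_exactly(self):
        trace = rest_trace(n=30, acc=(0.2, -0.5, 0.9))
        track = estimate_orientation(trace)
        for q in track.quaternions:
            np.testing.assert_array_equal(q, track.quaternions[0])

    def test_unit_norm_conserved_everywhere(self):
        model = default_behaviors()["running"]
        trace, _ = generate_trace(model, 500, 100.0, 3, gyro_noise_std=0.05)
        track = estimate_orientation(trace)
        np.testing.assert_allclose(Q.norm(track.quaternions), 1.0, atol=1e-9)

    def test_matches_stepwise_integration(self):
        model = default_behaviors()["walking"]
        trace, _ = generate_trace(model, 50, 10.0, 9)
        track = estimate_orientation(trace)
        q = initial_quaternion(trace.acc[0])
        for k in range(1, len(trace)):
            q = integrate_step(q, trace.gyro[k], trace.f)
            np.testing.assert_allclose(track.quaternions[k], q, atol=1e-12)

    def test_tracks_truth_at_high_rate(self):
        # noise-free 100 Hz traces: mean geodesic error < 0.01 rad over 10 s
        for name, model in default_behaviors().items():
            quiet = dataclasses.replace(model, motion_accel_std=0.0)
            trace, truth = generate_trace(quiet, 1000, 100.0, 11)
            est = estimate_orientation(trace)
            err = Q.geodesic_distance(est.quaternions, truth.quaternions)
            assert err.mean() < 0.01, f"{name}: mean error {err.mean():.4f} rad"

    def test_low_rate_drift_is_larger_but_bounded(self):
        # at 1 Hz the small-rotation assumption degrades; drift grows but
        # stays below a gross bound over a one-minute bout
        model = dataclasses.replace(default_behaviors()["walking"], motion_accel_std=0.0)
        hi, truth_hi = generate_trace(model, 600, 100.0, 21)
        lo, truth_lo = generate_trace(model, 60, 1.0, 21)
        err_hi = Q.geodesic_distance(
            estimate_orientation(hi).quaternions, truth_hi.quaternions
        ).mean()
        err_lo = Q.geodesic_distance(
            estimate_orientation(lo).quaternions, truth_lo.quaternions
        ).mean()
        assert err_lo > err_hi
        assert err_lo < np.pi / 2

    def test_rest_sample_averaging(self):
        trace = rest_trace(n=10, acc=(0.1, 0.2, 0.95))
        one = estimate_orientation(trace, rest_samples=1)
        several = estimate_orientation(trace, rest_samples=5)
        np.testing.assert_allclose(one.quaternions, several.quaternions, atol=1e-12)

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            ImuTrace(t=np.array([]), acc=np.empty((0, 3)), gyro=np.empty((0, 3)), f=1.0)
        with pytest.raises(InvalidInputError):
            estimate_orientation("not a trace")


class TestImuTraceValidation:
    def test_inconsistent_spacing_rejected(self):
        with pytest.raises(InvalidInputError):
            ImuTrace(
                t=np.array([0.0, 1.0, 3.0]),
                acc=np.zeros((3, 3)),
                gyro=np.zeros((3, 3)),
                f=1.0,
            )

    def test_non_monotonic_timestamps_rejected(self):
        with pytest.raises(InvalidInputError):
            ImuTrace(
                t=np.array([0.0, 2.0, 1.0]),
                acc=np.zeros((3, 3)),
                gyro=np.zeros((3, 3)),
                f=1.0,
            )

    def test_sample_access(self, upright_rest_trace):
        s = upright_rest_trace[3]
        assert s.t == 3.0
        np.testing.assert_array_equal(s.acc, [0, 0, 1])
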