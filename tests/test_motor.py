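"""Minimum-acceleration segments, trajectory generation, two-joint arm."""

import numpy as np
import pytest

from viascript.errors import InvalidInputError, UnreachableError
from viascript.motor import (GenerationConfig, SegmentBC, TwoJointArm,
                             execute_accelerations, execute_velocities,
                             forward_kinematics, generate_trajectory,
                             inverse_kinematics, joint_profiles,
                             min_acceleration_segment)
from viascript.synthetic import default_prototypes, to_sequence
from viascript.trajectory import ViaPointKind, extract_viapoints


def segment_cost(x: np.ndarray, dt: float) -> float:
    """Discretized integral of squared acceleration.

    Central second differences are exact for cubic polynomials, so the
    optimum's discretized cost equals its continuous cost.
    """
    acc = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt ** 2
    return float(np.sum(acc ** 2) * dt)


class TestMinAccelerationSegment:
    def test_stationary_optimum(self):
        bc = SegmentBC(1.0, 2.0, 0, 0, 1.0, 2.0, 0, 0, T=1.0)
        t, x, y, vx, vy = min_acceleration_segment(bc, 11)
        assert np.allclose(x, 1.0) and np.allclose(y, 2.0)
        assert np.allclose(vx, 0.0) and np.allclose(vy, 0.0)

    def test_zero_cost_linear_solution(self):
        bc = SegmentBC(0, 0, 1, 0, 1, 0, 1, 0, T=1.0)
        t, x, _, vx, _ = min_acceleration_segment(bc, 21)
        assert np.allclose(x, t, atol=1e-12)
        assert np.allclose(vx, 1.0, atol=1e-12)

    def test_smoothstep_values(self):
        # x0=0, x1=1, v0=v1=0, T=1: x(t) = 3t^2 - 2t^3
        bc = SegmentBC(0, 0, 0, 0, 1, 0, 0, 0, T=1.0)
        t, x, _, _, _ = min_acceleration_segment(bc, 5)
        assert x[2] == pytest.approx(0.5, abs=1e-12)          # t = 0.5
        assert x[1] == pytest.approx(0.15625, abs=1e-12)      # t = 0.25

    def test_invalid_duration(self):
        with pytest.raises(InvalidInputError):
            SegmentBC(0, 0, 0, 0, 1, 1, 0, 0, T=0.0)

    def test_beats_random_feasible_interpolants(self):
        # the closed-form cubic minimizes the discretized cost against
        # random perturbations satisfying the same boundary conditions
        rng = np.random.default_rng(42)
        n = 801
        for _ in range(50):
            x0, x1, v0, v1 = rng.normal(0, 5, 4)
            T = rng.uniform(0.5, 2.0)
            bc = SegmentBC(x0, 0, v0, 0, x1, 0, v1, 0, T=T)
            t, x, _, _, _ = min_acceleration_segment(bc, n)
            dt = t[1] - t[0]
            base = segment_cost(x, dt)
            u = t / T
            bump = (u ** 2) * (1 - u) ** 2  # vanishing value+slope at ends
            for _ in range(100):
                # amplitudes bounded away from zero so the perturbation
                # cost dominates the discretization error of the metric
                a, b = rng.choice([-1, 1], 2) * rng.uniform(2.0, 6.0, 2)
                pert = x + bump * (a * np.sin(np.pi * u) + b * u)
                assert base <= segment_cost(pert, dt) + 1e-9


class TestGenerateTrajectory:
    def test_two_collinear_viapoints_make_straight_path(self):
        from viascript.trajectory import ViaPoint, ViaPointSequence
        seq = ViaPointSequence((
            ViaPoint(0, 0, 1, 1, ViaPointKind.START, 0.0),
            ViaPoint(5, 5, 1, 1, ViaPointKind.END, 1.0),
        ))
        traj = generate_trajectory(seq)
        assert np.allclose(traj.y, traj.x, atol=1e-9)

    def test_passes_through_viapoints_exactly(self):
        proto = default_prototypes()["a"]
        seq = to_sequence(proto.skeleton)
        traj = generate_trajectory(seq)
        for p in seq:
            d = np.hypot(traj.x - p.x, traj.y - p.y)
            assert d.min() < 1e-9

    def test_round_trip_recovers_interior_kind_pattern(self):
        # regeneration followed by extraction preserves the tangent/cusp
        # structure of every default prototype and allograph
        for proto in default_prototypes().values():
            for variant in proto.variants():
                seq = to_sequence(variant)
                traj = generate_trajectory(seq)
                got = extract_viapoints(traj)
                assert got.kinds()[1:-1] == seq.kinds()[1:-1], proto.letter

    def test_translation_equivariance(self):
        from viascript.trajectory import ViaPoint, ViaPointSequence
        proto = default_prototypes()["n"]
        seq = to_sequence(proto.skeleton)
        traj = generate_trajectory(seq)
        moved = ViaPointSequence(tuple(
            ViaPoint(p.x + 3.0, p.y - 2.0, p.vx, p.vy, p.kind, p.sample_index)
            for p in seq))
        traj2 = generate_trajectory(moved)
        assert np.allclose(traj2.x, traj.x + 3.0, atol=1e-9)
        assert np.allclose(traj2.y, traj.y - 2.0, atol=1e-9)

    def test_uniform_time_step(self):
        proto = default_prototypes()["w"]
        traj = generate_trajectory(to_sequence(proto.skeleton))
        steps = np.diff(traj.t)
        assert np.allclose(steps, steps[0], atol=1e-9)


class TestKinematics:
    def test_fully_extended(self):
        arm = TwoJointArm()
        t1, t2 = inverse_kinematics(arm.L1 + arm.L2, 0.0, arm)
        assert t1 == pytest.approx(0.0, abs=1e-9)
        assert t2 == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_elbow(self):
        # at radius sqrt(L1^2 + L2^2) the law of cosines gives |theta2| = pi/2
        arm = TwoJointArm()
        r = np.hypot(arm.L1, arm.L2)
        t1, t2 = inverse_kinematics(r, 0.0, arm)
        assert abs(t2) == pytest.approx(np.pi / 2, abs=1e-9)

    @pytest.mark.parametrize("angles, expected", [
        ((0.0, 0.0), "extended"),
        ((np.pi / 2, 0.0), "up"),
        ((0.0, np.pi / 2), "bent"),
    ])
    def test_forward_kinematics_hand_values(self, angles, expected):
        arm = TwoJointArm(L1=0.25, L2=0.35)
        x, y = forward_kinematics(*angles, arm)
        targets = {"extended": (0.6, 0.0), "up": (0.0, 0.6), "bent": (0.25, 0.35)}
        assert (x, y) == pytest.approx(targets[expected], abs=1e-12)

    def test_fk_of_ik_identity_on_seeded_points(self):
        arm = TwoJointArm()
        rng = np.random.default_rng(123)
        for _ in range(1000):
            r = rng.uniform(arm.r_min + 1e-6, arm.r_max - 1e-6)
            phi = rng.uniform(-np.pi, np.pi)
            x, y = r * np.cos(phi), r * np.sin(phi)
            t1, t2 = inverse_kinematics(x, y, arm)
            fx, fy = forward_kinematics(t1, t2, arm)
            assert abs(fx - x) < 1e-9 and abs(fy - y) < 1e-9

    def test_unreachable_point_raises(self):
        arm = TwoJointArm()
        with pytest.raises(UnreachableError):
            inverse_kinematics(1.0, 0.0, arm)

    def test_elbow_branch(self):
        arm_up = TwoJointArm(elbow_branch="up")
        arm_dn = TwoJointArm(elbow_branch="down")
        _, t2u = inverse_kinematics(0.3, 0.2, arm_up)
        _, t2d = inverse_kinematics(0.3, 0.2, arm_dn)
        assert t2u == pytest.approx(-t2d)


class TestJointProfiles:
    def test_stationary_trajectory(self):
        from viascript.trajectory import Trajectory
        arm = TwoJointArm()
        t = np.arange(10) * 0.1
        traj = Trajectory(t, np.full(10, 0.3), np.full(10, 0.1))
        prof = joint_profiles(traj, arm)
        assert np.ptp(prof.theta1) < 1e-12 and np.ptp(prof.theta2) < 1e-12
        assert np.allclose(prof.omega1, 0) and np.allclose(prof.alpha2, 0)

    def test_arc_at_full_extension_freezes_elbow(self):
        from viascript.trajectory import Trajectory
        arm = TwoJointArm()
        phi = np.linspace(0.1, 0.5, 50)
        r = arm.r_max - 1e-12
        traj = Trajectory(phi, r * np.cos(phi), r * np.sin(phi))
        prof = joint_profiles(traj, arm)
        assert np.allclose(prof.theta2, 0.0, atol=1e-5)
        assert np.ptp(prof.theta1) > 0.3

    def test_double_integration_recovers_angles(self):
        from viascript.trajectory import Trajectory
        arm = TwoJointArm()
        t = np.linspace(0.0, 1.0, 400)
        traj = Trajectory(t, 0.35 + 0.05 * np.sin(2 * np.pi * t),
                          0.05 * np.cos(2 * np.pi * t))
        prof = joint_profiles(traj, arm)
        dt = prof.dt
        # trapezoidal double integration of the returned accelerations
        om1 = prof.omega1[0] + np.concatenate(
            [[0], np.cumsum((prof.alpha1[:-1] + prof.alpha1[1:]) / 2 * dt)])
        th1 = prof.theta1[0] + np.concatenate(
            [[0], np.cumsum((om1[:-1] + om1[1:]) / 2 * dt)])
        assert np.max(np.abs(th1 - prof.theta1)) < 50 * dt ** 2 / dt  # O(dt^2) per step


class TestExecution:
    def test_zero_accelerations_stay_put(self):
        arm = TwoJointArm()
        traj = execute_accelerations((0.5, 1.0), (0.0, 0.0),
                                     np.zeros(20), np.zeros(20), 0.05, arm)
        assert np.ptp(traj.x) < 1e-12 and np.ptp(traj.y) < 1e-12

    def _letter_plan(self):
        from viascript.motor import WorkspacePlacement
        proto = default_prototypes()["n"]
        plan = generate_trajectory(to_sequence(proto.skeleton))
        return WorkspacePlacement().to_workspace(plan)

    def test_acceleration_replay_tracks_plan(self):
        # driving the arm with the accelerations derived from a planned
        # letter reproduces the Cartesian path within integration error
        arm = TwoJointArm()
        ws = self._letter_plan()
        prof = joint_profiles(ws, arm)
        out = execute_accelerations((prof.theta1[0], prof.theta2[0]),
                                    (prof.omega1[0], prof.omega2[0]),
                                    prof.alpha1, prof.alpha2, prof.dt, arm)
        err = np.max(np.hypot(out.x - ws.x, out.y - ws.y))
        assert err < 2 * 0.005  # two grid units in workspace metres

    def test_velocity_command_variant_agrees(self):
        arm = TwoJointArm()
        ws = self._letter_plan()
        prof = joint_profiles(ws, arm)
        out = execute_velocities((prof.theta1[0], prof.theta2[0]),
                                 prof.omega1, prof.omega2, prof.dt, arm)
        err = np.max(np.hypot(out.x - ws.x, out.y - ws.y))
        assert err < 2 * 0.005
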