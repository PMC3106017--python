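"""Trajectory generation and the simulated two-joint arm.

Between consecutive via-points the pen path is the minimum-acceleration
trajectory: per coordinate, the curve minimizing the time integral of the
squared acceleration subject to position and velocity constraints at both
ends.  The unique optimum is the cubic Hermite interpolant, evaluated here
with :class:`scipy.interpolate.CubicHermiteSpline`.

Letterforms are planned in the Cartesian workspace and only then mapped to
an effector, so writing style is effector-independent (motor equivalence).
The default effector is a planar two-joint arm (shoulder angle theta1,
elbow angle theta2): inverse kinematics by the law of cosines, joint
velocity/acceleration profiles by finite differences, and execution by
double time-integration of joint accelerations followed by forward
kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import CubicHermiteSpline

from .errors import InvalidInputError, UnreachableError
from .trajectory import Trajectory, ViaPointSequence

DEFAULT_MIN_SEGMENT_T = 0.1


@dataclass(frozen=True)
class SegmentBC:
    """Boundary conditions of one minimum-acceleration segment."""

    x0: float; y0: float; vx0: float; vy0: float
    x1: float; y1: float; vx1: float; vy1: float
    T: float

    def __post_init__(self):
        vals = (self.x0, self.y0, self.vx0, self.vy0,
                self.x1, self.y1, self.vx1, self.vy1, self.T)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError("segment boundary conditions must be finite")
        if self.T <= 0:
            raise InvalidInputError(f"segment duration must be positive, got {self.T}")


@dataclass
class GenerationConfig:
    """How full trajectories are generated through via-points.

    ``points_per_segment`` controls the sampling density: the shortest
    segment receives that many samples and longer segments proportionally
    more, so the concatenated trajectory has one uniform time step.
    ``timing_policy`` assigns each segment a duration proportional to the
    Euclidean distance between its via-points, divided by a reference
    speed; with ``reference_speed=None`` the reference is the mean nonzero
    via-point speed of the sequence, which keeps the stated boundary
    velocities dimensionally consistent with the assigned durations.
    """

    points_per_segment: int = 20
    timing_policy: Literal["distance"] = "distance"
    reference_speed: float | None = None
    min_segment_duration: float = DEFAULT_MIN_SEGMENT_T

    def __post_init__(self):
        if self.points_per_segment < 2:
            raise InvalidInputError("points_per_segment must be >= 2")
        if self.min_segment_duration <= 0:
            raise InvalidInputError("min_segment_duration must be positive")


def min_acceleration_segment(bc: SegmentBC, n: int):
    """Sample the minimum-acceleration (cubic Hermite) segment.

    Returns ``(t, x, y, vx, vy)`` arrays of length ``n``, evenly spaced in
    time and including both endpoints; boundary values are reproduced
    exactly.
    """
    if n < 2:
        raise InvalidInputError("need at least 2 samples per segment")
    t = np.linspace(0.0, bc.T, n)
    sx = CubicHermiteSpline([0.0, bc.T], [bc.x0, bc.x1], [bc.vx0, bc.vx1])
    sy = CubicHermiteSpline([0.0, bc.T], [bc.y0, bc.y1], [bc.vy0, bc.vy1])
    return t, sx(t), sy(t), sx.derivative()(t), sy.derivative()(t)


def segment_durations(seq: ViaPointSequence, cfg: GenerationConfig) -> np.ndarray:
    pos = seq.positions()
    dists = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    ref = cfg.reference_speed
    if ref is None:
        speeds = np.linalg.norm(seq.velocities(), axis=1)
        nz = speeds[speeds > 0]
        ref = float(nz.mean()) if len(nz) else 1.0
    if ref <= 0:
        raise InvalidInputError("reference speed must be positive")
    return np.maximum(dists / ref, cfg.min_segment_duration)


def generate_trajectory(seq: ViaPointSequence, cfg: GenerationConfig | None = None) -> Trajectory:
    """Generate a full trajectory through a continuous via-point sequence.

    Each segment is a minimum-acceleration cubic through its two via-points
    with their stated velocities.  Segment durations are quantized to a
    common time step (the shortest segment divided into
    ``points_per_segment - 1`` intervals) so the concatenation is a valid
    uniformly sampled trajectory; the path passes through every via-point
    with its specified velocity exactly.
    """
    cfg = cfg or GenerationConfig()
    if len(seq) < 2:
        raise InvalidInputError("need at least 2 via-points")
    T = segment_durations(seq, cfg)
    dt = float(T.min()) / (cfg.points_per_segment - 1)
    n_steps = np.maximum(1, np.rint(T / dt).astype(int))  # intervals per segment
    pts = seq.points
    ts, xs, ys = [np.array([0.0])], [np.array([pts[0].x])], [np.array([pts[0].y])]
    t_offset = 0.0
    for k in range(len(pts) - 1):
        a, b = pts[k], pts[k + 1]
        Tk = n_steps[k] * dt
        bc = SegmentBC(a.x, a.y, a.vx, a.vy, b.x, b.y, b.vx, b.vy, Tk)
        t, x, y, _, _ = min_acceleration_segment(bc, n_steps[k] + 1)
        ts.append(t[1:] + t_offset)
        xs.append(x[1:])
        ys.append(y[1:])
        t_offset += Tk
    t_all = np.concatenate(ts)
    # rebuild exactly uniform stamps to avoid accumulated rounding
    t_all = np.arange(len(t_all)) * dt
    return Trajectory(t_all, np.concatenate(xs), np.concatenate(ys))


# ---------------------------------------------------------------------------
# Two-joint arm effector

@dataclass(frozen=True)
class TwoJointArm:
    """Planar two-segment manipulator (upper arm L1, forearm L2, metres)."""

    L1: float = 0.25
    L2: float = 0.35
    elbow_branch: Literal["up", "down"] = "up"

    def __post_init__(self):
        if self.L1 <= 0 or self.L2 <= 0:
            raise InvalidInputError("arm segment lengths must be positive")

    @property
    def r_min(self) -> float:
        return abs(self.L1 - self.L2)

    @property
    def r_max(self) -> float:
        return self.L1 + self.L2


@dataclass
class JointProfile:
    """Time-aligned joint angles with their velocities and accelerations."""

    t: np.ndarray
    theta1: np.ndarray
    theta2: np.ndarray
    omega1: np.ndarray
    omega2: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def forward_kinematics(theta1, theta2, arm: TwoJointArm):
    """Endpoint position of the arm: x = L1 cos(t1) + L2 cos(t1 + t2)."""
    theta1 = np.asarray(theta1, float)
    theta2 = np.asarray(theta2, float)
    x = arm.L1 * np.cos(theta1) + arm.L2 * np.cos(theta1 + theta2)
    y = arm.L1 * np.sin(theta1) + arm.L2 * np.sin(theta1 + theta2)
    return x, y


def inverse_kinematics(x: float, y: float, arm: TwoJointArm,
                       sample_index: int | None = None) -> tuple[float, float]:
    """Joint angles reaching ``(x, y)``, law-of-cosines solution.

    The elbow angle follows the configured branch; the shoulder angle is
    theta1 = atan2(y, x) - atan2(L2 sin t2, L1 + L2 cos t2).
    """
    r2 = x * x + y * y
    r = np.sqrt(r2)
    if not (arm.r_min - 1e-12 <= r <= arm.r_max + 1e-12):
        raise UnreachableError(x, y, arm.r_min, arm.r_max, sample_index)
    c2 = (r2 - arm.L1 ** 2 - arm.L2 ** 2) / (2.0 * arm.L1 * arm.L2)
    c2 = min(1.0, max(-1.0, c2))
    t2 = np.arccos(c2)
    if arm.elbow_branch == "down":
        t2 = -t2
    t1 = np.arctan2(y, x) - np.arctan2(arm.L2 * np.sin(t2), arm.L1 + arm.L2 * np.cos(t2))
    return float(t1), float(t2)


def joint_profiles(traj: Trajectory, arm: TwoJointArm) -> JointProfile:
    """Per-sample inverse kinematics with finite-difference derivatives.

    Velocities and accelerations use the same scheme as the perceptual
    velocity estimate (central differences inside, one-sided at the ends),
    applied twice.
    """
    n = len(traj)
    t1 = np.empty(n)
    t2 = np.empty(n)
    for i in range(n):
        t1[i], t2[i] = inverse_kinematics(float(traj.x[i]), float(traj.y[i]), arm, sample_index=i)
    t1 = np.unwrap(t1)
    t2 = np.unwrap(t2)
    dt = traj.dt
    w1, w2 = np.gradient(t1, dt), np.gradient(t2, dt)
    a1, a2 = np.gradient(w1, dt), np.gradient(w2, dt)
    return JointProfile(traj.t.copy(), t1, t2, w1, w2, a1, a2)


def execute_accelerations(theta0: tuple[float, float], omega0: tuple[float, float],
                          alpha1: np.ndarray, alpha2: np.ndarray, dt: float,
                          arm: TwoJointArm) -> Trajectory:
    """Drive the arm with joint acceleration commands (semi-implicit Euler).

    Each step updates velocity with the commanded acceleration, then
    position with the updated velocity; forward kinematics of the resulting
    joint series gives the written Cartesian path.
    """
    alpha1 = np.asarray(alpha1, float)
    alpha2 = np.asarray(alpha2, float)
    if not (np.all(np.isfinite(alpha1)) and np.all(np.isfinite(alpha2))):
        raise InvalidInputError("acceleration commands must be finite")
    n = len(alpha1)
    t1 = np.empty(n); t2 = np.empty(n)
    th1, th2 = theta0
    om1, om2 = omega0
    t1[0], t2[0] = th1, th2
    for i in range(1, n):
        om1 += alpha1[i - 1] * dt
        om2 += alpha2[i - 1] * dt
        th1 += om1 * dt
        th2 += om2 * dt
        t1[i], t2[i] = th1, th2
    x, y = forward_kinematics(t1, t2, arm)
    return Trajectory(np.arange(n) * dt, x, y)


def execute_velocities(theta0: tuple[float, float], omega1: np.ndarray,
                       omega2: np.ndarray, dt: float, arm: TwoJointArm) -> Trajectory:
    """Velocity-command variant of the effector (single integration)."""
    omega1 = np.asarray(omega1, float)
    omega2 = np.asarray(omega2, float)
    n = len(omega1)
    t1 = np.empty(n); t2 = np.empty(n)
    th1, th2 = theta0
    t1[0], t2[0] = th1, th2
    for i in range(1, n):
        th1 += omega1[i - 1] * dt
        th2 += omega2[i - 1] * dt
        t1[i], t2[i] = th1, th2
    x, y = forward_kinematics(t1, t2, arm)
    return Trajectory(np.arange(n) * dt, x, y)


@dataclass(frozen=True)
class WorkspacePlacement:
    """Affine placement of the canonical 0..40 letter box into arm reach.

    Defaults put the box in front of the arm, inside the reachable annulus
    of the default geometry.
    """

    scale: float = 0.005           # metres per grid unit
    offset_x: float = 0.22
    offset_y: float = -0.10

    def to_workspace(self, traj: Trajectory) -> Trajectory:
        return Trajectory(traj.t,
                          self.offset_x + self.scale * traj.x,
                          self.offset_y + self.scale * traj.y)

    def from_workspace(self, traj: Trajectory) -> Trajectory:
        return Trajectory(traj.t,
                          (traj.x - self.offset_x) / self.scale,
                          (traj.y - self.offset_y) / self.scale)
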