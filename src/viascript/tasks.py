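"""The six cognitive tasks.

Every task is Bayesian inference in the same generative model: letters and
writers have uniform priors, a (letter, writer) pair generates a via-point
sequence through the learned Markov tables, and trajectories relate to
via-point sequences through the deterministic extractor (perception) and
the minimum-acceleration generator (action).  Each task conditions on a
different subset of variables:

- letter recognition: posterior over letters given a trajectory (writer
  known, or marginalized with a uniform prior when unknown);
- writer recognition: the symmetric question;
- joint recognition: posterior over (letter, writer) pairs;
- writing: sample a via-point sequence for a (letter, writer), generate
  the trajectory, drive an effector;
- trajectory copying: extract via-points, regenerate — no letter knowledge;
- letter copying: recognize (as a distribution, never committing to one
  letter), then produce under a possibly different writer style;
- recognition with motor simulation: multiply the perceptual likelihood
  with a second likelihood obtained by regenerating a trajectory from the
  perceived via-points and re-perceiving it.

All likelihood bookkeeping is in log space; posteriors are normalized once
at the end and are strictly positive (Laplace floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import logsumexp, softmax

from .errors import (DegenerateSampleError, InvalidInputError,
                     ViaPointOverflowError)
from .motor import (GenerationConfig, JointProfile, TwoJointArm, WorkspacePlacement,
                    generate_trajectory, joint_profiles)
from .representation import LetterModel, sample_viapoint_sequence
from .trajectory import (Trajectory, ViaPoint, ViaPointSequence, discretize_sequence,
                         robust_extract, undiscretize_sequence)

AnswerPolicy = Literal["sample", "argmax"]


@dataclass
class TaskPosterior:
    """Normalized discrete distribution over task answers."""

    labels: tuple
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InvalidInputError("posterior must be a distribution")
        self.probs = p

    def argmax(self):
        return self.labels[int(np.argmax(self.probs))]

    def prob(self, label) -> float:
        return float(self.probs[self.labels.index(label)])


@dataclass
class TaskResult:
    posterior: TaskPosterior
    answer: object
    artifacts: dict = field(default_factory=dict)


def _answer(posterior: TaskPosterior, policy: AnswerPolicy,
            rng: np.random.Generator | None):
    if policy == "argmax":
        return posterior.argmax()
    if rng is None:
        raise InvalidInputError("answer policy 'sample' needs a random generator")
    return posterior.labels[int(rng.choice(len(posterior.labels), p=posterior.probs))]


def _perceive(traj: Trajectory, model: LetterModel) -> tuple[ViaPointSequence, np.ndarray]:
    seq = robust_extract(traj)
    return seq, discretize_sequence(seq, model.grid)


def letter_log_evidence(bins: np.ndarray, model: LetterModel,
                        writer: str | None = None) -> np.ndarray:
    """Unnormalized log posterior over letters (length-L vector).

    Known writer: that writer's likelihood row.  Unknown writer: sum of
    per-writer likelihoods under the uniform writer prior.
    """
    m = model.log_score_matrix(bins)
    if writer is None:
        return logsumexp(m, axis=0) - np.log(len(model.writers))
    return m[model.writer_index(writer)]


def writer_log_evidence(bins: np.ndarray, model: LetterModel,
                        letter: str | None = None) -> np.ndarray:
    m = model.log_score_matrix(bins)
    if letter is None:
        return logsumexp(m, axis=1) - np.log(len(model.letters))
    return m[:, model.letter_index(letter)]


def recognize_letter(traj: Trajectory, model: LetterModel,
                     writer: str | None = None,
                     answer_policy: AnswerPolicy = "sample",
                     rng: np.random.Generator | None = None) -> TaskResult:
    """Which letter is this trajectory?"""
    seq, bins = _perceive(traj, model)
    log_ev = letter_log_evidence(bins, model, writer)
    post = TaskPosterior(model.letters, softmax(log_ev))
    return TaskResult(post, _answer(post, answer_policy, rng),
                      {"viapoints": seq, "bins": bins, "log_evidence": log_ev})


def recognize_writer(traj: Trajectory, model: LetterModel,
                     letter: str | None = None,
                     answer_policy: AnswerPolicy = "sample",
                     rng: np.random.Generator | None = None) -> TaskResult:
    """Who wrote this trajectory?"""
    seq, bins = _perceive(traj, model)
    log_ev = writer_log_evidence(bins, model, letter)
    post = TaskPosterior(model.writers, softmax(log_ev))
    return TaskResult(post, _answer(post, answer_policy, rng),
                      {"viapoints": seq, "bins": bins, "log_evidence": log_ev})


def recognize_joint(traj: Trajectory, model: LetterModel,
                    answer_policy: AnswerPolicy = "sample",
                    rng: np.random.Generator | None = None) -> TaskResult:
    """Joint posterior over (letter, writer) pairs.

    Its marginals coincide exactly with the marginalized single-label
    recognitions on the same input.
    """
    seq, bins = _perceive(traj, model)
    m = model.log_score_matrix(bins)  # (W, L)
    labels = tuple((letter, writer) for writer in model.writers for letter in model.letters)
    post = TaskPosterior(labels, softmax(m.ravel()))
    return TaskResult(post, _answer(post, answer_policy, rng),
                      {"viapoints": seq, "bins": bins, "log_matrix": m})


def _sample_sequence(letter: str, writer: str, model: LetterModel,
                     rng: np.random.Generator, max_retries: int = 20) -> np.ndarray:
    """Draw a via-point sequence, resampling degenerate ones.

    A sequence is degenerate when two consecutive via-points coincide with
    both velocity bins zero: the segment between them has no extent and no
    motion to interpolate.  Production sampling is kinematically
    constrained (velocity signs follow the sampled displacements) so the
    generated stroke re-perceives like the sequence that planned it.
    """
    for _ in range(max_retries):
        bins = sample_viapoint_sequence(letter, writer, model, rng, kinematic=True)
        pos_same = np.all(np.diff(bins[:, :2], axis=0) == 0, axis=1)
        vel_zero = np.all(bins[:, 2:] == 0, axis=1)
        if not np.any(pos_same & (vel_zero[:-1] | vel_zero[1:])):
            return bins
    raise DegenerateSampleError(
        f"no valid via-point sequence for ({letter!r}, {writer!r}) "
        f"after {max_retries} draws")


def _production_sequence(bins: np.ndarray, grid) -> ViaPointSequence:
    """Continuous via-point sequence for production from sampled bins.

    Positions and velocity signs/tangent structure come straight from the
    sampled bins; velocity magnitudes are clamped to the local positional
    slope of the planned stroke.  One velocity bin spans a coarse range of
    speeds; a boundary velocity well above a segment's mean slope makes
    the minimum-acceleration cubic overshoot or graze zero mid-segment
    and grow tangents the sampled sequence never had, while a clamp at
    the slope keeps the interior velocity bounded away from zero.  The
    clamp keeps the regenerated stroke re-perceivable as its plan.
    """
    seq = undiscretize_sequence(bins, grid)
    pos = seq.positions()
    vel = seq.velocities()
    d = np.diff(pos, axis=0)
    dist = np.linalg.norm(d, axis=1)
    speeds = np.linalg.norm(vel, axis=1)
    nz = speeds[speeds > 0]
    ref = float(nz.mean()) if len(nz) else 1.0
    T = np.maximum(dist / ref, 1e-6)
    slopes = np.abs(d) / T[:, None]   # per segment, per coordinate
    n = len(pos)
    for j in range(n):
        adj = [k for k in (j - 1, j) if 0 <= k < n - 1]
        for c in range(2):
            if vel[j, c] == 0.0:
                continue
            cap = min(slopes[k, c] for k in adj)
            vel[j, c] = np.sign(vel[j, c]) * min(abs(vel[j, c]), cap)
    pts = tuple(
        ViaPoint(float(pos[j, 0]), float(pos[j, 1]),
                 float(vel[j, 0]), float(vel[j, 1]),
                 seq.points[j].kind, float(j))
        for j in range(n))
    return ViaPointSequence(pts)


@dataclass
class WriteResult:
    trajectory: Trajectory
    sequence: ViaPointSequence
    bins: np.ndarray
    joints: JointProfile | None = None


def write_letter(letter: str, writer: str, model: LetterModel,
                 rng: np.random.Generator,
                 cfg: GenerationConfig | None = None,
                 arm: TwoJointArm | None = None,
                 placement: WorkspacePlacement | None = None) -> WriteResult:
    """Write a letter in a writer's style through a simulated effector.

    Two-step approximation of the full inference: ancestral-sample a
    via-point sequence from the letter model, then generate the
    minimum-acceleration trajectory through it.  With an arm, the workspace
    path is placed into reach and converted to joint profiles.
    """
    bins = _sample_sequence(letter, writer, model, rng)
    seq = _production_sequence(bins, model.grid)
    traj = generate_trajectory(seq, cfg)
    joints = None
    if arm is not None:
        placement = placement or WorkspacePlacement()
        joints = joint_profiles(placement.to_workspace(traj), arm)
    return WriteResult(traj, seq, bins, joints)


def copy_trajectory(traj: Trajectory, cfg: GenerationConfig | None = None,
                    arm: TwoJointArm | None = None,
                    placement: WorkspacePlacement | None = None,
                    return_artifacts: bool = False):
    """Copy any trajectory without recognizing it.

    Extracts the via-points and regenerates through them; the planned copy
    passes through every input via-point exactly.  The letter model is not
    involved, so unknown symbols are copied too.
    """
    seq = robust_extract(traj)
    planned = generate_trajectory(seq, cfg)
    if not return_artifacts:
        return planned
    artifacts = {"viapoints": seq}
    if arm is not None:
        placement = placement or WorkspacePlacement()
        artifacts["joints"] = joint_profiles(placement.to_workspace(planned), arm)
    return planned, artifacts


def copy_letter(traj: Trajectory, model: LetterModel,
                reading_writer: str, output_writer: str,
                rng: np.random.Generator,
                cfg: GenerationConfig | None = None,
                return_artifacts: bool = False):
    """Copy the *letter* carried by a trajectory, possibly restyled.

    The input is read under ``reading_writer`` into a posterior over
    letters; a fresh via-point sequence is then drawn from the posterior-
    weighted mixture of letter models under ``output_writer`` and
    regenerated.  The letter identity is never committed explicitly — only
    the distribution over letters is computed, and the mixture draw
    approximates the exact sum over letters.
    """
    seq, bins = _perceive(traj, model)
    log_ev = letter_log_evidence(bins, model, reading_writer)
    post = TaskPosterior(model.letters, softmax(log_ev))
    li = int(rng.choice(len(model.letters), p=post.probs))
    out_bins = _sample_sequence(model.letters[li], output_writer, model, rng)
    out_seq = _production_sequence(out_bins, model.grid)
    out = generate_trajectory(out_seq, cfg)
    if not return_artifacts:
        return out
    return out, {"letter_posterior": post, "viapoints": out_seq, "bins": out_bins}


def simulate_percept(traj_or_seq, model: LetterModel,
                     cfg: GenerationConfig | None = None):
    """The internal motor-simulation loop.

    Regenerates a full trajectory through the perceived via-points with the
    motor model, then re-extracts via-points from the simulated trajectory
    with the *same* extractor as perception.  Returns
    ``(simulated_trajectory, simulated_bins)``.
    """
    if isinstance(traj_or_seq, Trajectory):
        seq = robust_extract(traj_or_seq)
    else:
        seq = traj_or_seq
    sim_traj = generate_trajectory(seq, cfg)
    try:
        sim_seq = robust_extract(sim_traj)
    except ViaPointOverflowError as exc:
        raise ViaPointOverflowError(exc.count, exc.limit, branch="simulation") from exc
    return sim_traj, discretize_sequence(sim_seq, model.grid)


def recognize_with_simulation(traj: Trajectory, model: LetterModel,
                              writer: str | None = None,
                              cfg: GenerationConfig | None = None,
                              answer_policy: AnswerPolicy = "sample",
                              rng: np.random.Generator | None = None) -> TaskResult:
    """Letter recognition aided by internal simulation of movements.

    The posterior is proportional to the product of two likelihood terms:
    the perceptual likelihood of the via-points extracted from the input,
    and the likelihood of the via-points re-extracted from the internally
    regenerated trajectory.  The same writer conditioning applies to both
    terms (summed per writer before marginalizing when unknown).
    """
    try:
        seq = robust_extract(traj)
    except ViaPointOverflowError as exc:
        raise ViaPointOverflowError(exc.count, exc.limit, branch="perception") from exc
    bins = discretize_sequence(seq, model.grid)
    sim_traj, sim_bins = simulate_percept(seq, model, cfg)
    term1 = model.log_score_matrix(bins)      # (W, L)
    term2 = model.log_score_matrix(sim_bins)  # (W, L)
    combined = term1 + term2
    if writer is None:
        log_ev = logsumexp(combined, axis=0) - np.log(len(model.writers))
    else:
        log_ev = combined[model.writer_index(writer)]
    post = TaskPosterior(model.letters, softmax(log_ev))
    return TaskResult(post, _answer(post, answer_policy, rng), {
        "simulated_trajectory": sim_traj,
        "perceived_bins": bins, "simulated_bins": sim_bins,
        "perceived_viapoints": seq,
        "log_term_perception": term1, "log_term_simulation": term2,
    })


def truncate_trajectory(traj: Trajectory, start_index: int, length: int) -> Trajectory:
    """Erase ``length`` consecutive samples starting at ``start_index``.

    Tail truncation simply shortens the trajectory; removing an interior
    span re-joins the two remaining parts into a single uniformly sampled
    trajectory (subsequent sample times shift to restore the uniform step,
    because the extractor requires one uniformly sampled series).
    """
    n = len(traj)
    if length < 0 or start_index < 0 or start_index + length > n:
        raise InvalidInputError(
            f"span [{start_index}, {start_index + length}) outside trajectory of {n} samples")
    if length == 0:
        return Trajectory(traj.t.copy(), traj.x.copy(), traj.y.copy())
    keep = np.ones(n, dtype=bool)
    keep[start_index:start_index + length] = False
    if keep.sum() < 2:
        raise InvalidInputError("truncation must leave at least 2 samples")
    x, y = traj.x[keep], traj.y[keep]
    t = traj.t[0] + traj.dt * np.arange(keep.sum())
    return Trajectory(t, x, y)
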