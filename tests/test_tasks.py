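"""The six cognitive tasks: recognition, writing, copying, simulation."""

import numpy as np
import pytest
from scipy.special import logsumexp, softmax

from viascript.errors import InvalidInputError
from viascript.motor import TwoJointArm
from viascript.representation import fit_letter_model, untrained_model
from viascript.synthetic import default_prototypes, to_sequence
from viascript.tasks import (copy_letter, copy_trajectory, recognize_joint,
                             recognize_letter, recognize_with_simulation,
                             recognize_writer, truncate_trajectory, write_letter)
from viascript.trajectory import (GridSpec, Trajectory, discretize_sequence,
                                  robust_extract)
from viascript.motor import generate_trajectory

LETTERS = ("A", "B")
WRITERS = ("w0", "w1")


def _traj(letter="n"):
    proto = default_prototypes()[letter]
    return generate_trajectory(to_sequence(proto.skeleton))


@pytest.fixture(scope="module")
def disjoint_model():
    """Two letters with disjoint via-point supports under two writers."""
    grid = GridSpec.unit()
    low = generate_trajectory(to_sequence(default_prototypes()["n"].skeleton))
    corpus = []
    for writer in WRITERS:
        seq = robust_extract(low)
        bins_a = discretize_sequence(seq, grid)
        bins_b = bins_a.copy()
        bins_b[:, :2] = np.clip(40 - bins_b[:, :2], 0, 40)  # mirrored letter
        corpus += [("A", writer, bins_a), ("B", writer, bins_b)] * 20
    return fit_letter_model(corpus, LETTERS, WRITERS, grid)


class TestRecognition:
    def test_untrained_model_gives_uniform_posteriors(self):
        model = untrained_model(LETTERS, WRITERS)
        traj = _traj()
        for res in (recognize_letter(traj, model, answer_policy="argmax"),
                    recognize_writer(traj, model, answer_policy="argmax"),
                    recognize_joint(traj, model, answer_policy="argmax")):
            assert np.allclose(res.posterior.probs,
                               1.0 / len(res.posterior.probs), atol=1e-12)

    def test_disjoint_supports_give_confident_answer(self, disjoint_model):
        res = recognize_letter(_traj(), disjoint_model, writer="w0",
                               answer_policy="argmax")
        assert res.answer == "A"
        assert res.posterior.prob("A") > 0.99

    def test_marginalized_writer_equals_explicit_double_loop(self, disjoint_model):
        traj = _traj()
        res = recognize_letter(traj, disjoint_model, writer=None,
                               answer_policy="argmax")
        m = disjoint_model.log_score_matrix(res.artifacts["bins"])
        # oracle: explicit sum of per-writer likelihoods, uniform prior
        brute = softmax(logsumexp(m, axis=0))
        assert np.allclose(res.posterior.probs, brute, atol=1e-12)

    def test_writer_recognition_marginal_oracle(self, disjoint_model):
        traj = _traj()
        res = recognize_writer(traj, disjoint_model, letter=None,
                               answer_policy="argmax")
        m = disjoint_model.log_score_matrix(res.artifacts["bins"])
        brute = softmax(logsumexp(m, axis=1))
        assert np.allclose(res.posterior.probs, brute, atol=1e-12)

    def test_joint_marginals_match_single_label_tasks(self, disjoint_model):
        traj = _traj()
        joint = recognize_joint(traj, disjoint_model, answer_policy="argmax")
        letters = recognize_letter(traj, disjoint_model, answer_policy="argmax")
        writers = recognize_writer(traj, disjoint_model, answer_policy="argmax")
        probs = joint.posterior.probs.reshape(len(WRITERS), len(LETTERS))
        # marginalized single-label posteriors use the same uniform prior,
        # so the joint marginals reproduce them exactly
        assert np.allclose(probs.sum(axis=0), letters.posterior.probs, atol=1e-12)
        assert np.allclose(probs.sum(axis=1), writers.posterior.probs, atol=1e-12)

    def test_posteriors_are_normalized_and_positive(self, disjoint_model):
        res = recognize_joint(_traj(), disjoint_model, answer_policy="argmax")
        assert res.posterior.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(res.posterior.probs > 0)

    def test_sampled_answer_is_deterministic_per_seed(self, disjoint_model):
        traj = _traj()
        a = recognize_letter(traj, disjoint_model, rng=np.random.default_rng(3))
        b = recognize_letter(traj, disjoint_model, rng=np.random.default_rng(3))
        assert a.answer == b.answer


class TestWriting:
    def test_same_seed_identical_trajectory(self, fitted):
        model, _ = fitted
        a = write_letter("a", "w_round", model, np.random.default_rng(9))
        b = write_letter("a", "w_round", model, np.random.default_rng(9))
        assert np.array_equal(a.trajectory.x, b.trajectory.x)
        assert np.array_equal(a.trajectory.y, b.trajectory.y)

    def test_different_seeds_vary(self, fitted):
        model, _ = fitted
        a = write_letter("a", "w_round", model, np.random.default_rng(1))
        b = write_letter("a", "w_round", model, np.random.default_rng(2))
        assert not (len(a.trajectory) == len(b.trajectory)
                    and np.allclose(a.trajectory.x, b.trajectory.x))

    def test_arm_output_produces_joint_profile(self, fitted):
        model, _ = fitted
        res = write_letter("o", "w_round", model, np.random.default_rng(4),
                           arm=TwoJointArm())
        assert res.joints is not None
        assert len(res.joints.theta1) == len(res.trajectory)
        assert np.all(np.isfinite(res.joints.alpha1))


class TestCopying:
    def test_straight_segment_reproduced(self, line_trajectory):
        out = copy_trajectory(line_trajectory)
        # endpoints and the straight geometry are preserved
        assert out.x[0] == pytest.approx(0.0, abs=1e-9)
        assert out.x[-1] == pytest.approx(10.0, abs=1e-9)
        assert np.max(np.abs(out.y)) < 1e-9

    def test_unknown_symbol_is_copyable(self):
        # a spiral is not in any letter repertoire but copies fine
        t = np.linspace(0.0, 1.0, 301)
        r = 1.0 + 2.0 * t
        theta = 2.2 * np.pi * t + 0.3
        traj = Trajectory(t, r * np.cos(theta), r * np.sin(theta))
        out = copy_trajectory(traj)
        seq = robust_extract(traj)
        for p in seq:
            assert np.min(np.hypot(out.x - p.x, out.y - p.y)) < 1e-9

    def test_copy_coincides_at_viapoints(self, fitted, corpus):
        traj = corpus.trials[0].trajectory
        out = copy_trajectory(traj)
        for p in robust_extract(traj):
            assert np.min(np.hypot(out.x - p.x, out.y - p.y)) < 1e-9

    def test_copy_letter_deterministic_and_restyles(self, fitted, corpus):
        model, _ = fitted
        trial = next(t for t in corpus.trials
                     if t.letter == "o" and t.writer == "w_round")
        a = copy_letter(trial.trajectory, model, "w_round", "w_slant",
                        np.random.default_rng(5))
        b = copy_letter(trial.trajectory, model, "w_round", "w_slant",
                        np.random.default_rng(5))
        assert np.array_equal(a.x, b.x)
        # the copy, read back with known letter, looks like the output style
        res = recognize_writer(a, model, letter="o", answer_policy="argmax")
        assert res.posterior.prob("w_slant") > res.posterior.prob("w_round")

    def test_copy_letter_of_unknown_symbol_yields_repertoire_letter(self, fitted):
        model, _ = fitted
        t = np.linspace(0.0, 1.0, 301)
        r = 3.0 + 10.0 * t
        theta = 1.8 * np.pi * t + 0.4
        traj = Trajectory(t, 20 + r * np.cos(theta), 20 + r * np.sin(theta))
        out = copy_letter(traj, model, "w_round", "w_round",
                          np.random.default_rng(6))
        res = recognize_letter(out, model, writer="w_round", answer_policy="argmax")
        assert res.answer in model.letters


class TestSimulation:
    def test_factorization_of_log_posterior(self, fitted, corpus):
        model, _ = fitted
        trial = corpus.trials[10]
        res = recognize_with_simulation(trial.trajectory, model,
                                        writer=trial.writer,
                                        answer_policy="argmax")
        t1 = res.artifacts["log_term_perception"]
        t2 = res.artifacts["log_term_simulation"]
        w = model.writer_index(trial.writer)
        brute = softmax(t1[w] + t2[w])
        assert np.allclose(res.posterior.probs, brute, atol=1e-12)

    def test_identical_branches_square_the_likelihood(self, disjoint_model):
        # if re-extraction reproduces the perceived via-points exactly the
        # combined posterior is the normalized square of the single branch
        traj = _traj()
        res = recognize_with_simulation(traj, disjoint_model, writer="w0",
                                        answer_policy="argmax")
        t1 = res.artifacts["log_term_perception"]
        t2 = res.artifacts["log_term_simulation"]
        if np.array_equal(res.artifacts["perceived_bins"],
                          res.artifacts["simulated_bins"]):
            single = recognize_letter(traj, disjoint_model, writer="w0",
                                      answer_policy="argmax")
            assert res.answer == single.answer
            w = 0
            assert np.allclose(res.posterior.probs, softmax(2 * t1[w]), atol=1e-12)

    def test_returns_simulated_artifacts(self, fitted, corpus):
        model, _ = fitted
        res = recognize_with_simulation(corpus.trials[0].trajectory, model,
                                        writer=corpus.trials[0].writer,
                                        answer_policy="argmax")
        assert len(res.artifacts["simulated_trajectory"]) > 2
        assert res.artifacts["simulated_bins"].shape[1] == 4


class TestTruncation:
    def _traj(self):
        t = np.arange(20) * 0.1
        return Trajectory(t, np.arange(20.0), np.arange(20.0) ** 2)

    def test_tail_removal_shortens(self):
        out = truncate_trajectory(self._traj(), 15, 5)
        assert len(out) == 15
        assert out.x[-1] == 14.0

    def test_zero_length_is_identity(self):
        traj = self._traj()
        out = truncate_trajectory(traj, 5, 0)
        assert np.array_equal(out.x, traj.x) and np.array_equal(out.t, traj.t)

    def test_interior_gap_rejoins_uniformly(self):
        out = truncate_trajectory(self._traj(), 5, 4)
        assert len(out) == 16
        steps = np.diff(out.t)
        assert np.allclose(steps, steps[0], atol=1e-12)
        assert out.x[5] == 9.0  # samples after the gap shift left

    def test_span_outside_trajectory_rejected(self):
        with pytest.raises(InvalidInputError):
            truncate_trajectory(self._traj(), 18, 5)
        with pytest.raises(InvalidInputError):
            truncate_trajectory(self._traj(), 0, 19)
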