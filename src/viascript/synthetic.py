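"""Synthetic handwriting corpora.

No public corpus of single-stroke cursive pen trajectories ships with this
package, so this module emulates one: 22 hand-designed via-point skeletons
(the lowercase Latin alphabet minus *i*, *j*, *t* and *x*, which need a
pen-up), a set of writer styles (slant, scale, roundness and trial-to-trial
jitter), and a deterministic corpus builder.  The default design mirrors a
small tablet study: 4 writers x 22 letters x 40 trials = 3,520 trajectories.

The skeletons live in a canonical 0..40 writing box with the baseline at
y = 10, x-height about 26, ascenders near 38 and descenders near 2.  They
are not traced from any real handwriting sample; they only need to be
mutually distinguishable and roughly letter-like.  Ascender letters (l, b,
h, k) are deliberately similar, and g/q share their body and differ only in
the tail, so that confusions and the benefit of motor simulation can be
studied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, ViaPointOverflowError
from .motor import GenerationConfig, generate_trajectory
from .trajectory import (Trajectory, ViaPoint, ViaPointKind, ViaPointSequence,
                         extract_viapoints, robust_extract)

BOX = 40.0

_K = ViaPointKind


def _vp(x, y, vx, vy, kind) -> tuple:
    return (float(x), float(y), float(vx), float(vy), kind)


def _S(x, y, vx, vy):
    return _vp(x, y, vx, vy, _K.START)


def _E(x, y, vx, vy):
    return _vp(x, y, vx, vy, _K.END)


def _H(x, y, vx):
    return _vp(x, y, vx, 0.0, _K.HORIZONTAL_TANGENT)


def _V(x, y, vy):
    return _vp(x, y, 0.0, vy, _K.VERTICAL_TANGENT)


def _C(x, y):
    return _vp(x, y, 0.0, 0.0, _K.CUSP)


@dataclass(frozen=True)
class LetterPrototype:
    """Canonical via-point skeleton of one letter, plus optional allographs.

    ``skeleton`` and each entry of ``allographs`` are sequences of
    ``(x, y, vx, vy, kind)`` tuples in the canonical box.
    """

    letter: str
    skeleton: tuple[tuple, ...]
    allographs: tuple[tuple[tuple, ...], ...] = ()

    def __post_init__(self):
        for variant in (self.skeleton, *self.allographs):
            if not (2 <= len(variant) <= 16):
                raise InvalidInputError(f"prototype {self.letter!r}: bad length")
            if variant[0][4] is not _K.START or variant[-1][4] is not _K.END:
                raise InvalidInputError(f"prototype {self.letter!r}: bad end kinds")
            for x, y, vx, vy, kind in variant[1:-1]:
                if kind is _K.HORIZONTAL_TANGENT and vy != 0:
                    raise InvalidInputError(f"{self.letter!r}: H point with vy != 0")
                if kind is _K.VERTICAL_TANGENT and vx != 0:
                    raise InvalidInputError(f"{self.letter!r}: V point with vx != 0")
                if kind is _K.CUSP and (vx != 0 or vy != 0):
                    raise InvalidInputError(f"{self.letter!r}: cusp with velocity")

    def variants(self) -> tuple[tuple[tuple, ...], ...]:
        return (self.skeleton, *self.allographs)


def to_sequence(points: Sequence[tuple]) -> ViaPointSequence:
    return ViaPointSequence(tuple(
        ViaPoint(x, y, vx, vy, kind, float(i))
        for i, (x, y, vx, vy, kind) in enumerate(points)))


def default_prototypes() -> dict[str, LetterPrototype]:
    """The 22 single-stroke letter skeletons (no i, j, t, x)."""
    P: dict[str, tuple] = {}
    # round-body family: shared oval, closing cusp, different tails -----
    # the closing vertical tangent is a genuine x-reversal (bowl edge
    # right of the cusp) so detection does not depend on a grazing touch
    P["a"] = (_S(26, 24, -6, 4), _H(18, 27, -9), _V(11, 20, -9), _H(18, 13, 9),
              _V(26, 18, 6), _C(22, 27), _H(29, 13, 5), _E(33, 19, 5, 7))
    P["d"] = (_S(23, 22, -5, 3), _H(17, 25, -7), _V(12, 19, -7), _H(17, 13, 7),
              _V(23, 17, 6), _C(20, 36), _H(27, 11, 2), _E(31, 17, 5, 6))
    P["g"] = (_S(26, 24, -6, 4), _H(18, 28, -9), _V(11, 20, -9), _H(18, 13, 9),
              _V(26, 18, 6), _C(23, 26), _H(17, 3, -2), _E(12, 9, -3, 6))
    P["q"] = (_S(26, 24, -6, 3), _H(18, 27, -9), _V(11, 20, -9), _H(18, 13, 9),
              _V(27, 18, 6), _C(25, 27), _H(30, 3, 2), _E(34, 10, 3, 7))
    P["c"] = (_S(27, 25, -7, 5), _H(19, 28, -8), _V(12, 20, -9), _H(19, 12, 9),
              _E(27, 16, 6, 5))
    P["o"] = (_S(26, 24, -6, 4), _H(18, 28, -8), _V(11, 20, -9), _H(18, 12, 8),
              _V(25, 20, 8), _E(22, 27, -5, 2))
    P["e"] = (_S(10, 14, 8, 3), _V(16, 19, 8), _H(11, 26, -6), _V(6, 18, -9),
              _H(12, 10, 8), _E(19, 15, 6, 6))
    # ascender family (deliberately confusable) ------------------------
    P["l"] = (_S(8, 10, 8, 4), _V(16, 25, 10), _H(12, 36, -6), _V(8, 24, -10),
              _H(13, 10, 5), _E(20, 16, 7, 8))
    l_slanted = (_S(8, 10, 4, 9), _C(14, 36), _H(18, 10, 3), _E(25, 16, 6, 6))
    P["b"] = (_S(5, 10, 8, 5), _V(14, 25, 10), _H(9, 36, -5), _V(4, 24, -10),
              _H(11, 10, 7), _V(17, 15, 8), _E(13, 21, -4, 3))
    P["h"] = (_S(5, 10, 7, 9), _V(13, 25, 10), _H(8, 36, -5), _V(3, 24, -10),
              _H(9, 10, 5), _H(14, 21, 4), _H(20, 10, 4), _E(25, 16, 5, 7))
    P["k"] = (_S(5, 10, 7, 9), _V(13, 25, 10), _H(8, 36, -5), _V(3, 24, -10),
              _H(9, 10, 5), _C(18, 27), _H(24, 10, 4), _E(29, 15, 5, 6))
    P["f"] = (_S(7, 12, 7, 9), _V(15, 26, 10), _H(10, 36, -5), _V(5, 24, -10),
              _C(9, 3), _E(14, 12, 4, 8))
    # arches: wide and shallow so slanted styles keep them monotone in x
    P["m"] = (_S(4, 10, 3, 8), _H(9, 20, 2), _H(14, 12, 2), _H(19, 20, 2),
              _H(24, 12, 2), _H(29, 20, 2), _H(34, 12, 2), _E(38, 17, 4, 6))
    P["n"] = (_S(10, 10, 4, 8), _H(15, 20, 2), _H(20, 12, 2), _H(25, 20, 2),
              _H(30, 12, 2), _E(34, 17, 4, 6))
    P["r"] = (_S(8, 10, 2, 10), _H(12, 25, 3), _V(17, 21, -5), _C(14, 10),
              _E(19, 14, 4, 5))
    # cups and points -----------------------------------------------------
    P["u"] = (_S(6, 24, 3, -8), _H(13, 10, 3), _C(18, 24), _H(23, 10, 2),
              _E(28, 17, 5, 7))
    P["y"] = (_S(6, 24, 3, -8), _H(14, 10, 3), _C(18, 24), _H(12, 3, -2),
              _E(8, 9, -3, 6))
    P["v"] = (_S(8, 24, 3, -9), _C(13, 9), _E(19, 24, 4, 8))
    P["w"] = (_S(4, 25, 3, -9), _C(11, 8), _H(16, 18, 2), _C(21, 8),
              _E(27, 25, 4, 8))
    P["z"] = (_S(8, 25, 6, 2), _C(16, 27), _C(9, 11), _E(18, 14, 7, 3))
    # remaining -----------------------------------------------------------
    P["s"] = (_S(25, 24, -6, 4), _H(18, 28, -5), _V(13, 24, -5), _V(20, 14, -5),
              _H(14, 9, -6), _E(10, 12, -4, 4))
    P["p"] = (_S(6, 26, 2, -10), _C(10, 3), _H(13, 26, 2), _V(19, 19, -8),
              _H(13, 11, -5), _E(10, 13, -3, 3))

    out = {}
    for letter, skeleton in P.items():
        allographs = (l_slanted,) if letter == "l" else ()
        out[letter] = LetterPrototype(letter, skeleton, allographs)
    return out


SUPPORTED_LETTERS = tuple(sorted(default_prototypes().keys()))


@dataclass(frozen=True)
class WriterStyle:
    """Per-writer style transform and trial-to-trial variability.

    ``slant`` shears positions and velocities about the box centre;
    ``scale_x``/``scale_y`` scale about the centre; ``roundness``
    multiplies the free (tangential) velocity component at interior
    via-points.  ``jitter_pos``/``jitter_vel`` are standard deviations (in
    grid units and grid units per time) of the per-trial Gaussian noise
    added at via-points; velocity components that the via-point kind pins
    to zero are left exactly zero so tangents stay tangents.
    ``allograph_probs`` weights a prototype's variants; shorter vectors are
    padded with zeros, so the default (1,) always picks the main skeleton.
    """

    name: str
    slant_deg: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0
    roundness: float = 1.0
    jitter_pos: float = 0.6
    jitter_vel: float = 0.5
    allograph_probs: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise InvalidInputError("style scales must be positive")
        if self.jitter_pos < 0 or self.jitter_vel < 0:
            raise InvalidInputError("jitter stds must be non-negative")
        p = np.asarray(self.allograph_probs, float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise InvalidInputError("allograph_probs must be a distribution")


def default_styles() -> tuple[WriterStyle, ...]:
    """Four writer styles: round, slanted, narrow and wide.

    One rounded and one strongly slanted style are included so that writer
    recognition has clearly separable targets; allograph variation is given
    to the slanted writer (who also prefers the slanted 'l').
    """
    return (
        WriterStyle("w_round", slant_deg=2.0, scale_x=1.0, scale_y=1.0,
                    roundness=1.2, allograph_probs=(1.0,)),
        WriterStyle("w_slant", slant_deg=10.0, scale_x=1.0, scale_y=0.95,
                    roundness=0.85, allograph_probs=(0.3, 0.7)),
        WriterStyle("w_narrow", slant_deg=4.0, scale_x=0.82, scale_y=1.08,
                    roundness=1.0, allograph_probs=(1.0,)),
        WriterStyle("w_wide", slant_deg=-6.0, scale_x=1.18, scale_y=0.8,
                    roundness=1.0, allograph_probs=(1.0,)),
    )


_CENTER = (20.0, 20.0)


def _style_matrix(style: WriterStyle) -> np.ndarray:
    """Linear part of the style map: scale about centre after shear."""
    tan = math.tan(math.radians(style.slant_deg))
    shear = np.array([[1.0, tan], [0.0, 1.0]])
    scale = np.array([[style.scale_x, 0.0], [0.0, style.scale_y]])
    return scale @ shear


def styled_viapoints(points: Sequence[tuple], style: WriterStyle) -> list[tuple]:
    """Apply the deterministic part of a style to a skeleton."""
    A = _style_matrix(style)
    cx, cy = _CENTER
    out = []
    n = len(points)
    for i, (x, y, vx, vy, kind) in enumerate(points):
        px, py = A @ np.array([x - cx, y - cy]) + np.array([cx, cy])
        pvx, pvy = A @ np.array([vx, vy])
        if 0 < i < n - 1:
            pvx *= style.roundness
            pvy *= style.roundness
        if kind is _K.HORIZONTAL_TANGENT:
            pvy = 0.0  # exact under a shear+diagonal-scale map anyway
        elif kind is _K.CUSP:
            pvx = pvy = 0.0
        out.append((float(px), float(py), float(pvx), float(pvy), kind))
    return out


def synthesize_trial(prototype: LetterPrototype, style: WriterStyle,
                     rng: np.random.Generator,
                     cfg: GenerationConfig | None = None) -> Trajectory:
    """One handwriting trial: allograph choice, style, jitter, generation.

    Deterministic given the generator state.  Via-points whose kind pins a
    velocity component to zero keep it at exactly zero; positions pushed
    outside the canonical box by jitter are clipped.
    """
    variants = prototype.variants()
    probs = np.zeros(len(variants))
    p = np.asarray(style.allograph_probs, float)[:len(variants)]
    probs[:len(p)] = p
    probs /= probs.sum()
    variant = variants[rng.choice(len(variants), p=probs)]
    styled = styled_viapoints(variant, style)
    n = len(styled)
    pts = []
    for i, (x, y, vx, vy, kind) in enumerate(styled):
        jx, jy = rng.normal(0.0, style.jitter_pos, size=2)
        jvx, jvy = rng.normal(0.0, style.jitter_vel, size=2)
        x = float(np.clip(x + jx, 0.0, BOX))
        y = float(np.clip(y + jy, 0.0, BOX))
        if vx != 0.0 or (kind in (_K.START, _K.END)):
            vx = vx + jvx
        if vy != 0.0 or (kind in (_K.START, _K.END)):
            vy = vy + jvy
        pts.append(ViaPoint(x, y, float(vx), float(vy), kind, float(i)))
    return generate_trajectory(ViaPointSequence(tuple(pts)), cfg)


@dataclass
class Trial:
    letter: str
    writer: str
    index: int
    trajectory: Trajectory


@dataclass
class Corpus:
    """A labelled synthetic corpus plus the manifest that rebuilds it."""

    trials: list[Trial]
    letters: tuple[str, ...]
    writers: tuple[str, ...]
    trials_per_letter: int
    manifest: dict

    def __len__(self) -> int:
        return len(self.trials)


def _trial_rng(seed: int, wi: int, li: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([seed, wi, li, trial])


def build_corpus(styles: Sequence[WriterStyle] | None = None,
                 trials_per_letter: int = 40, seed: int = 0,
                 letters: Sequence[str] | None = None,
                 cfg: GenerationConfig | None = None) -> Corpus:
    """Build a labelled corpus of synthetic trials.

    Every trial's generator is seeded from ``(seed, writer, letter, trial)``
    so the corpus is bit-identical under replay and each trajectory is
    reconstructible from the manifest alone.
    """
    if styles is None:
        styles = default_styles()
    if not styles or trials_per_letter < 1:
        raise InvalidInputError("need at least one style and one trial per letter")
    protos = default_prototypes()
    letters = tuple(letters) if letters is not None else tuple(sorted(protos))
    trials: list[Trial] = []
    for wi, style in enumerate(styles):
        for li, letter in enumerate(letters):
            for k in range(trials_per_letter):
                traj = synthesize_trial(protos[letter], style, _trial_rng(seed, wi, li, k), cfg)
                trials.append(Trial(letter, style.name, k, traj))
    manifest = {
        "seed": seed,
        "letters": list(letters),
        "trials_per_letter": trials_per_letter,
        "n_trajectories": len(trials),
        "styles": [
            {"name": s.name, "slant_deg": s.slant_deg, "scale_x": s.scale_x,
             "scale_y": s.scale_y, "roundness": s.roundness,
             "jitter_pos": s.jitter_pos, "jitter_vel": s.jitter_vel,
             "allograph_probs": list(s.allograph_probs)}
            for s in styles
        ],
    }
    return Corpus(trials, letters, tuple(s.name for s in styles),
                  trials_per_letter, manifest)


def corpus_from_manifest(manifest: dict) -> Corpus:
    styles = tuple(WriterStyle(
        name=s["name"], slant_deg=s["slant_deg"], scale_x=s["scale_x"],
        scale_y=s["scale_y"], roundness=s["roundness"],
        jitter_pos=s["jitter_pos"], jitter_vel=s["jitter_vel"],
        allograph_probs=tuple(s["allograph_probs"])) for s in manifest["styles"])
    return build_corpus(styles, manifest["trials_per_letter"], manifest["seed"],
                        letters=manifest["letters"])




# ---------------------------------------------------------------------------
# Evaluation harnesses

@dataclass
class EvalResult:
    """Aggregated cross-validated recognition performance."""

    task: str
    rate: float
    confusion: np.ndarray      # rows: true label, normalized to sum to 1
    labels: tuple[str, ...]
    fold_rates: list[float]
    n_test: int


def extract_corpus(corpus: Corpus, min_sep: float = 3.0) -> list[ViaPointSequence]:
    """Perceive every trial once (via-point sequences, trial order)."""
    return [robust_extract(tr.trajectory, min_sep) for tr in corpus.trials]


def _check_balanced(corpus: Corpus) -> dict[tuple[str, str, int], int]:
    index = {}
    for i, tr in enumerate(corpus.trials):
        index[(tr.writer, tr.letter, tr.index)] = i
    expected = len(corpus.writers) * len(corpus.letters) * corpus.trials_per_letter
    if len(index) != expected or len(corpus.trials) != expected:
        raise InvalidInputError("corpus is not balanced over writer x letter x trial")
    return index


def _fit_fold(corpus, sequences, train_ids):
    from .representation import SmoothingConfig, fit_letter_model
    from .trajectory import discretize_sequence, fit_grid
    grid = fit_grid(sequences[i] for i in train_ids)
    triples = ((corpus.trials[i].letter, corpus.trials[i].writer,
                discretize_sequence(sequences[i], grid)) for i in train_ids)
    return fit_letter_model(triples, corpus.letters, corpus.writers, grid)


def kfold_evaluate(corpus: Corpus, task: str = "letter", k: int = 8,
                   seed: int = 0, sequences: list[ViaPointSequence] | None = None,
                   cfg: GenerationConfig | None = None,
                   answer_policy: str = "sample") -> EvalResult:
    """K-fold cross-validated recognition on a balanced corpus.

    Per fold, the model is fitted on the training split and each test trial
    is answered by drawing from the task posterior (not its argmax), which
    is the protocol the recognition rates refer to; ``answer_policy="argmax"``
    switches to deterministic answers.  ``task`` is one of
    ``letter`` (writer known), ``letter_marginal`` (writer unknown),
    ``writer`` (letter known) or ``letter_with_simulation``.
    """
    from scipy.special import logsumexp, softmax
    from .tasks import simulate_percept
    from .trajectory import discretize_sequence

    if task not in ("letter", "letter_marginal", "writer", "letter_with_simulation"):
        raise InvalidInputError(f"unknown task {task!r}")
    if corpus.trials_per_letter % k != 0:
        raise InvalidInputError(f"{k} folds must divide {corpus.trials_per_letter} trials")
    _check_balanced(corpus)
    if sequences is None:
        sequences = extract_corpus(corpus)
    rng = np.random.default_rng(seed)

    # per-(writer, letter) seeded permutation of trial indices into folds
    fold_of = np.empty(len(corpus.trials), dtype=int)
    by_cell: dict[tuple[str, str], list[int]] = {}
    for i, tr in enumerate(corpus.trials):
        by_cell.setdefault((tr.writer, tr.letter), []).append(i)
    per_fold = corpus.trials_per_letter // k
    for cell_ids in by_cell.values():
        perm = rng.permutation(len(cell_ids))
        for pos_in_cell, j in enumerate(perm):
            fold_of[cell_ids[j]] = pos_in_cell // per_fold

    if task == "writer":
        labels = corpus.writers
    else:
        labels = corpus.letters
    lab_idx = {s: i for i, s in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)))
    fold_rates: list[float] = []
    n_test = 0
    sim_cache: dict[int, ViaPointSequence] = {}

    for f in range(k):
        train_ids = [i for i in range(len(corpus.trials)) if fold_of[i] != f]
        test_ids = [i for i in range(len(corpus.trials)) if fold_of[i] == f]
        model = _fit_fold(corpus, sequences, train_ids)
        correct = 0
        for i in test_ids:
            tr = corpus.trials[i]
            bins = discretize_sequence(sequences[i], model.grid)
            m = model.log_score_matrix(bins)
            if task == "letter":
                log_ev = m[model.writer_index(tr.writer)]
                truth = tr.letter
            elif task == "letter_marginal":
                log_ev = logsumexp(m, axis=0)
                truth = tr.letter
            elif task == "writer":
                log_ev = m[:, model.letter_index(tr.letter)]
                truth = tr.writer
            else:  # letter_with_simulation
                if i not in sim_cache:
                    sim_traj = generate_trajectory(sequences[i], cfg)
                    sim_cache[i] = robust_extract(sim_traj)
                sim_bins = discretize_sequence(sim_cache[i], model.grid)
                log_ev = (m + model.log_score_matrix(sim_bins))[model.writer_index(tr.writer)]
                truth = tr.letter
            probs = softmax(log_ev)
            if answer_policy == "argmax":
                ans = labels[int(np.argmax(probs))]
            else:
                ans = labels[int(rng.choice(len(labels), p=probs))]
            confusion[lab_idx[truth], lab_idx[ans]] += 1
            correct += ans == truth
        fold_rates.append(correct / len(test_ids))
        n_test += len(test_ids)

    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(confusion, row_sums, out=np.zeros_like(confusion),
                          where=row_sums > 0)
    rate = float(np.average(fold_rates))
    return EvalResult(task, rate, confusion, tuple(labels), fold_rates, n_test)


def novel_writer_evaluate(corpus: Corpus, seed: int = 0,
                          sequences: list[ViaPointSequence] | None = None) -> EvalResult:
    """Leave-one-writer-out letter recognition.

    For each writer, the model is trained on the other writers and every
    trial of the held-out writer is recognized with the writer unknown
    (marginalized).  This is strictly harder than the within-writer
    protocol because the test style was never observed.
    """
    from scipy.special import logsumexp, softmax
    from .trajectory import discretize_sequence

    _check_balanced(corpus)
    if sequences is None:
        sequences = extract_corpus(corpus)
    rng = np.random.default_rng(seed)
    labels = corpus.letters
    lab_idx = {s: i for i, s in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)))
    fold_rates: list[float] = []
    n_test = 0
    for held_out in corpus.writers:
        train_ids = [i for i, tr in enumerate(corpus.trials) if tr.writer != held_out]
        test_ids = [i for i, tr in enumerate(corpus.trials) if tr.writer == held_out]
        sub = Corpus([corpus.trials[i] for i in train_ids], corpus.letters,
                     tuple(w for w in corpus.writers if w != held_out),
                     corpus.trials_per_letter, corpus.manifest)
        model = _fit_fold(sub, [sequences[i] for i in train_ids],
                          list(range(len(train_ids))))
        correct = 0
        for i in test_ids:
            tr = corpus.trials[i]
            bins = discretize_sequence(sequences[i], model.grid)
            log_ev = logsumexp(model.log_score_matrix(bins), axis=0)
            ans = labels[int(rng.choice(len(labels), p=softmax(log_ev)))]
            confusion[lab_idx[tr.letter], lab_idx[ans]] += 1
            correct += ans == tr.letter
        fold_rates.append(correct / len(test_ids))
        n_test += len(test_ids)
    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(confusion, row_sums, out=np.zeros_like(confusion),
                          where=row_sums > 0)
    return EvalResult("letter_novel_writer", float(np.average(fold_rates)),
                      confusion, tuple(labels), fold_rates, n_test)
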