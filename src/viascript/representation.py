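"""Probabilistic letter representation.

A letter, as written by a given writer, is modelled as a first-order Markov
chain over its discretized via-points, with the four dimensions (x, y, vx,
vy) conditionally independent given letter and writer.  Every conditional
distribution is a Laplace succession law

    P(v | context) = (n_v + 1) / (n + K)

over K discrete values (41 position bins, 7 velocity bins), so that the
model is uniform before any observation and never assigns probability zero.
Because the number of free parameters vastly exceeds the corpus size, the
observation counts are smoothed with a binomial filter (width 9 for
position dimensions, width 7 for velocity dimensions) before the Laplace
conversion, generalizing each observation to neighbouring bins.

Via-point sequences vary in length between letters and allographs, so the
model also carries a Laplace-smoothed distribution over sequence length
N in 2..16 per (letter, writer); recognition scores only observed indices
plus the length term, which keeps sequences of different length comparable
in one posterior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidConfigError, InvalidInputError, UnknownLabelError
from .trajectory import (GridSpec, MAX_VIAPOINTS, N_POS_BINS, N_VEL_BINS, VEL_BIN_MAX)

MIN_SEQ_LEN = 2
N_LENGTHS = MAX_VIAPOINTS - MIN_SEQ_LEN + 1  # N in 2..16

MODEL_FORMAT_VERSION = 1


def laplace_probability(count_v: float, n: float, k: int) -> float:
    """Laplace succession law: (count_v + 1) / (n + K).

    Uniform (1/K) before any observation; never zero.
    """
    if count_v < 0 or n < count_v or k < 2:
        raise InvalidInputError(
            f"need 0 <= count_v <= n and K >= 2, got ({count_v}, {n}, {k})"
        )
    return (count_v + 1.0) / (n + k)


def binomial_kernel(width: int) -> np.ndarray:
    """Normalized binomial filter coefficients C(w-1, i) / 2**(w-1)."""
    if width < 1 or width % 2 == 0:
        raise InvalidConfigError(f"binomial filter width must be odd, got {width}")
    row = np.array([1.0])
    for _ in range(width - 1):
        row = np.convolve(row, [1.0, 1.0])
    return row / row.sum()


def _smooth_axis(counts: np.ndarray, width: int) -> np.ndarray:
    """Binomial smoothing along the last axis, boundary-truncated.

    The kernel is renormalized per position by the in-range kernel mass (so
    a uniform vector is a fixed point), then each vector is rescaled so its
    total count is preserved.
    """
    if width == 1:
        return counts.astype(float)
    kernel = binomial_kernel(width)
    k = counts.shape[-1]
    pad = width // 2
    # zero-padded convolution along last axis
    flat = counts.reshape(-1, k).astype(float)
    padded = np.zeros((flat.shape[0], k + 2 * pad))
    padded[:, pad:pad + k] = flat
    out = np.zeros_like(flat)
    norm = np.zeros(k)
    ones = np.zeros(k + 2 * pad)
    ones[pad:pad + k] = 1.0
    for i, w in enumerate(kernel):
        out += w * padded[:, i:i + k]
        norm += w * ones[i:i + k]
    out /= norm  # per-position boundary renormalization
    before = flat.sum(axis=1, keepdims=True)
    after = out.sum(axis=1, keepdims=True)
    scale = np.divide(before, after, out=np.ones_like(before), where=after > 0)
    return (out * scale).reshape(counts.shape)


@dataclass
class SmoothingConfig:
    """Binomial smoothing widths.

    ``pos_width``/``vel_width`` smooth each conditional count vector along
    its value axis.  ``context_pos_width``/``context_vel_width`` smooth the
    transition counts along the conditioning (previous-value) axis as well
    — kernel regression across contexts — so that a query or a sampled
    value one bin away from the training support does not fall into an
    empty context.  A width of 1 disables the corresponding smoothing.
    """

    pos_width: int = 9
    vel_width: int = 7
    context_pos_width: int = 9
    context_vel_width: int = 7

    def __post_init__(self):
        for w in (self.pos_width, self.vel_width,
                  self.context_pos_width, self.context_vel_width):
            if w < 1 or w % 2 == 0:
                raise InvalidConfigError("smoothing widths must be odd and >= 1")


@dataclass
class CountTable:
    """Raw (or smoothed) observation counts of the letter model.

    Array shapes, with W writers and L letters:

    - ``init_pos``:  (W, L, 2, 41)            first via-point, dims x, y
    - ``init_vel``:  (W, L, 2, 7)             first via-point, dims vx, vy
    - ``trans_pos``: (W, L, 15, 2, 41, 41)    index j = 1..15, prev x cur
    - ``trans_vel``: (W, L, 15, 2, 7, 7)
    - ``length``:    (W, L, 15)               sequence length N in 2..16
    """

    init_pos: np.ndarray
    init_vel: np.ndarray
    trans_pos: np.ndarray
    trans_vel: np.ndarray
    length: np.ndarray

    @staticmethod
    def zeros(n_writers: int, n_letters: int) -> "CountTable":
        W, L, J = n_writers, n_letters, MAX_VIAPOINTS - 1
        return CountTable(
            init_pos=np.zeros((W, L, 2, N_POS_BINS)),
            init_vel=np.zeros((W, L, 2, N_VEL_BINS)),
            trans_pos=np.zeros((W, L, J, 2, N_POS_BINS, N_POS_BINS)),
            trans_vel=np.zeros((W, L, J, 2, N_VEL_BINS, N_VEL_BINS)),
            length=np.zeros((W, L, N_LENGTHS)),
        )

    def add_sequence(self, w: int, l: int, bins: np.ndarray, weight: float = 1.0) -> None:
        bins = np.asarray(bins, dtype=int)
        n = len(bins)
        if not (MIN_SEQ_LEN <= n <= MAX_VIAPOINTS):
            raise InvalidInputError(f"sequence length {n} outside [2, 16]")
        vx = bins[:, 2] + VEL_BIN_MAX  # shift -3..3 to 0..6
        vy = bins[:, 3] + VEL_BIN_MAX
        self.init_pos[w, l, 0, bins[0, 0]] += weight
        self.init_pos[w, l, 1, bins[0, 1]] += weight
        self.init_vel[w, l, 0, vx[0]] += weight
        self.init_vel[w, l, 1, vy[0]] += weight
        for j in range(1, n):
            self.trans_pos[w, l, j - 1, 0, bins[j - 1, 0], bins[j, 0]] += weight
            self.trans_pos[w, l, j - 1, 1, bins[j - 1, 1], bins[j, 1]] += weight
            self.trans_vel[w, l, j - 1, 0, vx[j - 1], vx[j]] += weight
            self.trans_vel[w, l, j - 1, 1, vy[j - 1], vy[j]] += weight
        self.length[w, l, n - MIN_SEQ_LEN] += weight


def smooth_counts(table: CountTable, pos_width: int = 9, vel_width: int = 7) -> CountTable:
    """Binomial smoothing of counts along the current-bin axis.

    Position dimensions use a width-9 kernel, velocity dimensions width 7;
    the per-context totals are preserved to 1e-9.  The length table is not
    smoothed (its bins are not metrically adjacent letterforms).
    """
    return CountTable(
        init_pos=_smooth_axis(table.init_pos, pos_width),
        init_vel=_smooth_axis(table.init_vel, vel_width),
        trans_pos=_smooth_axis(table.trans_pos, pos_width),
        trans_vel=_smooth_axis(table.trans_vel, vel_width),
        length=table.length.astype(float),
    )


def smooth_contexts(table: CountTable, pos_width: int = 9, vel_width: int = 7) -> CountTable:
    """Binomial smoothing of transition counts along the previous-bin axis.

    Generalizes each observed transition to neighbouring conditioning
    values; initial and length tables have no conditioning value and are
    untouched.
    """
    def along_prev(arr: np.ndarray, width: int) -> np.ndarray:
        return np.swapaxes(_smooth_axis(np.swapaxes(arr, -1, -2), width), -1, -2)

    return CountTable(
        init_pos=table.init_pos.astype(float),
        init_vel=table.init_vel.astype(float),
        trans_pos=along_prev(table.trans_pos, pos_width),
        trans_vel=along_prev(table.trans_vel, vel_width),
        length=table.length.astype(float),
    )


def _laplace_tables(counts: CountTable) -> dict[str, np.ndarray]:
    def conv(arr: np.ndarray) -> np.ndarray:
        k = arr.shape[-1]
        n = arr.sum(axis=-1, keepdims=True)
        return (arr + 1.0) / (n + k)
    return {
        "init_pos": conv(counts.init_pos),
        "init_vel": conv(counts.init_vel),
        "trans_pos": conv(counts.trans_pos),
        "trans_vel": conv(counts.trans_vel),
        "length": conv(counts.length),
    }


_TABLE_KEYS = ("init_pos", "init_vel", "trans_pos", "trans_vel", "length")


@dataclass
class LetterModel:
    """Fitted probabilistic representation of letters.

    Holds the smoothed observation counts, the discretization grid and the
    label sets.  Two views of the counts are derived and cached:

    - ``probs``: Laplace succession laws, used for recognition scoring —
      strictly positive, uniform where nothing was observed;
    - sampling tables: the normalized smoothed counts themselves (the
      empirical predictive), used by ancestral sampling so that written
      letters are typical of the training data rather than diluted by the
      Laplace floor (which holds a large share of each conditional's mass
      when the value domain is much larger than the per-context counts).
      Contexts with no mass at all fall back to the Laplace law.
    """

    letters: tuple[str, ...]
    writers: tuple[str, ...]
    grid: GridSpec
    smoothing: SmoothingConfig
    counts: dict[str, np.ndarray]  # raw observation counts
    _probs: dict[str, np.ndarray] | None = field(default=None, repr=False)
    _logs: dict[str, np.ndarray] | None = field(default=None, repr=False)
    _samp: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self):
        self.letters = tuple(self.letters)
        self.writers = tuple(self.writers)

    @property
    def probs(self) -> dict[str, np.ndarray]:
        """Scoring tables: value- and context-smoothed Laplace laws."""
        if self._probs is None:
            s = self.smoothing
            t = smooth_counts(self.count_table(), s.pos_width, s.vel_width)
            t = smooth_contexts(t, s.context_pos_width, s.context_vel_width)
            self._probs = _laplace_tables(t)
        return self._probs

    @property
    def logs(self) -> dict[str, np.ndarray]:
        if self._logs is None:
            self._logs = {k: np.log(v) for k, v in self.probs.items()}
        return self._logs

    @property
    def sampling_tables(self) -> dict[str, np.ndarray]:
        """Production tables: context-smoothed empirical distributions.

        Values stay on the training support (no value-axis smoothing and
        no Laplace floor, both of which exist to score unseen inputs, not
        to write with); contexts with no mass fall back to the Laplace
        law.
        """
        if self._samp is None:
            s = self.smoothing
            t = smooth_contexts(self.count_table(), s.context_pos_width,
                                s.context_vel_width)
            out = {}
            for key in _TABLE_KEYS:
                c = getattr(t, key)
                n = c.sum(axis=-1, keepdims=True)
                emp = np.divide(c, n, out=np.zeros_like(c), where=n > 0)
                out[key] = np.where(n > 0, emp, self.probs[key])
            self._samp = out
        return self._samp

    def count_table(self) -> CountTable:
        return CountTable(**{k: self.counts[k] for k in _TABLE_KEYS})

    # -- label handling --------------------------------------------------
    def letter_index(self, letter: str) -> int:
        try:
            return self.letters.index(letter)
        except ValueError:
            raise UnknownLabelError(f"unknown letter {letter!r}")

    def writer_index(self, writer: str) -> int:
        try:
            return self.writers.index(writer)
        except ValueError:
            raise UnknownLabelError(f"unknown writer {writer!r}")

    # -- scoring ---------------------------------------------------------
    def log_score_matrix(self, bins: np.ndarray) -> np.ndarray:
        """Log-likelihood of a discrete sequence under every (writer, letter).

        Sum over via-point indices and the four dimensions of the log
        conditional probabilities, plus the log probability of the sequence
        length.  Returns a (W, L) array.
        """
        bins = np.asarray(bins, dtype=int)
        n = len(bins)
        if not (MIN_SEQ_LEN <= n <= MAX_VIAPOINTS):
            raise InvalidInputError(f"sequence length {n} outside [2, 16]")
        lg = self.logs
        vx = bins[:, 2] + VEL_BIN_MAX
        vy = bins[:, 3] + VEL_BIN_MAX
        total = (lg["init_pos"][:, :, 0, bins[0, 0]] + lg["init_pos"][:, :, 1, bins[0, 1]]
                 + lg["init_vel"][:, :, 0, vx[0]] + lg["init_vel"][:, :, 1, vy[0]])
        for j in range(1, n):
            total = total + (
                lg["trans_pos"][:, :, j - 1, 0, bins[j - 1, 0], bins[j, 0]]
                + lg["trans_pos"][:, :, j - 1, 1, bins[j - 1, 1], bins[j, 1]]
                + lg["trans_vel"][:, :, j - 1, 0, vx[j - 1], vx[j]]
                + lg["trans_vel"][:, :, j - 1, 1, vy[j - 1], vy[j]]
            )
        total = total + lg["length"][:, :, n - MIN_SEQ_LEN]
        return total

    # -- serialization ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "letters": list(self.letters),
            "writers": list(self.writers),
            "grid": {"x_min": self.grid.x_min, "y_min": self.grid.y_min,
                     "x_step": self.grid.x_step, "y_step": self.grid.y_step,
                     "v_step": self.grid.v_step},
            "smoothing": {"pos_width": self.smoothing.pos_width,
                          "vel_width": self.smoothing.vel_width,
                          "context_pos_width": self.smoothing.context_pos_width,
                          "context_vel_width": self.smoothing.context_vel_width},
        }
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                            **self.counts)

    @staticmethod
    def load(path) -> "LetterModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format_version") != MODEL_FORMAT_VERSION:
                raise InvalidInputError(
                    f"unsupported model format version {meta.get('format_version')}")
            counts = {k: data[k] for k in _TABLE_KEYS}
        return LetterModel(
            letters=tuple(meta["letters"]),
            writers=tuple(meta["writers"]),
            grid=GridSpec(**meta["grid"]),
            smoothing=SmoothingConfig(**meta["smoothing"]),
            counts=counts,
        )


def fit_letter_model(corpus: Iterable[tuple[str, str, np.ndarray]],
                     letters: Sequence[str], writers: Sequence[str],
                     grid: GridSpec,
                     smoothing: SmoothingConfig | None = None) -> LetterModel:
    """Fit the letter model by counting observations in a labelled corpus.

    ``corpus`` yields ``(letter, writer, bins)`` triples where ``bins`` is a
    discretized via-point sequence.  Counting is followed by binomial
    smoothing of the counts and Laplace conversion to probabilities.
    """
    letters = tuple(letters)
    writers = tuple(writers)
    smoothing = smoothing or SmoothingConfig()
    table = CountTable.zeros(len(writers), len(letters))
    n_seen = 0
    lmap = {s: i for i, s in enumerate(letters)}
    wmap = {s: i for i, s in enumerate(writers)}
    for letter, writer, bins in corpus:
        if letter not in lmap:
            raise UnknownLabelError(f"letter {letter!r} not in declared letter set")
        if writer not in wmap:
            raise UnknownLabelError(f"writer {writer!r} not in declared writer set")
        table.add_sequence(wmap[writer], lmap[letter], bins)
        n_seen += 1
    if n_seen == 0:
        raise InvalidInputError("cannot fit a model on an empty corpus")
    counts = {k: getattr(table, k).astype(float) for k in _TABLE_KEYS}
    return LetterModel(letters, writers, grid, smoothing, counts)


def untrained_model(letters: Sequence[str], writers: Sequence[str],
                    grid: GridSpec | None = None) -> LetterModel:
    """A model with uniform Laplace-floor tables (zero observations)."""
    table = CountTable.zeros(len(writers), len(letters))
    counts = {k: getattr(table, k).astype(float) for k in _TABLE_KEYS}
    return LetterModel(tuple(letters), tuple(writers), grid or GridSpec.unit(),
                       SmoothingConfig(), counts)


def sequence_log_score(bins: np.ndarray, letter: str, writer: str,
                       model: LetterModel) -> float:
    """Log-probability of one discrete sequence under one (letter, writer)."""
    w = model.writer_index(writer)
    l = model.letter_index(letter)
    return float(model.log_score_matrix(bins)[w, l])


def _allowed_vel_signs(prev_delta: int | None, next_delta: int | None) -> set[int]:
    """Velocity signs compatible with the sampled displacements at a point.

    Passing straight through (both displacements in one direction) forces
    that sign — a zero velocity there would add a tangent the positions do
    not support.  A positional extremum (displacement signs flip) forces a
    zero.  At the stroke ends, or next to a zero displacement, the single
    moving direction or a tangent are both admissible.
    """
    signs = set()
    for d in (prev_delta, next_delta):
        if d is not None and d != 0:
            signs.add(1 if d > 0 else -1)
    if len(signs) == 1:
        s = signs.pop()
        if prev_delta is not None and next_delta is not None \
                and prev_delta != 0 and next_delta != 0:
            return {s}
        return {0, s}
    return {0}


def sample_viapoint_sequence(letter: str, writer: str, model: LetterModel,
                             rng: np.random.Generator,
                             kinematic: bool = False) -> np.ndarray:
    """Ancestral sampling of a discrete via-point sequence.

    Draws the length N from the per-(letter, writer) length distribution,
    then samples each dimension of each via-point from its conditional
    table given the previous via-point.  Sampling uses the empirical
    predictive tables (normalized smoothed counts; see
    :class:`LetterModel`).  Deterministic given the generator state.

    With ``kinematic=True`` the velocity chains are sampled *after* the
    position chains, restricted to velocity signs compatible with the
    sampled displacements (a velocity cannot point against the motion
    through its via-point, and a positional extremum forces a tangent).
    The position and velocity chains are conditionally independent given
    letter and writer, so this ordering does not change the model — only
    the admissibility projection does.
    """
    w = model.writer_index(writer)
    l = model.letter_index(letter)
    p = model.sampling_tables
    n = MIN_SEQ_LEN + rng.choice(N_LENGTHS, p=_norm(p["length"][w, l]))
    out = np.zeros((n, 4), dtype=int)
    # position chains first (dims 0, 1)
    for d in range(2):
        out[0, d] = rng.choice(N_POS_BINS, p=_norm(p["init_pos"][w, l, d]))
        for j in range(1, n):
            out[j, d] = rng.choice(
                N_POS_BINS, p=_norm(p["trans_pos"][w, l, j - 1, d, out[j - 1, d]]))
    # velocity chains (dims 2, 3), optionally sign-restricted
    for d in range(2):
        deltas = np.diff(out[:, d])
        mask = np.ones(N_VEL_BINS)
        if kinematic:
            mask = _sign_mask(_allowed_vel_signs(None, int(deltas[0]) if n > 1 else None))
        out[0, 2 + d] = _draw_vel(p["init_vel"][w, l, d], mask, rng)
        for j in range(1, n):
            row = p["trans_vel"][w, l, j - 1, d, out[j - 1, 2 + d] + VEL_BIN_MAX]
            mask = np.ones(N_VEL_BINS)
            if kinematic:
                prev_d = int(deltas[j - 1])
                next_d = int(deltas[j]) if j < n - 1 else None
                mask = _sign_mask(_allowed_vel_signs(prev_d, next_d))
            out[j, 2 + d] = _draw_vel(row, mask, rng)
    return out


_VEL_VALUES = np.arange(N_VEL_BINS) - VEL_BIN_MAX


def _sign_mask(signs: set[int]) -> np.ndarray:
    return np.isin(np.sign(_VEL_VALUES), sorted(signs)).astype(float)


def _draw_vel(row: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> int:
    masked = row * mask
    if masked.sum() <= 0:
        masked = mask  # uniform over the admissible signs
    return int(rng.choice(N_VEL_BINS, p=_norm(masked))) - VEL_BIN_MAX


def _norm(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def count_free_parameters(n_writers: int, n_letters: int, pos_bins: int = N_POS_BINS,
                          vel_bins: int = N_VEL_BINS, order: int = 1,
                          joint: bool = False) -> int:
    """Free-parameter count of the per-index conditional tables.

    Separable case (dimensions independent given letter and writer): two
    position chains and two velocity chains of the given Markov order, each
    conditional distribution contributing K - 1 free parameters:

        2 * W * L * P**order * (P - 1)  +  2 * W * L * V**order * (V - 1)

    Joint (non-separable) first-order case: one table over the full
    four-dimensional domain of size P**2 * V**2:

        W * L * (P**2 V**2) * (P**2 V**2 - 1)
    """
    if n_writers < 1 or n_letters < 1 or pos_bins < 2 or vel_bins < 2:
        raise InvalidInputError("domain sizes must be positive (bins >= 2)")
    if order not in (1, 2, 3):
        raise InvalidInputError(f"order must be 1, 2 or 3, got {order}")
    if joint and order != 1:
        raise InvalidInputError("the joint table is only defined at order 1")
    W, L, P, V = int(n_writers), int(n_letters), int(pos_bins), int(vel_bins)
    if joint:
        d = P * P * V * V
        return W * L * d * (d - 1)
    return 2 * W * L * P ** order * (P - 1) + 2 * W * L * V ** order * (V - 1)
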