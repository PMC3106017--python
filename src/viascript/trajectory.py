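"""Pen trajectories and their via-point representation.

A planar pen trajectory is a uniformly sampled ``(t, x, y)`` series.  The
perceptual code of a letter is the ordered sequence of *via-points*: the
start and end of the stroke plus every interior point where the horizontal
or the vertical velocity component vanishes (horizontal/vertical tangents)
or where both do (cusps).  Each via-point is four-dimensional, carrying
position ``(x, y)`` and velocity ``(vx, vy)``.

For probabilistic modelling the continuous via-points are discretized onto
a fixed grid: positions onto 41 integer bins (0..40) of a canonical writing
box, velocities onto 7 integer bins (-3..3).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidGridError, InvalidInputError, TrajectoryParseError, ViaPointOverflowError

MAX_VIAPOINTS = 16
N_POS_BINS = 41  # integer bins 0..40
N_VEL_BINS = 7   # integer bins -3..3
VEL_BIN_MAX = 3


class ViaPointKind(str, Enum):
    START = "start"
    END = "end"
    HORIZONTAL_TANGENT = "horizontal_tangent"  # vy == 0
    VERTICAL_TANGENT = "vertical_tangent"      # vx == 0
    CUSP = "cusp"                              # vx == vy == 0


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled planar pen path.

    Invariants: equal lengths >= 2, strictly increasing `t` with a constant
    step (to 1e-9 relative), all values finite.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (t.ndim == x.ndim == y.ndim == 1):
            raise InvalidInputError("t, x, y must be one-dimensional")
        if not (len(t) == len(x) == len(y)):
            raise InvalidInputError("t, x, y must have equal length")
        if len(t) < 2:
            raise InvalidInputError("a trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise InvalidInputError("trajectory values must be finite")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise InvalidInputError("time stamps must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > 1e-9 * max(abs(dt), 1.0)):
            raise InvalidInputError("time step must be uniform (1e-9 relative)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def translated(self, dx: float, dy: float) -> "Trajectory":
        return Trajectory(self.t, self.x + dx, self.y + dy)


@dataclass(frozen=True)
class ViaPoint:
    """One four-dimensional via-point with its geometric kind.

    ``sample_index`` is the (fractional) index into the source trajectory at
    which the point was located; purely synthetic via-points may use any
    increasing values.
    """

    x: float
    y: float
    vx: float
    vy: float
    kind: ViaPointKind
    sample_index: float = 0.0

    def check(self, eps: float) -> None:
        if self.kind is ViaPointKind.HORIZONTAL_TANGENT and abs(self.vy) > eps:
            raise InvalidInputError(f"horizontal tangent with |vy|={abs(self.vy)} > {eps}")
        if self.kind is ViaPointKind.VERTICAL_TANGENT and abs(self.vx) > eps:
            raise InvalidInputError(f"vertical tangent with |vx|={abs(self.vx)} > {eps}")
        if self.kind is ViaPointKind.CUSP and (abs(self.vx) > eps or abs(self.vy) > eps):
            raise InvalidInputError("cusp with non-zero velocity")


@dataclass(frozen=True)
class ViaPointSequence:
    """Ordered via-points of a single stroke (2..16 points)."""

    points: tuple[ViaPoint, ...]

    def __post_init__(self):
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if not (2 <= len(pts) <= MAX_VIAPOINTS):
            raise InvalidInputError(
                f"a via-point sequence has 2..{MAX_VIAPOINTS} points, got {len(pts)}"
            )
        if pts[0].kind is not ViaPointKind.START:
            raise InvalidInputError("first via-point must have kind 'start'")
        if pts[-1].kind is not ViaPointKind.END:
            raise InvalidInputError("last via-point must have kind 'end'")
        idx = [p.sample_index for p in pts]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InvalidInputError("sample_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def positions(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points])

    def velocities(self) -> np.ndarray:
        return np.array([[p.vx, p.vy] for p in self.points])

    def kinds(self) -> tuple[ViaPointKind, ...]:
        return tuple(p.kind for p in self.points)


@dataclass(frozen=True)
class GridSpec:
    """Mapping between trajectory units and the discrete via-point grid.

    Positions map affinely onto 41 bins (0..40) of a canonical writing box;
    velocities scale linearly onto 7 bins (-3..3), with ``v_step`` units per
    velocity bin.  The same grid is used for discretization and for
    reconstructing continuous coordinates from bins (bin centers), so
    discretize(undiscretize(b)) == b for every bin.
    """

    x_min: float
    y_min: float
    x_step: float
    y_step: float
    v_step: float

    def __post_init__(self):
        if not (self.x_step > 0 and self.y_step > 0 and self.v_step > 0):
            raise InvalidGridError("grid steps must be strictly positive")

    # -- positions -------------------------------------------------------
    def pos_to_bins(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        xb = np.clip(np.rint((np.asarray(x, float) - self.x_min) / self.x_step), 0, N_POS_BINS - 1)
        yb = np.clip(np.rint((np.asarray(y, float) - self.y_min) / self.y_step), 0, N_POS_BINS - 1)
        return xb.astype(int), yb.astype(int)

    def bins_to_pos(self, xb, yb) -> tuple[np.ndarray, np.ndarray]:
        return (self.x_min + np.asarray(xb, float) * self.x_step,
                self.y_min + np.asarray(yb, float) * self.y_step)

    # -- velocities ------------------------------------------------------
    def vel_to_bins(self, v) -> np.ndarray:
        b = np.clip(np.rint(np.asarray(v, float) / self.v_step), -VEL_BIN_MAX, VEL_BIN_MAX)
        return b.astype(int)

    def bins_to_vel(self, vb) -> np.ndarray:
        return np.asarray(vb, float) * self.v_step

    @staticmethod
    def unit() -> "GridSpec":
        """Identity-like grid: the canonical 0..40 box, one unit per bin."""
        return GridSpec(x_min=0.0, y_min=0.0, x_step=1.0, y_step=1.0, v_step=5.0)


def estimate_velocities(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference velocity estimate.

    Central differences at interior samples, one-sided differences at the
    two ends (this is exactly ``numpy.gradient`` on a uniform grid).
    """
    if len(traj) < 2:
        raise InvalidInputError("need at least 2 samples to estimate velocities")
    dt = traj.dt
    return np.gradient(traj.x, dt), np.gradient(traj.y, dt)


def _component_detections(v: np.ndarray, eps: float, min_sep: float,
                          touch_tol: float = 0.0) -> list[float]:
    """Fractional sample indices where one velocity component vanishes.

    Three mechanisms, per the extractor's discrete-sampling policy:
    sign changes between consecutive samples (sub-sample root by linear
    interpolation); dwells (runs of >= 2 samples with |v| < eps, which
    collapse to the run midpoint); and touches (an isolated local minimum
    of |v| below ``touch_tol`` without a sign change, as happens at a cusp
    or tangent that the sampling grid straddles).  Detections closer than
    ``min_sep`` to either trajectory end are dropped (start/end are
    via-points already).
    """
    n = len(v)
    roots: list[float] = []

    # dwell runs: |v| < eps over >= 2 consecutive samples
    small = np.abs(v) < eps
    i = 0
    covered = np.zeros(n, dtype=bool)
    while i < n:
        if small[i]:
            j = i
            while j + 1 < n and small[j + 1]:
                j += 1
            if j > i:  # run of length >= 2
                # a run reaching both trajectory ends means the component
                # is flat throughout and carries no landmark at all
                if not (i <= min_sep and j >= (n - 1) - min_sep):
                    roots.append((i + j) / 2.0)
                covered[i:j + 1] = True
            i = j + 1
        else:
            i += 1

    # strict sign changes between consecutive samples
    for i in range(n - 1):
        if covered[i] or covered[i + 1]:
            continue
        a, b = v[i], v[i + 1]
        if a == 0.0:
            # exact isolated zero: count once, at the sample itself
            if 0 < i and v[i - 1] * b < 0:
                roots.append(float(i))
            continue
        if a * b < 0:
            roots.append(i + a / (a - b))

    # touches: |v| dips near zero and recovers with the same sign
    if touch_tol > 0:
        av = np.abs(v)
        for i in range(1, n - 1):
            if covered[i] or av[i] >= touch_tol:
                continue
            if av[i] <= av[i - 1] and av[i] < av[i + 1] and v[i - 1] * v[i + 1] > 0:
                denom = av[i - 1] - 2 * av[i] + av[i + 1]
                off = 0.5 * (av[i - 1] - av[i + 1]) / denom if denom > 0 else 0.0
                roots.append(i + float(np.clip(off, -0.5, 0.5)))

    lo, hi = min_sep, (n - 1) - min_sep
    return sorted(r for r in roots if lo <= r <= hi)


@dataclass(frozen=True)
class _Detection:
    frac: float
    axis: int  # 0 = vx zero (vertical tangent), 1 = vy zero (horizontal tangent)


def extract_viapoints(traj: Trajectory, eps: float | None = None,
                      min_sep: float = 3.0) -> ViaPointSequence:
    """Extract the via-point sequence of a trajectory.

    Returns the start point, the end point, and one interior via-point per
    zero of ``vx`` (vertical tangent) or ``vy`` (horizontal tangent), with
    sub-sample position and velocity by linear interpolation.  A zero of
    both components within ``min_sep`` samples merges into a single cusp;
    same-component detections closer than ``min_sep`` keep the one with the
    smaller interpolated speed.

    ``eps`` is the velocity-zero tolerance for dwell detection; by default
    1e-3 times the robust (95th percentile) peak speed of the trajectory.

    Raises :class:`ViaPointOverflowError` if more than 16 via-points result.
    """
    vx, vy = estimate_velocities(traj)
    speed_95 = float(np.percentile(np.hypot(vx, vy), 95))
    if eps is None:
        eps = 1e-3 * speed_95
        if eps <= 0:
            eps = 1e-12
    touch_tol = 0.035 * speed_95

    dets = [_Detection(f, 0) for f in _component_detections(vx, eps, min_sep, touch_tol)] + \
           [_Detection(f, 1) for f in _component_detections(vy, eps, min_sep, touch_tol)]
    dets.sort(key=lambda d: d.frac)

    def interp(arr: np.ndarray, f: float) -> float:
        i = int(math.floor(f))
        if i >= len(arr) - 1:
            return float(arr[-1])
        w = f - i
        return float((1 - w) * arr[i] + w * arr[i + 1])

    # merge passes: cross-axis pairs -> cusp; same-axis duplicates -> best.
    # Detections merge when close in samples or in space: near a cusp the
    # pen is slow, so two coincident zeros can straddle many samples.
    space_tol = 0.02 * math.hypot(np.ptp(traj.x), np.ptp(traj.y))

    def near(f1: float, f2: float) -> bool:
        if f2 - f1 < min_sep:
            return True
        dx = interp(traj.x, f2) - interp(traj.x, f1)
        dy = interp(traj.y, f2) - interp(traj.y, f1)
        return math.hypot(dx, dy) < space_tol

    merged: list[tuple[float, set[int]]] = []  # (frac, axes involved)
    for d in dets:
        if merged and near(merged[-1][0], d.frac):
            f_prev, axes = merged[-1]
            if d.axis not in axes:
                merged[-1] = ((f_prev + d.frac) / 2.0, axes | {d.axis})
            else:
                # same axis twice: keep the location with smaller residual speed
                sp_prev = math.hypot(interp(vx, f_prev), interp(vy, f_prev))
                sp_new = math.hypot(interp(vx, d.frac), interp(vy, d.frac))
                if sp_new < sp_prev:
                    merged[-1] = (d.frac, axes)
        else:
            merged.append((d.frac, {d.axis}))

    points: list[ViaPoint] = []
    n = len(traj)
    points.append(ViaPoint(float(traj.x[0]), float(traj.y[0]), float(vx[0]), float(vy[0]),
                           ViaPointKind.START, 0.0))
    for f, axes in merged:
        px, py = interp(traj.x, f), interp(traj.y, f)
        pvx, pvy = interp(vx, f), interp(vy, f)
        if axes == {0, 1}:
            kind, pvx, pvy = ViaPointKind.CUSP, 0.0, 0.0
        elif axes == {0}:
            kind, pvx = ViaPointKind.VERTICAL_TANGENT, 0.0
        else:
            kind, pvy = ViaPointKind.HORIZONTAL_TANGENT, 0.0
        points.append(ViaPoint(px, py, pvx, pvy, kind, f))
    points.append(ViaPoint(float(traj.x[-1]), float(traj.y[-1]), float(vx[-1]), float(vy[-1]),
                           ViaPointKind.END, float(n - 1)))

    if len(points) > MAX_VIAPOINTS:
        raise ViaPointOverflowError(len(points))
    return ViaPointSequence(tuple(points))


def robust_extract(traj: Trajectory, min_sep: float = 3.0,
                   max_retries: int = 3) -> ViaPointSequence:
    """Via-point extraction with a widening-separation fallback.

    Noisy or resampled trajectories occasionally yield more than 16
    detections; retrying with a larger merge window smooths duplicate
    detections away.  The overflow propagates if the retries are
    exhausted.
    """
    for attempt in range(max_retries + 1):
        try:
            return extract_viapoints(traj, min_sep=min_sep * (1.5 ** attempt))
        except ViaPointOverflowError:
            if attempt == max_retries:
                raise
    raise AssertionError("unreachable")


def discretize_sequence(seq: ViaPointSequence, grid: GridSpec) -> np.ndarray:
    """Discretize a via-point sequence onto the model grid.

    Returns an ``(N, 4)`` integer array with columns ``xb, yb, vxb, vyb``;
    position bins in 0..40, velocity bins in -3..3.
    """
    pos = seq.positions()
    vel = seq.velocities()
    xb, yb = grid.pos_to_bins(pos[:, 0], pos[:, 1])
    vxb = grid.vel_to_bins(vel[:, 0])
    vyb = grid.vel_to_bins(vel[:, 1])
    return np.column_stack([xb, yb, vxb, vyb]).astype(int)


def undiscretize_sequence(bins: np.ndarray, grid: GridSpec) -> ViaPointSequence:
    """Rebuild a continuous via-point sequence from discrete bins.

    Interior kinds are assigned from the velocity bins: both zero -> cusp;
    the smaller-magnitude component is treated as the vanishing one (and
    set exactly to zero) so the result satisfies the via-point invariants.
    """
    bins = np.asarray(bins, dtype=int)
    n = len(bins)
    if n < 2:
        raise InvalidInputError("need at least 2 via-points")
    x, y = grid.bins_to_pos(bins[:, 0], bins[:, 1])
    vx = grid.bins_to_vel(bins[:, 2])
    vy = grid.bins_to_vel(bins[:, 3])
    pts: list[ViaPoint] = []
    for i in range(n):
        if i == 0:
            kind = ViaPointKind.START
            pvx, pvy = vx[i], vy[i]
        elif i == n - 1:
            kind = ViaPointKind.END
            pvx, pvy = vx[i], vy[i]
        else:
            axb, ayb = abs(bins[i, 2]), abs(bins[i, 3])
            if axb == 0 and ayb == 0:
                kind, pvx, pvy = ViaPointKind.CUSP, 0.0, 0.0
            elif ayb <= axb:
                kind, pvx, pvy = ViaPointKind.HORIZONTAL_TANGENT, vx[i], 0.0
            else:
                kind, pvx, pvy = ViaPointKind.VERTICAL_TANGENT, 0.0, vy[i]
        pts.append(ViaPoint(float(x[i]), float(y[i]), float(pvx), float(pvy), kind, float(i)))
    return ViaPointSequence(tuple(pts))


def fit_grid(sequences: Iterable[ViaPointSequence]) -> GridSpec:
    """Fit a per-corpus discretization grid from training via-points.

    The canonical writing box spans the vertical extent of the corpus (the
    letter height maps to the 41 position bins) with the same scale on x
    (aspect preserved, x centred), so writer-style size and slant cues are
    kept rather than normalized away per trajectory.  The velocity scale is
    robust: the 95th percentile of the nonzero via-point velocity
    magnitudes maps to the outermost bin (+-3).
    """
    seqs = list(sequences)
    if not seqs:
        raise InvalidInputError("cannot fit a grid on an empty corpus")
    pos = np.concatenate([s.positions() for s in seqs])
    vel = np.concatenate([s.velocities() for s in seqs])
    y_min, y_max = float(pos[:, 1].min()), float(pos[:, 1].max())
    if y_max <= y_min:
        raise InvalidGridError("corpus has zero vertical extent")
    step = (y_max - y_min) / (N_POS_BINS - 1)
    x_mid = 0.5 * (float(pos[:, 0].min()) + float(pos[:, 0].max()))
    comp = np.abs(vel.ravel())
    comp = comp[comp > 0]
    v95 = float(np.percentile(comp, 95)) if len(comp) else 1.0
    v_step = max(v95 / VEL_BIN_MAX, 1e-12)
    return GridSpec(x_min=x_mid - (N_POS_BINS - 1) / 2 * step, y_min=y_min,
                    x_step=step, y_step=step, v_step=v_step)


# ---------------------------------------------------------------------------
# CSV I/O: header exactly `t,x,y`, decimal point, UTF-8.

def write_trajectory_csv(traj: Trajectory, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["t", "x", "y"])
        for t, x, y in zip(traj.t, traj.x, traj.y):
            writer.writerow([repr(float(t)), repr(float(x)), repr(float(y))])


def read_trajectory_csv(path) -> Trajectory:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _parse_trajectory_csv(fh)


def _parse_trajectory_csv(fh: io.TextIOBase) -> Trajectory:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise TrajectoryParseError("empty trajectory file", row=0)
    if [h.strip() for h in header] != ["t", "x", "y"]:
        raise TrajectoryParseError(f"expected header 't,x,y', got {header!r}", row=0)
    ts, xs, ys = [], [], []
    for i, row in enumerate(reader, start=1):
        if not row:
            continue
        if len(row) != 3:
            raise TrajectoryParseError(f"expected 3 columns, got {len(row)}", row=i)
        try:
            ts.append(float(row[0])); xs.append(float(row[1])); ys.append(float(row[2]))
        except ValueError:
            raise TrajectoryParseError(f"non-numeric value in {row!r}", row=i)
    if len(ts) < 2:
        raise TrajectoryParseError("trajectory needs at least 2 data rows", row=len(ts))
    try:
        return Trajectory(np.array(ts), np.array(xs), np.array(ys))
    except InvalidInputError as exc:
        raise TrajectoryParseError(str(exc)) from exc
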