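# Methods

`viascript` implements a Bayesian model of the perception–action loop of
cursive handwriting. One internal representation — a probabilistic code
over *via-points* — serves both reading and writing, and every cognitive
task the package solves (letter recognition, writer recognition, writing,
copying, recognition aided by motor simulation) is Bayesian inference in
the same generative model.

## The via-point code

A pen trajectory is a uniformly sampled planar series `(t, x, y)`.
Velocities are estimated by finite differences (central in the interior,
one-sided at the ends — `numpy.gradient`). The perceptual code of a stroke
is its ordered via-points: the start, the end, and every interior point
where `ẋ = 0` (vertical tangent), `ẏ = 0` (horizontal tangent) or both
(cusp). Each via-point is four-dimensional, `(x, y, ẋ, ẏ)`; at most 16
via-points are allowed per stroke (more raises an overflow error rather
than silently truncating, which would corrupt the Markov structure below).

The extractor works at sample level with three mechanisms:

- **sign changes** of a velocity component between consecutive samples,
  with the sub-sample root located by linear interpolation;
- **dwells** — runs of ≥ 2 samples with `|v| < ε`, collapsing to the run
  midpoint (`ε` defaults to 1e-3 × the robust, 95th-percentile, peak
  speed); a run that spans the whole trajectory means the component is
  flat and carries no landmark;
- **touches** — an isolated local minimum of `|v|` below 0.035 × the
  robust peak speed without a sign change. Touches are necessary because
  at a cusp, and at any tangent point the stroke passes straight through,
  the velocity reaches zero *at* the via-point without changing sign, and
  a finite sampling grid straddles the zero.

Detections merge into one via-point when they are closer than `min_sep`
samples (default 3) **or** closer in space than 2% of the trajectory's
bounding-box diagonal; near a cusp the pen is slow, so the two coincident
component zeros can straddle many samples while being the same geometric
event. Two same-component detections in one merge window keep the one
with the smaller interpolated speed. Noisy inputs occasionally produce
more than 16 detections; perception-side callers retry with a widening
merge window (`robust_extract`) before giving up.

For modelling, via-points are discretized: positions onto 41 integer bins
(0..40) of a canonical writing box, velocities onto 7 integer bins
(−3..3). The grid is fitted per corpus, not per trajectory: the vertical
extent of the training data spans the 41 bins, the horizontal scale equals
the vertical one (aspect preserved, x centred), and the velocity scale
maps the 95th percentile of via-point velocity magnitudes to the outermost
bin. Per-trajectory normalization would erase the size and slant cues that
distinguish writers.

## The letter representation

Given letter `ℓ` and writer `w`, the discretized via-point sequence is
modelled as a first-order Markov chain per dimension, the four dimensions
being conditionally independent given `(ℓ, w)`. Every conditional
distribution is a Laplace succession law

    P(v | context) = (n_v + 1) / (n + K),      K = 41 or 7,

uniform before any observation and never zero. Priors over letters and
writers are uniform.

This representation is deliberately over-parameterized: at 4 writers × 22
letters it has 296,032 free parameters per subsequent via-point index
(separable, first order), against 11,885,984 at second order, 485,566,048
at third order, and 597,042,141,696 for a non-separable first-order table
— the audit is `count_free_parameters`, and the separability + first-order
assumptions are what make the model fit in memory at all. Because a
realistic corpus (3,520 sequences) is far smaller than the parameter
count, observation counts are smoothed with binomial filters before the
Laplace conversion: width 9 along position-value axes, width 7 along
velocity-value axes. We additionally smooth the *transition* counts along
the conditioning (previous-value) axis with the same kernels — kernel
regression across contexts. Without context smoothing, any query or
sampled value one bin off the training support falls into an empty
context whose conditional is uniform; with it, neighbouring contexts
share evidence. Both steps preserve total counts to 1e-9 and keep a
uniform count vector fixed (the truncated kernel is renormalized per
position).

Sequences differ in length between letters and allographs, and the
original formulation leaves open how different lengths compete inside one
posterior; we add an explicit Laplace-smoothed length distribution
`P(N | ℓ, w)` over N ∈ 2..16 and score only observed indices plus the
length term. Without it, shorter sequences systematically out-score
longer ones.

Two views of the fitted counts are used:

- **scoring tables**: the smoothed Laplace laws — strictly positive, so
  recognition never hits log(0);
- **sampling tables**: the normalized smoothed counts themselves (the
  empirical predictive), used by ancestral sampling. With n ≈ 40 and
  K = 41 the +1 floor holds roughly 45% of each conditional's mass; a
  writer sampling from the raw Laplace law would produce uniform noise in
  nearly half of all dimensions. The floor exists to *score* unseen
  inputs, not to write with. A context with no mass at all falls back to
  the Laplace law.

## Trajectory generation and the effector

Between consecutive via-points the pen path minimizes the time integral
of squared acceleration subject to position and velocity constraints at
both ends; the optimum is the cubic Hermite interpolant per coordinate
(evaluated with `scipy.interpolate.CubicHermiteSpline`). Segment
durations are proportional to the Euclidean distance between via-points,
divided by a reference speed that defaults to the sequence's mean nonzero
via-point speed — this keeps the stated boundary velocities dimensionally
consistent with the durations regardless of the input's units (a fixed
unit reference speed is available through `GenerationConfig`). Durations
are quantized to a common time step (the shortest segment receives
`points_per_segment − 1 = 19` intervals) so the concatenated trajectory
is uniformly sampled while still passing through every via-point with its
specified velocity exactly.

Letterforms are planned in the Cartesian workspace and only then mapped
to an effector — this is what makes writing style effector-independent
(motor equivalence). The simulated effector is a planar two-joint arm
(defaults L1 = 0.25 m, L2 = 0.35 m, elbow-up branch; both configurable):
inverse kinematics by the law of cosines, joint velocities and
accelerations by the same finite-difference scheme as perception, and
execution by semi-implicit Euler double integration of acceleration
commands (a velocity-command variant integrates once). The canonical
0..40 letter box is placed into the reachable annulus by a configurable
affine placement (5 mm per grid unit, offset (0.22, −0.10) m).

## The six tasks

All likelihoods are handled in log space and normalized once.

- **Letter recognition**: extract and discretize the input's via-points;
  the posterior over letters is proportional to the sequence likelihood
  under the known writer, or to the uniform-prior sum of per-writer
  likelihoods when the writer is unknown. Writer recognition is the
  symmetric question; joint recognition scores all (letter, writer) pairs
  and its marginals coincide exactly with the single-label posteriors.
- **Writing**: a two-step approximation of the full inference — sample a
  discrete via-point sequence from the letter model, rebuild continuous
  coordinates, generate the minimum-acceleration trajectory, drive the
  arm. Sampling is *kinematically constrained*: the position chains are
  sampled first, then the velocity chains restricted to signs compatible
  with the sampled displacements (a velocity cannot point against the
  motion through its via-point; a positional extremum forces a tangent).
  Position and velocity chains are conditionally independent given
  (letter, writer), so the ordering does not change the model — only the
  admissibility projection does. When rebuilding continuous velocities,
  magnitudes are clamped to the local positional slope: one velocity bin
  spans a coarse range of speeds, and an excessive boundary velocity
  makes the cubic overshoot and grow tangents the plan never had.
  Degenerate draws (coincident consecutive via-points with zero
  velocity) are resampled up to a bounded retry count.
- **Trajectory copying**: extract via-points, regenerate — the letter
  model is never consulted, so arbitrary symbols copy too, and the copy
  coincides with the input exactly at every via-point.
- **Letter copying**: the input is read (under the reading writer) into a
  posterior over letters; a fresh sequence is drawn from the
  posterior-weighted mixture under the output writer and regenerated.
  The letter identity is never committed — only its distribution.
- **Recognition with motor simulation**: the posterior is proportional to
  the product of two likelihood terms — the perceptual term above, and a
  second term obtained by regenerating a trajectory through the perceived
  via-points with the motor model and re-extracting via-points from it
  with the *same* extractor. Both terms condition on the same writer
  argument. On complete letters the two modes agree almost always; on
  truncated letters the regenerated arc can restore via-point structure
  the cut removed, and cases exist where perception alone misreads the
  stimulus while the product term recovers it. `truncate_trajectory`
  implements the stimulus manipulation: a tail cut shortens the series,
  an interior cut re-joins the remainder into one uniformly sampled
  trajectory (the extractor requires a single uniform series).

## The synthetic corpus

No public corpus of single-stroke cursive pen trajectories exists to
train on, so the package generates one. 22 hand-designed via-point
skeletons cover the lowercase Latin alphabet minus i, j, t, x (which need
a pen-up); each skeleton lives in the canonical box (baseline y = 10,
x-height ≈ 26, ascenders ≈ 36, descenders ≈ 3). The letter `l` has two
allographs — a 6-point loop and a 4-point slanted spike. Confusable
structures are included on purpose: the ascender letters l/b/h/k share
their upstroke loop, and g/q share their entire bowl and differ only in
the tail, so confusion matrices and the truncation experiment have
something to measure.

Four writer styles perturb the skeletons deterministically — slant
(shear up to 10°), horizontal/vertical scale (0.8–1.2), "roundness" (a
tangential-velocity multiplier), and an allograph preference — and each
trial adds seeded Gaussian jitter at via-points: 0.6 grid units in
position, 0.5 units/time on the *free* velocity components only (the
components a via-point's kind pins to zero stay exactly zero, so tangents
remain tangents). The default design is 4 writers × 22 letters × 40
trials = 3,520 trajectories; every trial's generator is seeded from
(corpus seed, writer, letter, trial), so the corpus is bit-identical
under replay and reconstructible from its manifest alone.

The skeleton geometry was tuned against two measured properties rather
than against any recognition score: (i) a noiseless generate→extract
round trip must reproduce each skeleton's interior tangent/cusp pattern,
and (ii) the distribution of extracted via-point counts within one
(letter, writer) cell should be strongly modal, because real handwriting
keeps a letterform's topology stable across repetitions. The second
property is what drives many geometric choices documented in the source
(interior tangents are genuine sign reversals rather than grazing
touches; arches are wide and shallow so sheared styles keep them
monotone; extrema sit off the clipping boundary).

What the generator does *not* emulate: pen-up strokes and multi-stroke
letters, pen pressure, curvature-dependent speed profiles (the
two-thirds power law), letter-to-letter co-articulation, and the
long-tailed irregularity of real human trials. Passing tests therefore
show that the model behaves as designed on data satisfying its own
assumptions — single-stroke, canonically oriented, topologically stable
letterforms — not that it would reach the same rates on tablet
recordings.

## Evaluation protocols and observed behaviour

`kfold_evaluate` implements the recognition protocol: per fold (default
8 folds, i.e. 35 training and 5 test trials per cell), fit on the
training split, then answer each test trial by *drawing* from its
posterior — not by argmax — which is the convention all reported
recognition rates use (`answer_policy="argmax"` is available). The
leave-one-writer-out protocol trains on three writers and reads the
fourth with the writer marginalized; it is strictly harder than the
within-writer protocol because the held-out style was never observed.

At the default study conditions the package's own acceptance run
(`scripts/acceptance.py`) measures, from scratch: within-writer letter
recognition ≈ 97%, ≈ 97% with the writer marginalized, ≈ 92% for a novel
writer, writer recognition ≈ 85%, recognition with motor simulation
≈ 98%, closed write→read loop ≥ 93% per letter (argmax), and a clean-data
agreement between the two reading modes of ≈ 100%, with at least one
truncated-letter case where motor simulation corrects a perception-only
misreading. These numbers characterize the synthetic corpus, not any
human dataset.

## Numerical choices and limitations

- Tolerances: conditional distributions normalize to 1 within 1e-12;
  via-point pass-through and the FK∘IK identity hold to 1e-9; CSV
  round-trips to 1e-9.
- Tie-breaks: argmax answers take the first maximal index; the elbow
  branch is fixed per arm configuration.
- Degenerate inputs: empty corpora, unreachable workspace points,
  non-uniform time steps, >16 via-points and malformed CSVs raise typed
  errors (`viascript.errors`) rather than warnings.
- The model is strictly first-order and dimension-separable; higher-order
  variants exist only as parameter-count audits.
- Recognition assumes canonically oriented input; no rotation invariance.
- The sampling-time kinematic projection and slope clamp mean the
  production distribution is a constrained version of the learned one;
  unconstrained ancestral sampling remains available
  (`sample_viapoint_sequence(..., kinematic=False)`).
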