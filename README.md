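# viascript

Bayesian perception–action modelling of cursive handwriting with a shared
via-point representation.

`viascript` is for computational cognitive and motor-control researchers
who want a working, testable implementation of the idea that *reading and
writing letters share one internal code*. A single-stroke letter is
summarized by its **via-points** — the start, the end, and every point
where the pen's horizontal or vertical velocity vanishes (tangents and
cusps), each carrying position and velocity `(x, y, ẋ, ẏ)`. Perception
extracts via-points from a trajectory; action plans a trajectory through
via-points; one probabilistic representation of letters sits between the
two, and every cognitive task is Bayesian inference in the same model.

## The model

For letter ℓ and writer w, the discretized via-point sequence
`v₀, v₁, …` (positions on 41 bins, velocities on 7 bins) follows a
first-order Markov chain per dimension, the four dimensions independent
given (ℓ, w). Every conditional is a Laplace succession law

    P(v | context, ℓ, w) = (n_v + 1) / (n + K)

learned by counting, smoothed with binomial filters (width 9 for
positions, 7 for velocities), with uniform priors over letters and
writers. Recognition computes

    P(ℓ | trajectory, w) ∝ Π_j Π_d P(v_j^d | v_{j−1}^d, ℓ, w) · P(N | ℓ, w)

and the symmetric/marginalized variants give writer and joint
recognition. Writing runs the model generatively: sample a via-point
sequence, connect consecutive via-points with minimum-acceleration
(cubic Hermite) segments, and drive a two-joint arm through inverse
kinematics. Reading *with motor simulation* multiplies the perceptual
likelihood with a second term obtained by regenerating a trajectory from
the perceived via-points and re-perceiving it — an internal simulation
loop that helps on degraded (truncated) stimuli.

No public corpus of single-stroke cursive pen trajectories is available,
so the package ships a seeded synthetic-writer module: 22 hand-designed
letter skeletons (the alphabet minus the pen-up letters i, j, t, x), four
writer styles (slant, scale, roundness, allograph preference) and
per-trial jitter, emulating a 4 writers × 22 letters × 40 trials = 3,520
trajectory study. See `docs/methods.md` for assumptions and limitations.

## Worked example

```python
import numpy as np
from viascript import (build_corpus, extract_corpus, fit_grid, fit_letter_model,
                       discretize_sequence, recognize_letter, write_letter)

corpus = build_corpus(trials_per_letter=40, seed=1)   # 4 writers x 22 letters x 40
sequences = extract_corpus(corpus)                    # via-point sequences
grid = fit_grid(sequences)
model = fit_letter_model(
    ((t.letter, t.writer, discretize_sequence(s, grid))
     for t, s in zip(corpus.trials, sequences)),
    corpus.letters, corpus.writers, grid)

# ask the model to write an 'a' the way the round writer does, then read it back
rng = np.random.default_rng(42)
written = write_letter("a", "w_round", model, rng)
result = recognize_letter(written.trajectory, model, writer="w_round",
                          answer_policy="argmax")
print("sampled via-points:", len(written.bins))
print("answer:", result.answer)
top = np.argsort(result.posterior.probs)[::-1][:3]
for i in top:
    print(f"  P({model.letters[i]}) = {result.posterior.probs[i]:.3f}")
```

Output:

```
sampled via-points: 8
answer: a
  P(a) = 0.960
  P(q) = 0.037
  P(g) = 0.002
```

The model wrote an 8-via-point `a`, read its own writing back, and is
96% confident in `a` — the residual mass falls on `q` and `g`, the
letters sharing the same bowl. `write_letter` also returns the joint
profiles of the simulated arm when given a `TwoJointArm`.

The same workflows are available from a shell:

```
viascript build-corpus --out corpus/ --seed 1
viascript fit --corpus corpus/ --out model.npz
viascript write --model model.npz --letter a --writer w_round --seed 42 --out a.csv
viascript recognize --model model.npz --traj a.csv --writer w_round --seed 0
viascript eval --corpus corpus/ --task letter --folds 8 --seed 0
viascript audit-params
```

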