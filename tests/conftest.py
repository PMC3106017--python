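"""Shared fixtures.

The default synthetic corpus (4 writers x 22 letters x 40 trials) and the
model fitted on it are expensive, so they are built once per session and
shared by the evaluation and acceptance tests.
"""

import numpy as np
import pytest

from viascript.representation import fit_letter_model
from viascript.synthetic import build_corpus, extract_corpus
from viascript.trajectory import Trajectory, discretize_sequence, fit_grid

CORPUS_SEED = 1


@pytest.fixture(scope="session")
def corpus():
    return build_corpus(trials_per_letter=40, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def sequences(corpus):
    return extract_corpus(corpus)


@pytest.fixture(scope="session")
def fitted(corpus, sequences):
    """(model, grid) fitted on the full default corpus."""
    grid = fit_grid(sequences)
    triples = ((t.letter, t.writer, discretize_sequence(s, grid))
               for t, s in zip(corpus.trials, sequences))
    model = fit_letter_model(triples, corpus.letters, corpus.writers, grid)
    return model, grid


@pytest.fixture()
def line_trajectory():
    """Straight segment (0,0) -> (10,0) at constant speed."""
    t = np.linspace(0.0, 1.0, 51)
    return Trajectory(t, 10.0 * t, np.zeros_like(t))


@pytest.fixture()
def sine_arch():
    """x(t)=t, y(t)=sin(pi t) on [0,1]: one horizontal tangent at t=0.5."""
    t = np.linspace(0.0, 1.0, 101)
    return Trajectory(t, t.copy(), np.sin(np.pi * t))
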