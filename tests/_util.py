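"""Shared test helpers: independent oracles kept deliberately separate
from the library's own code paths."""

from __future__ import annotations

import numpy as np


def grid_search_logistic_mle(
    x: np.ndarray,
    y: np.ndarray,
    half_width: float = 16.0,
    n_points: int = 17,
    n_zoom: int = 14,
) -> np.ndarray:
    """Coarse-to-fine grid maximizer of the Bernoulli log-likelihood.

    Independent of the IRLS fitter: evaluates the log-likelihood on a full
    (intercept + cues) coefficient grid and repeatedly zooms the window to
    twice the current spacing around the best grid point.  Valid because
    the logistic log-likelihood is concave.
    """
    design = np.hstack([np.ones((len(y), 1)), x])
    p_dim = design.shape[1]
    center = np.zeros(p_dim)
    width = half_width
    for _ in range(n_zoom):
        axes = [np.linspace(c - width, c + width, n_points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        betas = np.stack([g.ravel() for g in grids])  # (p_dim, n_points**p_dim)
        eta = design @ betas
        ll = y @ eta - np.logaddexp(0.0, eta).sum(axis=0)
        center = betas[:, int(np.argmax(ll))]
        width = 2.0 * (2.0 * width / (n_points - 1))
    return center


def random_logistic_instance(
    rng: np.random.Generator,
    n: int = 20,
    p: int = 2,
    coef_scale: float = 1.0,
    corr: float = 0.3,
):
    """A random correlated-cue logistic-regression instance with both
    outcome classes present."""
    cov = np.full((p, p), corr) + (1 - corr) * np.eye(p)
    x = rng.multivariate_normal(np.zeros(p), cov, size=n)
    beta = rng.uniform(-coef_scale, coef_scale, size=p)
    intercept = rng.uniform(-0.5, 0.5)
    prob = 1.0 / (1.0 + np.exp(-(intercept + x @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if y.min() == y.max():  # redraw degenerate outcomes
        return random_logistic_instance(rng, n=n, p=p, coef_scale=coef_scale, corr=corr)
    return x, y


def expand_table_to_vectors(a: int, b: int, c: int, d: int):
    """0/1-coded (first occurrence, repeat) vectors matching a 2x2 table."""
    first = np.concatenate([np.zeros(a + b), np.ones(c + d)])
    repeat = np.concatenate([np.zeros(a), np.ones(b), np.zeros(c), np.ones(d)])
    return first, repeat
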