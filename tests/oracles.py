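"""Independent brute-force oracles used by the model tests.

These deliberately avoid the package's solver: the regularized objective is
evaluated on a dense coefficient grid (with one refinement pass around the
coarse minimum), so solver results can be checked against an exhaustive
search on tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp


def reg_objective(Fp: np.ndarray, Fb: np.ndarray, beta: np.ndarray, lam_grid: np.ndarray) -> np.ndarray:
    """Objective f(lambda) for each row of ``lam_grid`` (G x J)."""
    eta_b = Fb @ lam_grid.T  # (N, G)
    eta_p = Fp @ lam_grid.T  # (m, G)
    return logsumexp(eta_b, axis=0) - eta_p.mean(axis=0) + np.abs(lam_grid) @ beta


def brute_force_min(
    Fp: np.ndarray,
    Fb: np.ndarray,
    beta: np.ndarray,
    lo: float = -5.0,
    hi: float = 5.0,
    step: float = 0.25,
    refine_step: float = 0.01,
) -> tuple[np.ndarray, float]:
    """Two-stage dense grid search over lambda in [lo, hi]^J.

    Coarse scan at ``step``, then a local refinement at ``refine_step``
    around the coarse argmin.  If the coarse argmin sits on the box
    boundary the box is doubled (the true optimum lies outside), so the
    search is not silently truncated.  Returns (argmin, min objective).
    """
    J = Fp.shape[1]
    while True:
        axis = np.arange(lo, hi + 1e-9, step)
        grid = np.array(list(itertools.product(axis, repeat=J)))
        f = reg_objective(Fp, Fb, beta, grid)
        best = grid[np.argmin(f)]
        on_edge = np.any(np.isclose(np.abs(best), hi))
        if not on_edge or hi >= 80:
            break
        lo, hi, step = 2 * lo, 2 * hi, 2 * step
    # refinement window of +/- one coarse step
    axes = [
        np.arange(b - step, b + step + 1e-9, refine_step) for b in best
    ]
    grid2 = np.array(list(itertools.product(*axes)))
    f2 = reg_objective(Fp, Fb, beta, grid2)
    i = int(np.argmin(f2))
    return grid2[i], float(f2[i])


def random_tiny_instance(seed: int):
    """A random presence-background instance with <= 3 features and <= 20
    background rows, feature values in [0, 1]."""
    rng = np.random.default_rng(seed)
    J = int(rng.integers(1, 4))
    N = int(rng.integers(6, 21))
    m = int(rng.integers(2, 7))
    Fb = rng.uniform(size=(N, J))
    Fp = Fb[rng.integers(0, N, size=m)] + rng.normal(scale=0.05, size=(m, J))
    Fp = np.clip(Fp, 0, 1)
    beta = rng.uniform(0.05, 0.3, size=J)
    return Fp, Fb, beta
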