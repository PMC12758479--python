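"""Independent brute-force oracles used by the tests.

These re-state the transport objectives from scratch (plain loops, no
code shared with the solver) and minimize them by coordinate-wise grid
line search.  The entropic-KL objective is jointly convex in the
coupling, so cyclic exact line search converges to the global minimum;
the non-convex Gromov objective is handled with multiple starts.
"""

from __future__ import annotations

import itertools

import numpy as np


def uot_objective(pi, cost, mass_a, mass_b, lam, rho) -> float:
    """Loop re-statement of the unbalanced entropic objective."""
    pi = np.asarray(pi, dtype=float)
    total = 0.0
    for i in range(pi.shape[0]):
        for j in range(pi.shape[1]):
            total += cost[i, j] * pi[i, j]
            if pi[i, j] > 0:
                total += (pi[i, j] * np.log(pi[i, j]) - pi[i, j]) / lam

    def kl(marg, ref):
        s = 0.0
        for m, r in zip(marg, ref):
            if r == 0:
                if m > 0:
                    return np.inf
                continue
            s += (m * np.log(m / r) - m if m > 0 else 0.0) + r
        return s

    total += rho * kl(pi.sum(axis=1), mass_a)
    total += rho * kl(pi.sum(axis=0), mass_b)
    return float(total)


def _coordinate_grid_descent(objective, shape, step, upper, start, max_sweeps=200):
    pi = start.copy()
    grid = np.arange(0.0, upper + step / 2, step)
    best = objective(pi)
    for _ in range(max_sweeps):
        changed = False
        for i, j in itertools.product(range(shape[0]), range(shape[1])):
            old = pi[i, j]
            vals = []
            for g in grid:
                pi[i, j] = g
                vals.append(objective(pi))
            k = int(np.argmin(vals))
            pi[i, j] = grid[k]
            if abs(grid[k] - old) > 1e-15:
                changed = True
            best = vals[k]
        if not changed:
            break
    return pi, best


def grid_oracle_uot(cost, mass_a, mass_b, lam, rho, step, upper=1.0):
    """Globally minimize the (convex) unbalanced entropic objective."""
    shape = cost.shape

    def obj(pi):
        return uot_objective(pi, cost, mass_a, mass_b, lam, rho)

    start = np.full(shape, 0.5 * (mass_a.sum() + mass_b.sum())
                    / (shape[0] * shape[1]))
    return _coordinate_grid_descent(obj, shape, step, upper, start)


def ugw_objective(pi, d_a, d_b, mass_a, mass_b, lam, rho) -> float:
    """Loop re-statement of the unbalanced Gromov objective."""
    pi = np.asarray(pi, dtype=float)
    n, m = pi.shape
    quad = 0.0
    for i in range(n):
        for j in range(m):
            for k in range(n):
                for l in range(m):
                    quad += (d_a[i, k] - d_b[j, l]) ** 2 * pi[i, j] * pi[k, l]
    reg = uot_objective(pi, np.zeros((n, m)), mass_a, mass_b, lam, rho)
    return float(quad + reg)


def grid_oracle_ugw(d_a, d_b, mass_a, mass_b, lam, rho, step, upper=1.0,
                    n_starts=5, seed=0):
    """Multi-start coordinate grid descent on the non-convex objective."""
    rng = np.random.default_rng(seed)
    shape = (d_a.shape[0], d_b.shape[0])

    def obj(pi):
        return ugw_objective(pi, d_a, d_b, mass_a, mass_b, lam, rho)

    starts = [np.outer(mass_a, mass_b)]
    for _ in range(n_starts - 1):
        starts.append(rng.random(shape) * mass_a.sum() / shape[0])
    best_pi, best_val = None, np.inf
    for start in starts:
        pi, val = _coordinate_grid_descent(obj, shape, step, upper, start)
        if val < best_val:
            best_pi, best_val = pi, val
    return best_pi, best_val
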