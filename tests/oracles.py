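"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic feasible solutions (vertices) of the flux polytope with
plain linear algebra instead of calling an LP solver.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-8):
    """Yield all vertices of {v : S v = 0, lb <= v <= ub}.

    Every vertex is a basic solution: choose a set F of 'free' columns with
    |F| = rank(S) and full column rank, put each remaining variable at one
    of its bounds, and solve for the free variables. Exponential, so only
    usable for tiny networks (n <= ~8).
    """
    m, n = S.shape
    r = np.linalg.matrix_rank(S)
    cols = range(n)
    seen = set()
    for free in itertools.combinations(cols, r):
        Sf = S[:, free]
        if np.linalg.matrix_rank(Sf) < r:
            continue
        fixed = [j for j in cols if j not in free]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.empty(n)
            rhs = np.zeros(m)
            for j, val in zip(fixed, bounds_choice):
                v[j] = val
                rhs -= S[:, j] * val
            sol, residual, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
            if np.linalg.norm(Sf @ sol - rhs) > tol:
                continue
            for j, val in zip(free, sol):
                v[j] = val
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            key = tuple(np.round(v, 6))
            if key in seen:
                continue
            seen.add(key)
            yield v


def best_vertex_objective(S, lb, ub, c, sense="max"):
    """Optimal objective over all vertices; None if infeasible."""
    best = None
    for v in enumerate_vertices(S, np.asarray(lb, float), np.asarray(ub, float)):
        val = float(c @ v)
        if best is None or (val > best if sense == "max" else val < best):
            best = val
    return best


def random_flux_network(rng, max_mets=5, max_rxns=7):
    """A random small bounded flux polytope (always feasible: 0 inside)."""
    m = int(rng.integers(2, max_mets + 1))
    n = int(rng.integers(m + 1, max_rxns + 1))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    lb = np.where(rng.random(n) < 0.5, 0.0, -rng.integers(1, 8, size=n).astype(float))
    ub = rng.integers(1, 8, size=n).astype(float)
    c = rng.integers(-3, 4, size=n).astype(float)
    return S, lb, ub, c
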