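"""Brute-force oracle for tiny flux LPs: exhaustive vertex enumeration.

For a bounded polytope {v : S v = 0, l <= v <= u} every vertex has at
least n - rank(S) coordinates at a bound.  With n <= ~8 we can enumerate
every choice of pinned coordinates and bound sides, solve the reduced
linear system for the free coordinates, and keep the feasible solutions.
The optimum of a linear objective over the polytope is then the best
vertex.  Completely independent of the package's LP path.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_vertices(S: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                       tol: float = 1e-8) -> list[np.ndarray]:
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_pinned = n - rank
    vertices: list[np.ndarray] = []
    for pinned in itertools.combinations(range(n), n_pinned):
        free = [j for j in range(n) if j not in pinned]
        for sides in itertools.product((0, 1), repeat=n_pinned):
            v = np.empty(n)
            for j, side in zip(pinned, sides):
                v[j] = upper[j] if side else lower[j]
            if free:
                A = S[:, free]
                b = -S[:, pinned] @ v[list(pinned)] if n_pinned else np.zeros(S.shape[0])
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lower - tol) or np.any(v > upper + tol):
                continue
            vertices.append(np.clip(v, lower, upper))
    return vertices


def optimal_objective(S, lower, upper, objective_index: int,
                      maximize: bool = True) -> float | None:
    """Best objective over the enumerated vertices; None if infeasible."""
    vertices = enumerate_vertices(np.asarray(S, float),
                                  np.asarray(lower, float),
                                  np.asarray(upper, float))
    if not vertices:
        return None
    values = [v[objective_index] for v in vertices]
    return max(values) if maximize else min(values)
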