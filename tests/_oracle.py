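"""Brute-force vertex-enumeration LP oracle for tiny networks.

Independent of the solver path under test: the feasible region
{S v = 0, lb <= v <= ub} is reduced to the null space of S, every vertex of
the resulting polytope is enumerated by intersecting d-subsets of the bound
hyperplanes, and the objective is maximized over the (finite) vertex set.
Only usable for a handful of reactions; that is the point.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import null_space


def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub}, rows of the result."""
    n = S.shape[1]
    N = null_space(S) if S.size else np.eye(n)
    d = N.shape[1]
    if d == 0:
        v = np.zeros(n)
        if np.all(v >= lb - tol) and np.all(v <= ub + tol):
            return v[None, :]
        return np.empty((0, n))
    # bound constraints in reduced coordinates t (v = N t): A t <= b
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    vertices: list[np.ndarray] = []
    for rows in combinations(range(2 * n), d):
        M = A[list(rows)]
        if np.linalg.matrix_rank(M, tol=1e-10) < d:
            continue
        t, *_ = np.linalg.lstsq(M, b[list(rows)], rcond=None)
        if np.max(np.abs(M @ t - b[list(rows)])) > 1e-8:
            continue
        if np.any(A @ t > b + 1e-7):
            continue
        v = N @ t
        if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
            vertices.append(v)
    return np.array(vertices) if vertices else np.empty((0, n))


def fba_oracle(model) -> float:
    """Maximal objective flux by exhaustive vertex enumeration."""
    S, _, rxn_ids, lb, ub = model.to_arrays()
    verts = enumerate_vertices(S, lb, ub)
    if len(verts) == 0:
        raise ValueError("infeasible (no vertices)")
    j = rxn_ids.index(model.objective_id)
    return float(verts[:, j].max())
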