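"""Independent brute-force oracles used by the test suite.

Each oracle deliberately uses a different algorithm (or a plain loop
formulation) from the package implementation it checks.
"""

import itertools
import math

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize


def brute_adjacency(X: np.ndarray, power: int, signed: bool = False) -> np.ndarray:
    """Double-loop correlation^power adjacency."""
    n, p = X.shape
    A = np.ones((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            xi, xj = X[:, i], X[:, j]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                r = 0.0
            else:
                r = float(((xi - xi.mean()) * (xj - xj.mean())).mean() / (si * sj))
            A[i, j] = ((1 + r) / 2) ** power if signed else abs(r) ** power
    return A


def brute_tom(A: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    p = A.shape[0]
    T = np.ones((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(p) if u != i and u != j)
            k_i = sum(A[i, u] for u in range(p) if u != i)
            k_j = sum(A[j, u] for u in range(p) if u != j)
            T[i, j] = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
    return T


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """Exact summation of the hypergeometric upper tail with math.comb."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(M, n) + 1):
        total += math.comb(M, x) * math.comb(N - M, n - x)
    return total / denom


def vertex_enumeration_lp(S, lb, ub, c):
    """Maximize c'v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    A vertex fixes at least (n - rank(S)) coordinates at bounds; enumerate
    all bound patterns of all coordinate subsets of that size, solve the
    remaining square-ish linear system, keep feasible points.  Exponential,
    so only for networks with <= ~6 reactions.
    """
    S = np.asarray(S, float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fix = n - rank
    best_val, best_v = -np.inf, None
    for idx in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in idx]
        for pattern in itertools.product(*[(lb[j], ub[j]) for j in idx]):
            v = np.zeros(n)
            for j, val in zip(idx, pattern):
                v[j] = val
            if free:
                rhs = -S[:, list(idx)] @ np.array(pattern)
                sol, res, rk, _ = np.linalg.lstsq(S[:, free], rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            val = float(c @ v)
            if val > best_val + 1e-12:
                best_val, best_v = val, v.copy()
    return best_val, best_v


def slsqp_qp(S, lb, ub, v_ref, x0=None):
    """Independent QP route: scipy SLSQP on the raw (un-reduced) problem."""
    n = S.shape[1]
    x0 = np.clip(v_ref, lb, ub) if x0 is None else x0
    res = minimize(
        lambda v: float((v - v_ref) @ (v - v_ref)),
        x0,
        jac=lambda v: 2.0 * (v - v_ref),
        method="SLSQP",
        bounds=Bounds(lb, ub),
        constraints=[{"type": "eq", "fun": lambda v: S @ v,
                      "jac": lambda v: S}],
        options={"maxiter": 800, "ftol": 1e-14},
    )
    return res.x if res.success else None
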