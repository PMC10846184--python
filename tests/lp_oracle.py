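"""Independent brute-force LP oracle for cross-checking the FBA engine.

A textbook dense two-phase tableau simplex with Bland's rule, written from
scratch on purpose: it shares no code path with the package's HiGHS-backed
solves, so agreement between the two is a genuine dual-route check.  Only
suitable for the small networks used in tests (tens of variables).
"""

from __future__ import annotations

import numpy as np

TOL = 1e-9
MAX_ITER = 20000


def _pivot_loop(T, basis, n_allowed):
    """Bland-rule pivoting on tableau T (last row = reduced costs, last col =
    rhs).  Only columns < n_allowed may enter.  Returns 'optimal'/'unbounded'."""
    m = T.shape[0] - 1
    for _ in range(MAX_ITER):
        entering = -1
        for j in range(n_allowed):
            if T[m, j] < -TOL:
                entering = j
                break
        if entering < 0:
            return "optimal"
        best_ratio, leaving = None, -1
        for i in range(m):
            a = T[i, entering]
            if a > TOL:
                ratio = T[i, -1] / a
                if (best_ratio is None or ratio < best_ratio - TOL
                        or (abs(ratio - best_ratio) <= TOL
                            and basis[i] < basis[leaving])):
                    best_ratio, leaving = ratio, i
        if leaving < 0:
            return "unbounded"
        piv = T[leaving, entering]
        T[leaving, :] /= piv
        for i in range(T.shape[0]):
            if i != leaving and T[i, entering] != 0.0:
                T[i, :] -= T[i, entering] * T[leaving, :]
        basis[leaving] = entering
    raise RuntimeError("simplex did not converge")


def simplex_solve(c, A, b):
    """min c@x  s.t.  A x = b, x >= 0  (dense two-phase simplex).

    Returns (status, x, objective) with status 'optimal', 'infeasible' or
    'unbounded'.
    """
    A = np.array(A, dtype=float)
    b = np.array(b, dtype=float)
    c = np.array(c, dtype=float)
    m, n = A.shape
    flip = b < 0
    A[flip] *= -1.0
    b[flip] *= -1.0

    # ----- phase 1: artificial basis, minimize sum of artificials
    T = np.zeros((m + 1, n + m + 1))
    T[:m, :n] = A
    T[:m, n:n + m] = np.eye(m)
    T[:m, -1] = b
    basis = list(range(n, n + m))
    T[m, n:n + m] = 1.0
    T[m, :] -= T[:m, :].sum(axis=0)  # price out the artificial basis
    _pivot_loop(T, basis, n + m)
    if -T[m, -1] > 1e-7:
        return "infeasible", None, None
    # drive leftover artificials out of the basis (or drop redundant rows)
    keep = []
    for i in range(m):
        if basis[i] >= n:
            pivot_col = next((j for j in range(n) if abs(T[i, j]) > TOL), None)
            if pivot_col is None:
                continue  # redundant constraint
            piv = T[i, pivot_col]
            T[i, :] /= piv
            for r in range(m + 1):
                if r != i and T[r, pivot_col] != 0.0:
                    T[r, :] -= T[r, pivot_col] * T[i, :]
            basis[i] = pivot_col
        keep.append(i)
    T = np.vstack([T[keep, :], T[m:m + 1, :]])
    basis = [basis[i] for i in keep]
    m2 = len(keep)

    # ----- phase 2: original costs, artificial columns barred from entering
    T[m2, :] = 0.0
    T[m2, :n] = c
    for i in range(m2):
        if c[basis[i]] != 0.0:
            T[m2, :] -= c[basis[i]] * T[i, :]
    status = _pivot_loop(T, basis, n)
    if status != "optimal":
        return status, None, None
    x = np.zeros(n)
    for i in range(m2):
        if basis[i] < n:
            x[basis[i]] = T[i, -1]
    return "optimal", x, float(c @ x)


def solve_bounded(c, A_eq, b_eq, lb, ub):
    """min c@v  s.t.  A_eq v = b_eq, lb <= v <= ub, via shift to standard form."""
    A_eq = np.asarray(A_eq, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = A_eq.shape
    # x = v - lb >= 0; slack rows x + s = ub - lb
    A = np.zeros((m + n, 2 * n))
    A[:m, :n] = A_eq
    A[m:, :n] = np.eye(n)
    A[m:, n:] = np.eye(n)
    b = np.concatenate([np.asarray(b_eq, dtype=float) - A_eq @ lb, ub - lb])
    status, x, _ = simplex_solve(np.concatenate([c, np.zeros(n)]), A, b)
    if status != "optimal":
        return status, None, None
    v = x[:n] + lb
    return "optimal", v, float(c @ v)


def _network_arrays(network):
    met_index = {m.id: i for i, m in enumerate(network.metabolites)}
    n = len(network.reactions)
    S = np.zeros((len(met_index), n))
    for j, r in enumerate(network.reactions):
        for met_id, coeff in r.stoichiometry.items():
            S[met_index[met_id], j] = coeff
    lb = np.array([r.lower_bound for r in network.reactions])
    ub = np.array([r.upper_bound for r in network.reactions])
    obj = np.array([r.objective_coefficient for r in network.reactions])
    return S, lb, ub, obj


def oracle_fba_objective(network):
    """Maximal biomass objective by the independent simplex; None if not optimal."""
    S, lb, ub, obj = _network_arrays(network)
    status, _, value = solve_bounded(-obj, S, np.zeros(S.shape[0]), lb, ub)
    return -value if status == "optimal" else None


def oracle_max_uptake(network, exchange_id):
    """Minimal exchange flux by the independent simplex; None if not optimal."""
    S, lb, ub, _ = _network_arrays(network)
    rxn_ids = [r.id for r in network.reactions]
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(exchange_id)] = 1.0
    status, _, value = solve_bounded(c, S, np.zeros(S.shape[0]), lb, ub)
    return value if status == "optimal" else None
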