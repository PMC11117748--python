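"""Independent brute-force oracles for the LP layer.

Kept deliberately separate from the package: vertex enumeration over the
flux polytope (numpy linear algebra only) and a scipy/HiGHS linear program
with explicit flux splitting. Neither shares code with the optlang/GLPK
route used by the implementation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

TOL = 1e-7


def model_arrays(model):
    """Extract (S, lb, ub, c) dense arrays in model reaction order."""
    mets = {m.id: i for i, m in enumerate(model.metabolites)}
    n = len(model.reactions)
    S = np.zeros((len(mets), n))
    lb = np.zeros(n)
    ub = np.zeros(n)
    c = np.zeros(n)
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[mets[met.id], j] = coef
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        c[j] = rxn.objective_coefficient
    return S, lb, ub, c


def enumerate_vertices(A, b, lb, ub):
    """All vertices of {v : A v = b, lb <= v <= ub} (small n only).

    A vertex activates the equalities plus enough bound constraints to pin
    down all n coordinates: fix a subset of variables at a bound, solve the
    reduced equality system for the rest, keep solutions inside the box.
    """
    A = np.atleast_2d(A)
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A) if A.size else 0
    k = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        Af = A[:, free] if free else np.zeros((A.shape[0], 0))
        if free and np.linalg.matrix_rank(Af) < len(free):
            continue
        for sides in itertools.product((0, 1), repeat=k):
            v = np.full(n, np.nan)
            for j, side in zip(fixed, sides):
                v[j] = ub[j] if side else lb[j]
            rhs = b - A[:, fixed] @ v[list(fixed)] if fixed else b.copy()
            if free:
                sol, *_ = np.linalg.lstsq(Af, rhs, rcond=None)
                if np.linalg.norm(Af @ sol - rhs) > TOL:
                    continue
                v[free] = sol
            elif np.linalg.norm(rhs) > TOL:
                continue
            if np.all(v >= lb - TOL) and np.all(v <= ub + TOL):
                vertices.append(np.clip(v, lb, ub))
    return vertices


def fba_oracle(model):
    """Optimum of c.v over the flux polytope by vertex enumeration.

    Returns (objective, vertex) or (None, None) when the polytope is empty.
    """
    S, lb, ub, c = model_arrays(model)
    verts = enumerate_vertices(S, np.zeros(S.shape[0]), lb, ub)
    if not verts:
        return None, None
    vals = [c @ v for v in verts]
    i = int(np.argmax(vals))
    return vals[i], verts[i]


def fva_oracle(model, fraction_of_optimum=1.0):
    """Exact per-reaction flux ranges at objective >= fraction * optimum."""
    S, lb, ub, c = model_arrays(model)
    opt, _ = fba_oracle(model)
    assert opt is not None
    target = fraction_of_optimum * opt
    zeros = np.zeros(S.shape[0])
    # candidate extrema: vertices of the polytope that satisfy the objective
    # constraint, plus vertices of the slice where the constraint is active
    cands = [v for v in enumerate_vertices(S, zeros, lb, ub) if c @ v >= target - TOL]
    cands += enumerate_vertices(
        np.vstack([S, c]), np.append(zeros, target), lb, ub
    )
    ranges = {}
    for j, rxn in enumerate(model.reactions):
        vals = [v[j] for v in cands]
        ranges[rxn.id] = (min(vals), max(vals))
    return ranges


def pfba_oracle(model, fraction_of_optimum=1.0):
    """Minimum total |flux| at the optimal objective, via scipy linprog.

    Splits each flux into positive and negative parts and minimizes their
    sum subject to steady state, bounds, and c.v = fraction * optimum.
    """
    S, lb, ub, c = model_arrays(model)
    opt, _ = fba_oracle(model)
    assert opt is not None
    m, n = S.shape
    # variables: [p; q], v = p - q, p,q >= 0
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(m)
    # box on v (p - q <= ub, -(p - q) <= -lb) and c.v >= fraction * optimum
    A_ub = np.vstack([np.hstack([np.eye(n), -np.eye(n)]),
                      np.hstack([-np.eye(n), np.eye(n)]),
                      np.hstack([-c, c])])
    b_ub = np.concatenate([ub, -lb, [-fraction_of_optimum * opt]])
    span = np.maximum(np.abs(lb), np.abs(ub))
    bounds = [(0, s) for s in span] * 2
    res = linprog(np.ones(2 * n), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    assert res.status == 0, res.message
    return res.fun
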