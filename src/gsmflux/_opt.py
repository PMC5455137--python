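"""Shared LP/NLP plumbing on top of scipy's HiGHS and SLSQP interfaces.

All flux LPs in the package are instances of
``opt c'v  s.t.  S v = 0, lb <= v <= ub`` and are solved here so that
status handling and tolerances are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, NonlinearConstraint, linprog, minimize

TOL_ZERO = 1e-6

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded",
           4: "numerical"}


@dataclass
class LPResult:
    status: str
    x: np.ndarray | None
    objective: float | None


def solve_lp(c: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
             sense: str = "max") -> LPResult:
    """Optimize ``c'v`` over ``{S v = 0, lb <= v <= ub}``."""
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=np.column_stack([lb, ub]), method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return LPResult(status=status, x=None, objective=None)
    return LPResult(status="optimal", x=res.x, objective=float(sign * res.fun))


def independent_rows(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Row-reduce S to full row rank (QR with column pivoting on Sᵀ).

    Stoichiometric matrices carry dependent rows (conserved moieties such
    as the NAD(H) or adenylate pools); SLSQP's least-squares subproblems
    need the equality constraints to be independent.
    """
    from scipy.linalg import qr

    if S.shape[0] == 0:
        return S
    _, R, piv = qr(S.T, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * max(1.0, diag.max() if diag.size else 1.0)))
    return S[np.sort(piv[:rank])]


def random_feasible_points(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                           n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Sample feasible points as convex mixtures of random LP vertices.

    Cheap stand-in for hit-and-run that is adequate for multi-start
    initialization and for objective-dominance property tests.
    """
    nv = S.shape[1]
    vertices = []
    for _ in range(max(2 * int(np.sqrt(n)) + 2, 8)):
        c = rng.standard_normal(nv)
        res = solve_lp(c, S, lb, ub, sense="max")
        if res.status == "optimal":
            vertices.append(res.x)
    if not vertices:
        return []
    vertices = np.array(vertices)
    points = []
    for _ in range(n):
        w = rng.dirichlet(np.ones(len(vertices)))
        points.append(w @ vertices)
    return points


def solve_fractional_nlp(numerator: np.ndarray,
                         denom, denom_grad,
                         S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                         starts: list[np.ndarray],
                         extra_constraints: list | None = None,
                         ftol: float = 1e-8,
                         maxiter: int = 600) -> LPResult:
    """Maximize ``(numerator'v) / denom(v)`` over the flux polytope.

    ``denom`` and ``denom_grad`` are callables (the denominator is a
    positive quadratic form plus an optional rank-one term).  Non-convex
    fractional program solved by direct NLP from multiple starts; the best
    local optimum is returned with status ``local_optimum``.  The objective
    is treated as 0 where the numerator vanishes, so the all-zero point is
    never reported as an optimum.
    """
    eps = 1e-12

    def negobj(v: np.ndarray) -> float:
        num = float(numerator @ v)
        den = denom(v) + eps
        return -num / den

    def grad(v: np.ndarray) -> np.ndarray:
        num = float(numerator @ v)
        den = denom(v) + eps
        return -(numerator * den - num * denom_grad(v)) / den**2

    cons = [LinearConstraint(independent_rows(S), 0.0, 0.0)]
    if extra_constraints:
        cons.extend(extra_constraints)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        res = minimize(negobj, x0, jac=grad, method="SLSQP",
                       bounds=np.column_stack([lb, ub]),
                       constraints=cons,
                       options={"maxiter": maxiter, "ftol": ftol})
        if res.x is None:
            continue
        # keep the iterate only if it is feasible
        if np.max(np.abs(S @ res.x)) > 1e-5:
            continue
        if np.any(res.x < lb - 1e-6) or np.any(res.x > ub + 1e-6):
            continue
        val = -negobj(res.x)
        if best is None or val > best[0]:
            best = (val, res.x)
    if best is None:
        return LPResult(status="infeasible", x=None, objective=None)
    return LPResult(status="local_optimum", x=best[1], objective=best[0])


def solve_linear_under_constraints(c: np.ndarray, S: np.ndarray,
                                   lb: np.ndarray, ub: np.ndarray,
                                   sense: str,
                                   extra: list,
                                   starts: list[np.ndarray]) -> LPResult:
    """Optimize a linear function subject to S v = 0, bounds and arbitrary
    (possibly nonlinear) extra constraints, via SLSQP multi-start.

    Used for FVA under a relaxed nonlinear objective constraint.
    """
    sign = -1.0 if sense == "max" else 1.0
    cons = [LinearConstraint(independent_rows(S), 0.0, 0.0)] + list(extra)
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        res = minimize(lambda v: sign * float(c @ v), x0,
                       jac=lambda v: sign * c, method="SLSQP",
                       bounds=np.column_stack([lb, ub]), constraints=cons,
                       options={"maxiter": 400, "ftol": 1e-9})
        if res.x is None:
            continue
        if np.max(np.abs(S @ res.x)) > 1e-5:
            continue
        ok = True
        for con in extra:
            if isinstance(con, NonlinearConstraint):
                val = np.atleast_1d(con.fun(res.x))
                if np.any(val < np.atleast_1d(con.lb) - 1e-6) or \
                   np.any(val > np.atleast_1d(con.ub) + 1e-6):
                    ok = False
            elif isinstance(con, LinearConstraint):
                val = np.atleast_1d(con.A @ res.x)
                if np.any(val < np.atleast_1d(con.lb) - 1e-6) or \
                   np.any(val > np.atleast_1d(con.ub) + 1e-6):
                    ok = False
        if not ok:
            continue
        val = float(c @ res.x)
        if best is None or sign * val < sign * best[0]:
            best = (val, res.x)
    if best is None:
        return LPResult(status="infeasible", x=None, objective=None)
    return LPResult(status="local_optimum", x=best[1], objective=best[0])
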