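"""Independent brute-force oracles used to check the optimization code.

Each oracle deliberately avoids the code path it certifies: the fractional
objective is maximized by dense grid search over the (low-dimensional)
feasible affine subspace, ROOM by exhaustive enumeration of all binary
assignments, blocked reactions by per-reaction FVA with scipy only, and
coupling ratios by dense sampling of the flux polytope.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog


def feasible_parametrization(model, lb, ub, tol=1e-9):
    """Affine parametrization {v0 + N t} of {S v = 0, fixed bounds}.

    Bounds with lb == ub are folded into the equality system, so the
    remaining dimensions are the true degrees of freedom.
    """
    S = model.stoichiometric_matrix()
    n = S.shape[1]
    A = [S]
    b = [np.zeros(S.shape[0])]
    for j in range(n):
        if abs(ub[j] - lb[j]) < tol:
            row = np.zeros(n)
            row[j] = 1.0
            A.append(row[None, :])
            b.append([lb[j]])
    A = np.vstack(A)
    b = np.concatenate(b)
    # particular solution via least squares; verify exact
    v0, *_ = np.linalg.lstsq(A, b, rcond=None)
    assert np.allclose(A @ v0, b, atol=1e-7)
    N = null_space(A)
    return v0, N


def grid_max_fractional(model, lb, ub, numerator, denom, n_grid=60,
                        t_range=12.0):
    """Global maximum of numerator'v / denom(v) by dense grid search.

    Only usable when the feasible affine subspace has <= 3 dimensions.
    Returns (best value, best v).
    """
    v0, N = feasible_parametrization(model, lb, ub)
    dim = N.shape[1]
    assert dim <= 3, f"grid oracle needs <= 3 free dimensions, got {dim}"
    axes = [np.linspace(-t_range, t_range, n_grid)] * dim
    best_val, best_v = -np.inf, None
    for t in itertools.product(*axes):
        v = v0 + N @ np.array(t)
        if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
            continue
        num = float(numerator @ v)
        den = denom(v)
        val = 0.0 if den <= 1e-12 else num / den
        if val > best_val:
            best_val, best_v = val, v
    return best_val, best_v


def room_bruteforce(model, lb, ub, v_wild, delta, epsilon):
    """Minimal number of out-of-band reactions by exhaustive enumeration.

    For every binary vector b (ordered by popcount), reactions with
    b_j = 0 are pinned inside the wild band; the first feasible LP gives
    the optimum Σb.  Only for networks with <= 12 reactions.
    """
    S = model.stoichiometric_matrix()
    n = S.shape[1]
    assert n <= 12
    v_u = v_wild + delta * np.abs(v_wild) + epsilon
    v_l = v_wild - delta * np.abs(v_wild) - epsilon
    for total in range(n + 1):
        for free in itertools.combinations(range(n), total):
            lo, hi = lb.copy(), ub.copy()
            for j in range(n):
                if j not in free:
                    lo[j] = max(lo[j], v_l[j])
                    hi[j] = min(hi[j], v_u[j])
            if np.any(lo > hi + 1e-12):
                continue
            res = linprog(np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lo, np.maximum(lo, hi)]),
                          method="highs")
            if res.status == 0:
                return total
    return None


def blocked_reactions_fva(model):
    """Blocked reactions by plain per-reaction FVA with scipy linprog."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = S.shape[1]
    blocked = []
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                     bounds=np.column_stack([lb, ub]), method="highs")
        lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                     bounds=np.column_stack([lb, ub]), method="highs")
        vmax = -hi.fun if hi.status == 0 else np.inf
        vmin = lo.fun if lo.status == 0 else -np.inf
        if abs(vmax) <= 1e-6 and abs(vmin) <= 1e-6:
            blocked.append(model.reactions[j].id)
    return blocked


def sample_flux_ratios(model, target, reaction, n=400, seed=0):
    """Observed ratios |v_j| / v_target over sampled feasible points.

    Random-objective LP vertices plus convex mixtures; used to bracket
    the exact coupling ratio interval from the inside.
    """
    rng = np.random.default_rng(seed)
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    nv = S.shape[1]
    jt = model.reaction_index(target)
    jr = model.reaction_index(reaction)
    vertices = []
    for _ in range(60):
        c = rng.standard_normal(nv)
        res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status == 0:
            vertices.append(res.x)
    ratios = []
    V = np.array(vertices)
    for _ in range(n):
        w = rng.dirichlet(np.ones(len(V)))
        v = w @ V
        if v[jt] > 1e-6:
            ratios.append(abs(v[jr]) / v[jt])
    return np.array(ratios)
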