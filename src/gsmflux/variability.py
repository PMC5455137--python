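"""Flux variability analysis with a relaxed (possibly nonlinear) objective.

After FBA fixes the objective value Z, each target flux is minimized and
maximized subject to all FBA constraints plus the relaxed objective
constraint — ``objective ≥ 0.95·Z`` for a maximized objective at the
default 5% relaxation.  For the linear growth objective the subproblems
are LPs; for the fractional objectives the relaxation
``μ − 0.95·Z·denom(v) ≥ 0`` is a smooth (quadratic) constraint handled by
the NLP solver directly, warm-started from the incumbent flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import LinearConstraint, NonlinearConstraint

from ._opt import TOL_ZERO, solve_linear_under_constraints, solve_lp
from .fba_engine import (
    CultureCondition,
    ObjectiveSpec,
    PhenotypeReport,
    _atp_signs,
    _usage_mask,
    apply_condition,
    solve_fba,
)
from .model_core import MetabolicModel

__all__ = ["FluxRange", "fva", "yield_ranges"]


@dataclass
class FluxRange:
    reaction_id: str
    vmin: float
    vmax: float
    relaxation: float = 0.05

    def __iter__(self):
        yield self.vmin
        yield self.vmax


def _objective_constraint(model: MetabolicModel, spec: ObjectiveSpec,
                          z_star: float, relaxation: float):
    """Constraint keeping the objective within ``(1−relaxation)·Z*``."""
    n = len(model.reactions)
    j_mu = model.reaction_index(model.biomass_reaction_id)
    z_rel = (1.0 - relaxation) * z_star
    if spec.kind == "lp_biomass":
        A = np.zeros((1, n))
        A[0, j_mu] = 1.0
        return LinearConstraint(A, z_rel, np.inf)
    mask = _usage_mask(model, spec)
    if spec.kind == "yield_per_flux":
        def fun(v):
            return v[j_mu] - z_rel * float(v * mask @ v)

        def jac(v):
            g = -z_rel * 2.0 * mask * v
            g[j_mu] += 1.0
            return g[None, :]
    else:  # weighted
        w = spec.w
        idx, sigma = _atp_signs(model)

        def fun(v):
            va = float(np.sum(np.maximum(sigma * v[idx], 0.0))) if idx else 0.0
            den = w * float(v * mask @ v) + (1.0 - w) * va ** 2
            return v[j_mu] - z_rel * den

        def jac(v):
            g = -z_rel * 2.0 * w * mask * v
            if idx:
                va = float(np.sum(np.maximum(sigma * v[idx], 0.0)))
                pos = (sigma * v[idx]) > 0
                gi = np.zeros(len(idx))
                gi[pos] = -z_rel * 2.0 * (1.0 - w) * va * sigma[pos]
                g[idx] += gi
            g[j_mu] += 1.0
            return g[None, :]
    return NonlinearConstraint(fun, 0.0, np.inf, jac=jac)


def fva(model: MetabolicModel, condition: CultureCondition,
        spec: ObjectiveSpec, targets: list[str] | None = None,
        relaxation: float = 0.05, seed: int = 12345,
        incumbent: PhenotypeReport | None = None) -> list[FluxRange]:
    """Per-target flux ranges under the relaxed objective constraint.

    ``targets`` defaults to all exchange reactions plus biomass; unknown
    ids raise.  Subproblems run in sorted-id order, warm-started from the
    incumbent FBA flux.
    """
    for t in targets or []:
        if not model.has_reaction(t):
            raise ValueError(f"unknown FVA target {t!r}")
    if targets is None:
        targets = sorted([r.id for r in model.reactions if r.is_exchange]
                         + [model.biomass_reaction_id])
    else:
        targets = sorted(targets)
    rep = incumbent or solve_fba(model, condition, spec, seed=seed)
    if rep.flux.status not in ("optimal", "local_optimum"):
        raise RuntimeError(f"FBA did not solve: {rep.flux.status}")
    z_star = rep.flux.objective_value
    S = model.stoichiometric_matrix()
    lb, ub = apply_condition(model, condition)
    v0 = rep.flux.vector(model)
    con = _objective_constraint(model, spec, z_star, relaxation)

    ranges = []
    for t in targets:
        j = model.reaction_index(t)
        c = np.zeros(len(model.reactions))
        c[j] = 1.0
        if spec.kind == "lp_biomass":
            lohi = []
            A_ub = -con.A  # μ ≥ z_rel  ->  -μ ≤ -z_rel
            from scipy.optimize import linprog

            for sense, sgn in (("min", 1.0), ("max", -1.0)):
                res = linprog(sgn * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                              A_ub=A_ub, b_ub=[-float(np.atleast_1d(con.lb)[0])],
                              bounds=np.column_stack([lb, ub]), method="highs")
                lohi.append(float(res.x[j]) if res.status == 0 else np.nan)
            vmin, vmax = lohi
        else:
            lo = solve_linear_under_constraints(c, S, lb, ub, "min", [con], [v0])
            hi = solve_linear_under_constraints(c, S, lb, ub, "max", [con], [v0])
            vmin = lo.objective if lo.x is not None else np.nan
            vmax = hi.objective if hi.x is not None else np.nan
        # the incumbent itself is feasible: tighten against it
        vj = float(v0[j])
        if not np.isnan(vmin):
            vmin = min(vmin, vj)
        if not np.isnan(vmax):
            vmax = max(vmax, vj)
        ranges.append(FluxRange(t, vmin, vmax, relaxation))
    return ranges


def yield_ranges(model: MetabolicModel, condition: CultureCondition,
                 spec: ObjectiveSpec, products: list[str],
                 substrate: str, relaxation: float = 0.05,
                 seed: int = 12345):
    """Point yields and FVA yield ranges, product flux ÷ substrate uptake.

    Yields are normalized by the substrate uptake magnitude at the FBA
    optimum; zero uptake yields are reported as NaN.
    """
    import pandas as pd

    rep = solve_fba(model, condition, spec, seed=seed)
    uptake = abs(rep.flux.fluxes.get(substrate, 0.0))
    ranges = fva(model, condition, spec, targets=products,
                 relaxation=relaxation, seed=seed, incumbent=rep)
    rows = []
    for fr in ranges:
        point = rep.flux.fluxes.get(fr.reaction_id, np.nan)
        if uptake > TOL_ZERO:
            rows.append({"product": fr.reaction_id,
                         "Y_point": point / uptake,
                         "Y_min": fr.vmin / uptake,
                         "Y_max": fr.vmax / uptake})
        else:
            rows.append({"product": fr.reaction_id, "Y_point": np.nan,
                         "Y_min": np.nan, "Y_max": np.nan})
    return pd.DataFrame(rows)
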