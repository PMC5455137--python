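"""Mutant phenotype prediction by regulatory on/off minimization (ROOM).

ROOM predicts the flux state of a deletion mutant as the steady-state
distribution that minimizes the *number* of reactions whose flux leaves a
tolerance band around the wild-type flux — the idea being that cells keep
both their metabolic network and gene expression as unchanged as possible
after a perturbation.  The band for reaction j is

    v_wild − δ|v_wild| − ε  <=  v_j  <=  v_wild + δ|v_wild| + ε

with relative tolerance δ (default 0.05) and absolute tolerance ε
(default 0.001).  The count of out-of-band reactions Σ b_j is minimized as
a mixed-integer LP with per-reaction big-M constants taken from the bound
differences, solved with HiGHS.

Enzyme deletions map to reaction bounds through EC annotations: a
reaction is closed only when *all* of its annotated enzymes are deleted
(surviving isozymes keep the reaction open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from ._opt import TOL_ZERO
from .fba_engine import CultureCondition, ObjectiveSpec, apply_condition, solve_fba
from .model_core import FluxState, MetabolicModel
from .variability import fva

__all__ = [
    "ROOMParams",
    "DeletionResult",
    "delete_enzymes",
    "room",
    "single_deletion_screen",
    "double_deletion_screen",
]


@dataclass
class ROOMParams:
    delta: float = 0.05
    epsilon: float = 0.001
    wild_reference: FluxState | None = None

    def __post_init__(self) -> None:
        if self.delta < 0 or self.epsilon < 0:
            raise ValueError("delta and epsilon must be non-negative")


@dataclass
class DeletionResult:
    deleted: list[str]
    flux: FluxState | None
    n_changed: int
    viable: bool
    yields: dict[str, float] = field(default_factory=dict)
    fva_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    note: str = ""


def delete_enzymes(model: MetabolicModel, ecs: list[str]) -> MetabolicModel:
    """Close reactions catalyzed exclusively by the deleted enzymes.

    A reaction with at least one surviving annotated isozyme keeps its
    wild-type bounds.  Unknown ECs are warnings, not errors.
    """
    import warnings

    mutant = model.copy()
    known = set(model.enzymes)
    for ec in ecs:
        if ec not in known:
            warnings.warn(f"EC {ec} not present in model; ignored")
    deleted = {ec for ec in ecs if ec in known}
    for rxn in mutant.reactions:
        if not rxn.enzymes:
            continue
        if all(e in deleted for e in rxn.enzymes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return mutant


def room(model: MetabolicModel, condition: CultureCondition,
         params: ROOMParams, deletions: list[str],
         tol_zero: float = TOL_ZERO) -> DeletionResult:
    """Solve the ROOM MILP for a set of enzyme deletions.

    Requires ``params.wild_reference`` (a solved wild-type flux state for
    the same culture condition).  Infeasibility is reported as an inviable
    mutant, not an error.
    """
    if params.wild_reference is None:
        raise ValueError("ROOM needs a wild-type reference flux state")
    wild = params.wild_reference
    mutant = delete_enzymes(model, deletions)
    S = mutant.stoichiometric_matrix()
    lb, ub = apply_condition(mutant, condition)
    n_m, n_r = S.shape

    v_w = np.array([wild.fluxes.get(r.id, 0.0) for r in model.reactions])
    v_u = v_w + params.delta * np.abs(v_w) + params.epsilon
    v_l = v_w - params.delta * np.abs(v_w) - params.epsilon

    # variables: v (n_r) then b (n_r binary)
    n = 2 * n_r
    c = np.zeros(n)
    c[n_r:] = 1.0
    integrality = np.zeros(n)
    integrality[n_r:] = 1.0

    A_rows, lo_rows, hi_rows = [], [], []
    # steady state
    A = np.hstack([S, np.zeros((n_m, n_r))])
    A_rows.append(A)
    lo_rows.append(np.zeros(n_m))
    hi_rows.append(np.zeros(n_m))
    # band constraints with per-reaction big-M from the bound differences:
    # v_j − b_j (ub_j − v_u_j) <= v_u_j   and   v_j − b_j (lb_j − v_l_j) >= v_l_j
    Au = np.zeros((n_r, n))
    Al = np.zeros((n_r, n))
    for j in range(n_r):
        Au[j, j] = 1.0
        Au[j, n_r + j] = -(max(ub[j], v_u[j]) - v_u[j])
        Al[j, j] = 1.0
        Al[j, n_r + j] = -(min(lb[j], v_l[j]) - v_l[j])
    A_rows.append(Au)
    lo_rows.append(np.full(n_r, -np.inf))
    hi_rows.append(v_u)
    A_rows.append(Al)
    lo_rows.append(v_l)
    hi_rows.append(np.full(n_r, np.inf))

    constraints = LinearConstraint(np.vstack(A_rows),
                                   np.concatenate(lo_rows),
                                   np.concatenate(hi_rows))
    bounds = OptBounds(np.concatenate([lb, np.zeros(n_r)]),
                       np.concatenate([ub, np.ones(n_r)]))
    res = milp(c=c, constraints=constraints, integrality=integrality,
               bounds=bounds)
    if res.status != 0 or res.x is None:
        return DeletionResult(deleted=list(deletions), flux=None,
                              n_changed=-1, viable=False,
                              note=f"MILP {res.message}")
    v = res.x[:n_r]
    b = res.x[n_r:]
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    mu = fluxes.get(model.biomass_reaction_id, 0.0)
    flux = FluxState(fluxes=fluxes, objective_value=float(np.round(res.fun)),
                     status="optimal")
    uptake = sum(abs(min(fluxes.get(ex, 0.0), 0.0)) for ex in condition.uptakes)
    yields = {"_mu": mu}
    if uptake > tol_zero:
        yields["Y_X_S"] = mu / uptake
        for r in model.reactions:
            if r.is_exchange and fluxes.get(r.id, 0.0) > tol_zero:
                yields[f"Y_{r.id}"] = fluxes[r.id] / uptake
    return DeletionResult(deleted=list(deletions), flux=flux,
                          n_changed=int(np.round(np.sum(b))),
                          viable=mu > tol_zero, yields=yields)


def mutant_fva(model: MetabolicModel, condition: CultureCondition,
               result: DeletionResult, params: ROOMParams,
               targets: list[str], relaxation: float = 0.05
               ) -> dict[str, tuple[float, float]]:
    """FVA ranges for a ROOM mutant.

    The mutant flux space is the deletion-constrained polytope with the
    ROOM band count fixed at its optimum, relaxed by the standard 5%:
    reactions that stayed inside the wild band at the ROOM optimum are
    held inside their bands and the targets are then min/maximized.  This
    is one defensible reading of mutant feasible ranges; it is recorded as
    an interpretation, not the only possible one.
    """
    from scipy.optimize import linprog

    if result.flux is None:
        return {}
    wild = params.wild_reference
    mutant = delete_enzymes(model, result.deleted)
    S = mutant.stoichiometric_matrix()
    lb, ub = apply_condition(mutant, condition)
    v = result.flux.vector(model)
    v_w = np.array([wild.fluxes.get(r.id, 0.0) for r in model.reactions])
    v_u = v_w + params.delta * np.abs(v_w) + params.epsilon
    v_l = v_w - params.delta * np.abs(v_w) - params.epsilon
    slack = relaxation * (np.abs(v_u) + np.abs(v_l) + 1.0)
    inside = (v <= v_u + 1e-7) & (v >= v_l - 1e-7)
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[inside] = np.maximum(lb2[inside], v_l[inside] - slack[inside])
    ub2[inside] = np.minimum(ub2[inside], v_u[inside] + slack[inside])
    out = {}
    for t in targets:
        j = model.reaction_index(t)
        c = np.zeros(len(model.reactions))
        c[j] = 1.0
        lohi = []
        for sgn in (1.0, -1.0):
            res = linprog(sgn * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb2, ub2]), method="highs")
            lohi.append(float(res.x[j]) if res.status == 0 else np.nan)
        out[t] = (min(lohi[0], v[j]), max(lohi[1], v[j]))
    return out


def _wild_reference(model: MetabolicModel, condition: CultureCondition,
                    spec: ObjectiveSpec, seed: int) -> FluxState:
    rep = solve_fba(model, condition, spec, seed=seed)
    if rep.flux.status not in ("optimal", "local_optimum"):
        raise RuntimeError(f"wild-type FBA failed: {rep.flux.status}")
    return rep.flux


def single_deletion_screen(model: MetabolicModel, condition: CultureCondition,
                           candidate_ecs: list[str] | None = None,
                           spec: ObjectiveSpec | None = None,
                           params: ROOMParams | None = None,
                           seed: int = 12345) -> list[DeletionResult]:
    """ROOM screen over single enzyme deletions.

    Candidates default to the enzymes directionally coupled to growth
    (deleting fully/partially coupled enzymes necessarily slows growth,
    and blocked/uncoupled enzymes cannot change the phenotype).
    """
    spec = spec or ObjectiveSpec(kind="yield_per_flux")
    if candidate_ecs is None:
        from .gap_coupling import flux_coupling

        report = flux_coupling(model)
        candidate_ecs = sorted(ec for ec, cls in report.enzyme_classes.items()
                               if cls == "directional")
    params = params or ROOMParams()
    if params.wild_reference is None:
        params = ROOMParams(delta=params.delta, epsilon=params.epsilon,
                            wild_reference=_wild_reference(model, condition,
                                                           spec, seed))
    results = []
    for ec in candidate_ecs:
        try:
            results.append(room(model, condition, params, [ec]))
        except Exception as exc:  # per-candidate failures recorded
            results.append(DeletionResult(deleted=[ec], flux=None,
                                          n_changed=-1, viable=False,
                                          note=str(exc)))
    return results


def double_deletion_screen(model: MetabolicModel, condition: CultureCondition,
                           candidate_ecs: list[str] | None = None,
                           spec: ObjectiveSpec | None = None,
                           params: ROOMParams | None = None,
                           max_pairs: int | None = None,
                           seed: int = 12345) -> list[DeletionResult]:
    """ROOM screen over enzyme pairs, excluding single-essential enzymes."""
    import itertools

    spec = spec or ObjectiveSpec(kind="yield_per_flux")
    params = params or ROOMParams()
    if params.wild_reference is None:
        params = ROOMParams(delta=params.delta, epsilon=params.epsilon,
                            wild_reference=_wild_reference(model, condition,
                                                           spec, seed))
    singles = single_deletion_screen(model, condition, candidate_ecs, spec,
                                     params, seed)
    viable = [r.deleted[0] for r in singles if r.viable]
    results = []
    for i, (e1, e2) in enumerate(itertools.combinations(sorted(viable), 2)):
        if max_pairs is not None and i >= max_pairs:
            break
        try:
            results.append(room(model, condition, params, [e1, e2]))
        except Exception as exc:
            results.append(DeletionResult(deleted=[e1, e2], flux=None,
                                          n_changed=-1, viable=False,
                                          note=str(exc)))
    return results
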