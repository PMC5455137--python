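"""Steady-state flux prediction under three objective functions.

The three objectives correspond to distinct physiological regimes of
anaerobic glycerol fermentation:

``lp_biomass``
    plain growth-rate maximization, ``max μ`` — a linear program whose
    optimum sits on a vertex of the flux polytope; for organisms able to
    secrete formate and H₂ it routes the substrate almost entirely into
    the oxidative branch and predicts no PDO;
``yield_per_flux``
    growth per total squared flux, ``max μ / Σ v²`` — a non-convex
    fractional program modelling growth maximization at minimal enzyme
    usage; appropriate under substrate limitation;
``weighted``
    ``max μ / (w·Σ v² + (1−w)·v_ATP²)`` with ``w ∈ (0,1)`` — additionally
    penalizes ATP production, modelling the sub-optimal growth observed
    under substrate excess (the calibrated weight for glycerol excess is
    w = 0.04).

An allosteric logistic upper bound couples acetate secretion to glycerol
uptake; the constraint applies to glycerol cultures only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._opt import (
    TOL_ZERO,
    LPResult,
    random_feasible_points,
    solve_fractional_nlp,
    solve_lp,
)
from .model_core import FluxState, MetabolicModel

__all__ = [
    "ObjectiveSpec",
    "CultureCondition",
    "AcetateConstraintParams",
    "PhenotypeReport",
    "acetate_upper_bound",
    "apply_condition",
    "solve_fba",
    "solve_fba_lp",
    "solve_fba_fractional",
    "solve_fba_weighted",
    "robustness_scan",
    "hydrogen_ferredoxin_ratio",
    "calibrate_weight",
    "loopless_check",
]


@dataclass
class AcetateConstraintParams:
    """Logistic acetate-secretion bound parameters.

    v0 is the bound at zero uptake, vmax the saturation value
    (mmol·gDW⁻¹·h⁻¹) and rate the accumulation rate (g·h·mmol⁻¹).
    """

    v0: float = 0.158
    vmax: float = 11.5
    rate: float = 0.0859

    def __post_init__(self) -> None:
        if not (0 < self.v0 < self.vmax):
            raise ValueError("require 0 < v0 < vmax")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def acetate_upper_bound(v_glycerol_uptake: float,
                        params: AcetateConstraintParams | None = None) -> float:
    """Logistic upper bound on acetate secretion as a function of glycerol
    uptake magnitude.

    Monotone non-decreasing, rising from ``v0`` at zero uptake toward the
    ``vmax`` asymptote.  Written in the overflow-safe form
    ``vmax / (1 + (vmax/v0 - 1) e^{-rate·u})``.
    """
    p = params or AcetateConstraintParams()
    if v_glycerol_uptake < 0:
        raise ValueError("uptake magnitude must be non-negative")
    return p.vmax / (1.0 + (p.vmax / p.v0 - 1.0) * math.exp(-p.rate * v_glycerol_uptake))


@dataclass
class ObjectiveSpec:
    kind: str = "lp_biomass"  # lp_biomass | yield_per_flux | weighted
    w: float | None = None
    enzyme_usage_set: list[str] | None = None  # None = all reactions

    def __post_init__(self) -> None:
        if self.kind not in ("lp_biomass", "yield_per_flux", "weighted"):
            raise ValueError(f"unknown objective kind {self.kind!r}")
        if self.kind == "weighted":
            if self.w is None or not (0.0 < self.w < 1.0):
                raise ValueError("weighted objective requires w in (0, 1) exclusive")


@dataclass
class CultureCondition:
    """Substrate uptake bounds (magnitudes, keyed by exchange id)."""

    uptakes: dict[str, float] = field(default_factory=dict)
    fix_uptake: bool = True
    acetate_constraint_on: bool = False
    acetate_params: AcetateConstraintParams = field(default_factory=AcetateConstraintParams)
    glycerol_exchange_id: str | None = None
    acetate_exchange_id: str | None = None
    blocked_products: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ex, u in self.uptakes.items():
            if u < 0:
                raise ValueError(f"uptake magnitude for {ex} must be >= 0")


@dataclass
class PhenotypeReport:
    flux: FluxState
    yields: dict[str, float]
    alpha_h2_fd: float | None
    v_atp_prod: float
    substrate_uptake: float

    @property
    def mu(self) -> float:
        return self.yields.get("_mu", 0.0)


def _guess_exchange(model: MetabolicModel, fragment: str) -> str | None:
    for r in model.reactions:
        if r.is_exchange and fragment in r.id.lower():
            return r.id
    return None


def _guess_acetate_exchange(model: MetabolicModel) -> str | None:
    for r in model.reactions:
        if not r.is_exchange:
            continue
        (mid,) = r.stoichiometry
        name = (model.metabolite(mid).name or mid).lower()
        if "acetate" in name or "acetic" in name:
            return r.id
    return None


def apply_condition(model: MetabolicModel, condition: CultureCondition
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Bound arrays for a culture condition.

    Substrate uptakes (magnitudes) map to negative lower bounds on their
    exchanges (fixed when ``fix_uptake``); NGAM is pinned to its rate; the
    logistic acetate bound is applied when switched on (glycerol cultures).
    """
    lb, ub = model.bounds_arrays()
    for ex_id, u in condition.uptakes.items():
        j = model.reaction_index(ex_id)
        if condition.fix_uptake:
            lb[j] = ub[j] = -u
        else:
            lb[j] = -u
            ub[j] = min(ub[j], 0.0)
    for rid in condition.blocked_products:
        j = model.reaction_index(rid)
        lb[j] = min(0.0, lb[j])
        ub[j] = 0.0
    if model.ngam_reaction_id:
        j = model.reaction_index(model.ngam_reaction_id)
        lb[j] = ub[j] = model.ngam
    if condition.acetate_constraint_on:
        gly = condition.glycerol_exchange_id or _guess_exchange(model, "glyc")
        ace = condition.acetate_exchange_id or _guess_acetate_exchange(model)
        if gly is None or ace is None:
            raise ValueError("acetate constraint needs glycerol and acetate "
                             "exchange ids")
        u = condition.uptakes.get(gly, abs(lb[model.reaction_index(gly)]))
        j = model.reaction_index(ace)
        ub[j] = min(ub[j], acetate_upper_bound(u, condition.acetate_params))
    return lb, ub


def _atp_signs(model: MetabolicModel) -> tuple[list[int], np.ndarray]:
    """Indices of ATP-producing reactions with orientation toward synthesis."""
    atp_ids = [m.id for m in model.metabolites if "atp" in m.id.lower()]
    idx, sigma = [], []
    for rid in model.atp_producing_ids:
        j = model.reaction_index(rid)
        coeff = sum(model.reactions[j].stoichiometry.get(a, 0.0) for a in atp_ids)
        idx.append(j)
        sigma.append(1.0 if coeff >= 0 else -1.0)
    return idx, np.array(sigma)


def atp_production_flux(model: MetabolicModel, v: np.ndarray) -> float:
    """v_ATP = Σ max(σ_j v_j, 0) over the designated ATP-producing reactions."""
    idx, sigma = _atp_signs(model)
    if not idx:
        return 0.0
    return float(np.sum(np.maximum(sigma * v[idx], 0.0)))


def _report(model: MetabolicModel, condition: CultureCondition,
            res: LPResult) -> PhenotypeReport:
    if res.x is None:
        flux = FluxState(fluxes={}, objective_value=float("nan"), status=res.status)
        return PhenotypeReport(flux=flux, yields={}, alpha_h2_fd=None,
                               v_atp_prod=0.0, substrate_uptake=0.0)
    v = res.x
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    flux = FluxState(fluxes=fluxes, objective_value=res.objective,
                     status=res.status)
    uptake = sum(abs(min(fluxes.get(ex, 0.0), 0.0)) for ex in condition.uptakes)
    mu = fluxes.get(model.biomass_reaction_id, 0.0)
    yields = {"_mu": mu}
    if uptake > TOL_ZERO:
        yields["Y_X_S"] = mu / uptake
        for r in model.reactions:
            if r.is_exchange and fluxes.get(r.id, 0.0) > TOL_ZERO:
                yields[f"Y_{r.id}"] = fluxes[r.id] / uptake
    alpha = None
    try:
        alpha = hydrogen_ferredoxin_ratio(flux, model)
    except ValueError:
        alpha = None
    return PhenotypeReport(flux=flux, yields=yields, alpha_h2_fd=alpha,
                           v_atp_prod=atp_production_flux(model, v),
                           substrate_uptake=uptake)


def solve_fba_lp(model: MetabolicModel, condition: CultureCondition
                 ) -> PhenotypeReport:
    """FBA with linear growth-rate maximization (``max μ``)."""
    S = model.stoichiometric_matrix()
    lb, ub = apply_condition(model, condition)
    c = np.zeros(len(model.reactions))
    c[model.reaction_index(model.biomass_reaction_id)] = 1.0
    res = solve_lp(c, S, lb, ub, sense="max")
    return _report(model, condition, res)


def _usage_mask(model: MetabolicModel, spec: ObjectiveSpec) -> np.ndarray:
    if spec.enzyme_usage_set is None:
        return np.ones(len(model.reactions))
    mask = np.zeros(len(model.reactions))
    for rid in spec.enzyme_usage_set:
        mask[model.reaction_index(rid)] = 1.0
    return mask


def _nlp_starts(model: MetabolicModel, S, lb, ub, seed: int = 12345,
                n_random: int = 4) -> list[np.ndarray]:
    """Multi-start points for the fractional objectives.

    The growth-rate LP vertex, a few random feasible mixtures, and LP
    vertices along the growth/ATP trade-off path (max μ under a cap on
    ATP production) — the latter make the low-ATP basin reachable.
    """
    from scipy.optimize import linprog as _lp

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    c = np.zeros(S.shape[1])
    c[model.reaction_index(model.biomass_reaction_id)] = 1.0
    res = solve_lp(c, S, lb, ub, sense="max")
    if res.status == "optimal":
        starts.append(res.x)
    starts.extend(random_feasible_points(S, lb, ub, n_random, rng))
    idx, sigma = _atp_signs(model)
    if idx and res.status == "optimal":
        c_atp = np.zeros(S.shape[1])
        c_atp[idx] = sigma
        res_min = solve_lp(c_atp, S, lb, ub, sense="min")
        if res_min.status == "optimal":
            atp_lo = res_min.objective
            atp_hi = atp_production_flux(model, res.x)
            for t in np.linspace(atp_lo, atp_hi, 8):
                r2 = _lp(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         A_ub=c_atp[None, :], b_ub=[t + 1e-9],
                         bounds=np.column_stack([lb, ub]), method="highs")
                if r2.status == 0:
                    starts.append(r2.x)
    # nudge away from an all-zero start, where the ratio is degenerate
    return [s + 1e-9 * rng.standard_normal(len(s)) if np.allclose(s, 0) else s
            for s in starts]


def _solve_fractional(model: MetabolicModel, S, lb, ub, num, denom, dgrad,
                      seed: int) -> LPResult:
    """Multi-start fractional solve with orthant enumeration.

    The fractional objectives are non-convex chiefly through reversible
    internal reactions (the directionality of, e.g., the ferredoxin:NAD
    reductase partitions the optima into separate basins).  When the model
    has at most three reversible internal reactions, the solve is repeated
    with every sign restriction of those reactions and the best local
    optimum over all orthants is returned.
    """
    best = solve_fractional_nlp(num, denom, dgrad, S, lb, ub,
                                starts=_nlp_starts(model, S, lb, ub, seed))
    revs = [j for j, r in enumerate(model.reactions)
            if not r.is_exchange and lb[j] < 0 < ub[j]]
    if 1 <= len(revs) <= 3:
        import itertools

        for pattern in itertools.product((1, -1), repeat=len(revs)):
            lb2, ub2 = lb.copy(), ub.copy()
            for j, sgn in zip(revs, pattern):
                if sgn > 0:
                    lb2[j] = 0.0
                else:
                    ub2[j] = 0.0
            cand = solve_fractional_nlp(
                num, denom, dgrad, S, lb2, ub2,
                starts=_nlp_starts(model, S, lb2, ub2, seed, n_random=2))
            if cand.x is not None and (best.x is None
                                       or cand.objective > best.objective):
                best = cand
    return best


def solve_fba_fractional(model: MetabolicModel, condition: CultureCondition,
                         spec: ObjectiveSpec | None = None,
                         seed: int = 12345) -> PhenotypeReport:
    """FBA maximizing biomass yield per enzyme usage, ``max μ / Σ v²``.

    Solved as a direct non-convex NLP with multi-start (growth-rate LP
    solution, random feasible points, growth/ATP trade-off vertices, and
    sign-restricted orthants of reversible internal reactions); the best
    local optimum is returned.
    """
    spec = spec or ObjectiveSpec(kind="yield_per_flux")
    S = model.stoichiometric_matrix()
    lb, ub = apply_condition(model, condition)
    mask = _usage_mask(model, spec)
    num = np.zeros(len(model.reactions))
    num[model.reaction_index(model.biomass_reaction_id)] = 1.0

    def denom(v):
        return float(v * mask @ v)

    def dgrad(v):
        return 2.0 * mask * v

    res = _solve_fractional(model, S, lb, ub, num, denom, dgrad, seed)
    return _report(model, condition, res)


def solve_fba_weighted(model: MetabolicModel, condition: CultureCondition,
                       w: float, spec: ObjectiveSpec | None = None,
                       seed: int = 12345) -> PhenotypeReport:
    """FBA maximizing ``μ / (w·Σ v² + (1−w)·v_ATP²)`` with ``w ∈ (0,1)``.

    v_ATP sums the positive-direction fluxes of the model's designated
    ATP-producing reactions; as w → 1 the optimizer of the plain
    yield-per-flux objective is recovered.
    """
    if not (0.0 < w < 1.0):
        raise ValueError("w must lie strictly inside (0, 1)")
    spec = spec or ObjectiveSpec(kind="weighted", w=w)
    S = model.stoichiometric_matrix()
    lb, ub = apply_condition(model, condition)
    mask = _usage_mask(model, spec)
    num = np.zeros(len(model.reactions))
    num[model.reaction_index(model.biomass_reaction_id)] = 1.0
    idx, sigma = _atp_signs(model)

    def vatp(v):
        if not idx:
            return 0.0
        return float(np.sum(np.maximum(sigma * v[idx], 0.0)))

    def denom(v):
        return w * float(v * mask @ v) + (1.0 - w) * vatp(v) ** 2

    def dgrad(v):
        g = 2.0 * w * mask * v
        if idx:
            a = vatp(v)
            pos = (sigma * v[idx]) > 0
            g_idx = np.zeros(len(idx))
            g_idx[pos] = 2.0 * (1.0 - w) * a * sigma[pos]
            g[idx] += g_idx
        return g

    res = _solve_fractional(model, S, lb, ub, num, denom, dgrad, seed)
    return _report(model, condition, res)


def solve_fba(model: MetabolicModel, condition: CultureCondition,
              spec: ObjectiveSpec, seed: int = 12345) -> PhenotypeReport:
    """Dispatch on the objective kind."""
    if spec.kind == "lp_biomass":
        return solve_fba_lp(model, condition)
    if spec.kind == "yield_per_flux":
        return solve_fba_fractional(model, condition, spec, seed=seed)
    return solve_fba_weighted(model, condition, spec.w, spec, seed=seed)


def robustness_scan(model: MetabolicModel, condition: CultureCondition,
                    spec: ObjectiveSpec, uptake_grid,
                    substrate_exchange_id: str | None = None,
                    pdo_exchange_id: str | None = None,
                    seed: int = 12345):
    """Growth-rate and PDO-secretion robustness over an uptake grid.

    One FBA solve per grid point; the acetate bound is re-evaluated per
    point when the condition enables it.  Per-point solver failures are
    recorded (status column) and the scan continues.
    """
    import pandas as pd

    sub = substrate_exchange_id or _guess_exchange(model, "glyc")
    pdo = pdo_exchange_id or _guess_exchange(model, "pdo")
    rows = []
    for u in uptake_grid:
        cond = CultureCondition(
            uptakes={**condition.uptakes, sub: float(u)},
            fix_uptake=condition.fix_uptake,
            acetate_constraint_on=condition.acetate_constraint_on,
            acetate_params=condition.acetate_params,
            glycerol_exchange_id=condition.glycerol_exchange_id,
            acetate_exchange_id=condition.acetate_exchange_id,
            blocked_products=list(condition.blocked_products))
        rep = solve_fba(model, cond, spec, seed=seed)
        rows.append({
            "uptake": float(u),
            "mu": rep.flux.fluxes.get(model.biomass_reaction_id, np.nan),
            "v_pdo": rep.flux.fluxes.get(pdo, np.nan) if pdo else np.nan,
            "status": rep.flux.status,
        })
    return pd.DataFrame(rows)


def hydrogen_ferredoxin_ratio(flux: FluxState, model: MetabolicModel,
                              hydrogenase_ids: list[str] | None = None,
                              fd_producer_ids: list[str] | None = None,
                              tol: float = TOL_ZERO) -> float:
    """Diagnostic ratio α = hydrogen formation / reduced-ferredoxin formation.

    Defaults identify hydrogenases by EC 1.12.* and reduced-ferredoxin
    producers of the pyruvate:ferredoxin oxidoreductase type by EC 1.2.7.*;
    both sets can be overridden with explicit reaction ids.  α > 1 means
    the ferredoxin:NAD reductase must run in the NADH-consuming direction
    (more H₂ formed than ferredoxin reduced by PFOR alone).
    """
    def by_ec(prefix):
        return [r.id for r in model.reactions
                if any(e.startswith(prefix) for e in r.enzymes)]

    hyd = hydrogenase_ids if hydrogenase_ids is not None else by_ec("1.12.")
    fdp = fd_producer_ids if fd_producer_ids is not None else by_ec("1.2.7.")
    v_h2 = sum(max(flux.fluxes.get(r, 0.0), 0.0) for r in hyd)
    v_fd = sum(max(flux.fluxes.get(r, 0.0), 0.0) for r in fdp)
    if v_fd <= tol:
        raise ValueError("no reduced-ferredoxin formation: ratio undefined")
    return v_h2 / v_fd


def calibrate_weight(model: MetabolicModel, condition: CultureCondition,
                     experimental_yields, w_grid,
                     substrate_exchange_id: str | None = None,
                     seed: int = 12345) -> tuple[float, "object"]:
    """Grid search for the weight w minimizing the mean relative yield error.

    ``experimental_yields`` is a table with one row per culture condition:
    column ``uptake`` (substrate uptake magnitude) plus any subset of the
    yield columns the phenotype report produces (``Y_X_S``, ``Y_EX_pdo``,
    ...).  Returns (w*, error table).
    """
    import pandas as pd

    w_grid = list(w_grid)
    df = pd.DataFrame(experimental_yields)
    if df.empty or not w_grid:
        raise ValueError("need a non-empty experimental table and w grid")
    sub = substrate_exchange_id or _guess_exchange(model, "glyc")
    ycols = [c for c in df.columns if c.startswith("Y_")]
    rows = []
    for w in w_grid:
        errs = []
        for _, row in df.iterrows():
            cond = CultureCondition(
                uptakes={**condition.uptakes, sub: float(row["uptake"])},
                fix_uptake=condition.fix_uptake,
                acetate_constraint_on=condition.acetate_constraint_on,
                acetate_params=condition.acetate_params,
                glycerol_exchange_id=condition.glycerol_exchange_id,
                acetate_exchange_id=condition.acetate_exchange_id)
            rep = solve_fba_weighted(model, cond, float(w), seed=seed)
            for col in ycols:
                obs = float(row[col])
                pred = rep.yields.get(col, 0.0)
                if abs(obs) > 0:
                    errs.append(abs(pred - obs) / abs(obs))
        rows.append({"w": float(w),
                     "mean_relative_error": float(np.mean(errs)) if errs else np.inf})
    table = pd.DataFrame(rows)
    best = table["mean_relative_error"].min()
    # ties broken toward the largest w: prefer the least departure from
    # the optimal-growth (w -> 1) objective that the data cannot refute
    tied = table[table["mean_relative_error"] <= best + 1e-9]
    w_star = float(tied["w"].max())
    return w_star, table


def loopless_check(flux: FluxState, model: MetabolicModel,
                   tol: float = TOL_ZERO) -> list[list[str]]:
    """Detect thermodynamically infeasible internal cycles in a flux state.

    A loop is a circulation: a non-zero flux pattern over active internal
    (non-exchange) reactions, sign-compatible with the given state, that
    balances every metabolite with no net exchange.  Detection solves one
    LP for the maximal circulation; its support is then decomposed into
    simple cycles on the directed metabolite graph, and each candidate is
    certified as a genuine circulation.  An empty list certifies the state
    loopless.
    """
    import networkx as nx

    active = [j for j, r in enumerate(model.reactions)
              if not r.is_exchange and r.id != model.biomass_reaction_id
              and abs(flux.fluxes.get(r.id, 0.0)) > tol]
    if not active:
        return []
    S = model.stoichiometric_matrix()
    Sa = S[:, active]
    sign = np.array([np.sign(flux.fluxes[model.reactions[j].id]) for j in active])
    # max Σ σ_j w_j  s.t.  Sa w = 0,  w between 0 and σ (componentwise)
    lo = np.minimum(0.0, sign)
    hi = np.maximum(0.0, sign)
    res = solve_lp(sign, Sa, lo, hi, sense="max")
    if res.status != "optimal" or res.objective <= tol:
        return []
    w = res.x
    support = [active[k] for k in range(len(active)) if abs(w[k]) > tol]

    G = nx.DiGraph()
    label: dict[tuple[str, str], str] = {}
    for j in support:
        r = model.reactions[j]
        s = np.sign(flux.fluxes[r.id])
        cons = [m for m, c in r.stoichiometry.items() if c * s < 0]
        prod = [m for m, c in r.stoichiometry.items() if c * s > 0]
        for a in cons:
            for b in prod:
                G.add_edge(a, b)
                label[(a, b)] = r.id

    cycles: list[list[str]] = []
    seen: set[frozenset] = set()
    for cyc in nx.simple_cycles(G):
        rids = []
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            rids.append(label[(a, b)])
        key = frozenset(rids)
        if len(key) < 2 or key in seen:
            continue
        # certify: do these reactions alone admit a circulation?
        idx = [model.reaction_index(r) for r in key]
        Sc = S[:, idx]
        sg = np.array([np.sign(flux.fluxes[model.reactions[j].id]) for j in idx])
        r2 = solve_lp(sg, Sc, np.minimum(0.0, sg), np.maximum(0.0, sg), sense="max")
        if r2.status == "optimal" and r2.objective > tol:
            seen.add(key)
            cycles.append(sorted(key))
        if len(cycles) >= 100:
            break
    return cycles
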