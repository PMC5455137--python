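"""Blocked-metabolite detection and flux coupling relative to growth.

Blocked metabolites are those that cannot carry net production in any
feasible steady-state flux distribution (detected with one production-
maximization LP per metabolite through a temporary sink, equivalent in
result to the classical binary-MILP formulation but deterministic).

Flux coupling classifies each reaction by the attainable extremes of the
ratio ``|v_j| / v_target`` (target defaults to the biomass reaction),
computed exactly by the Charnes–Cooper substitution: two LPs per reaction
on the normalized polytope ``{S y = 0, t·lb <= y <= t·ub, y_target = 1}``.

Classes (relative to the target):

- ``blocked``      the reaction can carry no flux at all;
- ``full``         the ratio is a single non-zero constant;
- ``partial``      the ratio is confined to a strictly positive interval;
- ``directional``  the reaction can be silent while the target runs, but
                   cannot run while the target is silent (non-zero v_j
                   implies non-zero v_target);
- ``uncoupled``    neither flux constrains the other.

Reversible reactions are classified on ``|v_j|``: expression prediction
cares about enzyme activity, not direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._opt import TOL_ZERO, solve_lp
from .model_core import MetabolicModel

__all__ = [
    "CouplingReport",
    "find_blocked_metabolites",
    "find_blocked_reactions",
    "flux_coupling",
    "classify_enzymes",
]

_CLASS_RANK = {"full": 3, "partial": 2, "directional": 1, "uncoupled": 0}


@dataclass
class CouplingReport:
    target: str
    classes: dict[str, str] = field(default_factory=dict)        # reaction -> class
    ratio_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    enzyme_classes: dict[str, str] = field(default_factory=dict)

    def reactions_in_class(self, cls: str) -> list[str]:
        return sorted(r for r, c in self.classes.items() if c == cls)

    def to_frame(self, model: MetabolicModel):
        import pandas as pd

        rows = []
        for rid, cls in self.classes.items():
            rmin, rmax = self.ratio_bounds.get(rid, (np.nan, np.nan))
            rows.append({"reaction": rid, "Rmin": rmin, "Rmax": rmax,
                         "class": cls,
                         "ECs": ";".join(model.reaction(rid).enzymes)})
        return pd.DataFrame(rows).sort_values("reaction").reset_index(drop=True)


def _open_exchange_bounds(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    """Structural-analysis bounds: every reaction at its declared limits.

    Blocked detection and coupling describe what the network can do under
    its declared bounds, not under one culture condition; no condition
    overrides are applied here.
    """
    return model.bounds_arrays()


def find_blocked_metabolites(model: MetabolicModel,
                             tol_zero: float = TOL_ZERO) -> list[str]:
    """Metabolites with no feasible net production (GapFind-style).

    Each metabolite gets a temporary sink whose maximal flux is the
    maximal attainable net production; blocked iff that optimum is ≤ tol.
    LP failures are recorded as ``lp_failed:<id>`` entries and the scan
    continues.
    """
    S = model.stoichiometric_matrix()
    lb, ub = _open_exchange_bounds(model)
    n_m, n_r = S.shape
    blocked: list[str] = []
    for i, met in enumerate(model.metabolites):
        sink = np.zeros((n_m, 1))
        sink[i, 0] = -1.0
        S_ext = np.hstack([S, sink])
        c = np.zeros(n_r + 1)
        c[-1] = 1.0
        res = solve_lp(c, S_ext,
                       np.append(lb, 0.0), np.append(ub, 1000.0), sense="max")
        if res.status != "optimal":
            blocked.append(f"lp_failed:{met.id}")
        elif res.objective <= tol_zero:
            blocked.append(met.id)
    return blocked


def find_blocked_reactions(model: MetabolicModel,
                           tol_zero: float = TOL_ZERO) -> list[str]:
    """Reactions whose unconstrained FVA interval is [0, 0]."""
    S = model.stoichiometric_matrix()
    lb, ub = _open_exchange_bounds(model)
    n_r = S.shape[1]
    blocked = []
    for j, rxn in enumerate(model.reactions):
        c = np.zeros(n_r)
        c[j] = 1.0
        hi = solve_lp(c, S, lb, ub, sense="max")
        if hi.status == "unbounded" or (hi.status == "optimal"
                                        and hi.objective > tol_zero):
            continue
        lo = solve_lp(c, S, lb, ub, sense="min")
        if lo.status == "unbounded" or (lo.status == "optimal"
                                        and lo.objective < -tol_zero):
            continue
        blocked.append(rxn.id)
    return blocked


def _ratio_extremes(S, lb, ub, j_target: int, j: int
                    ) -> tuple[float, float]:
    """Extremes of v_j / v_target via the Charnes–Cooper substitution.

    Variables (y, t) with y = t·v, t ≥ 0, y_target = 1; linear constraints
    ``S y = 0`` and ``lb·t ≤ y ≤ ub·t``.  Unbounded ratios come back as
    ±inf.
    """
    n_m, n_r = S.shape
    # columns: y (n_r), t
    A_eq = np.hstack([S, np.zeros((n_m, 1))])
    row = np.zeros((1, n_r + 1))
    row[0, j_target] = 1.0
    A_eq = np.vstack([A_eq, row])
    b_eq = np.append(np.zeros(n_m), 1.0)
    # inequality rows: lb_k * t - y_k <= 0 ; y_k - ub_k * t <= 0
    A_ub = []
    for k in range(n_r):
        r1 = np.zeros(n_r + 1); r1[k] = -1.0; r1[-1] = lb[k]
        r2 = np.zeros(n_r + 1); r2[k] = 1.0; r2[-1] = -ub[k]
        A_ub.append(r1); A_ub.append(r2)
    A_ub = np.array(A_ub)
    from scipy.optimize import linprog

    out = []
    for sense in ("min", "max"):
        c = np.zeros(n_r + 1)
        c[j] = 1.0 if sense == "min" else -1.0
        res = linprog(c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub,
                      b_ub=np.zeros(len(A_ub)),
                      bounds=[(None, None)] * n_r + [(0, None)],
                      method="highs")
        if res.status == 0:
            out.append(float(res.x[j]))
        elif res.status == 3:
            out.append(-np.inf if sense == "min" else np.inf)
        else:
            out.append(np.nan)
    return out[0], out[1]


def flux_coupling(model: MetabolicModel, target: str | None = None,
                  tol_zero: float = TOL_ZERO) -> CouplingReport:
    """Classify every reaction's coupling to the target (default biomass)."""
    target = target or model.biomass_reaction_id
    S = model.stoichiometric_matrix()
    lb, ub = _open_exchange_bounds(model)
    j_t = model.reaction_index(target)
    blocked = set(find_blocked_reactions(model, tol_zero))
    if target in blocked:
        raise ValueError(f"target reaction {target} is blocked")

    report = CouplingReport(target=target)
    n_r = S.shape[1]
    for j, rxn in enumerate(model.reactions):
        if rxn.id in blocked:
            report.classes[rxn.id] = "blocked"
            report.ratio_bounds[rxn.id] = (0.0, 0.0)
            continue
        if j == j_t:
            report.classes[rxn.id] = "full"
            report.ratio_bounds[rxn.id] = (1.0, 1.0)
            continue
        lo, hi = _ratio_extremes(S, lb, ub, j_t, j)
        # magnitude interval of the ratio
        if np.isnan(lo) or np.isnan(hi):
            rmin, rmax = 0.0, np.inf
        elif lo <= 0.0 <= hi:
            rmin, rmax = 0.0, max(abs(lo), abs(hi))
        else:
            rmin = min(abs(lo), abs(hi))
            rmax = max(abs(lo), abs(hi))
        report.ratio_bounds[rxn.id] = (rmin, rmax)
        if rmin > tol_zero and abs(rmax - rmin) <= 1e-7 * max(1.0, rmin):
            report.classes[rxn.id] = "full"
        elif rmin > tol_zero:
            report.classes[rxn.id] = "partial"
        else:
            # can be silent while target runs; directional iff it cannot
            # run while the target is silent
            lb2, ub2 = lb.copy(), ub.copy()
            lb2[j_t] = ub2[j_t] = 0.0
            c = np.zeros(n_r)
            c[j] = 1.0
            hi2 = solve_lp(c, S, lb2, ub2, sense="max")
            lo2 = solve_lp(c, S, lb2, ub2, sense="min")
            can_run = False
            if hi2.status == "optimal" and hi2.objective > tol_zero:
                can_run = True
            if lo2.status == "optimal" and lo2.objective < -tol_zero:
                can_run = True
            if hi2.status == "unbounded" or lo2.status == "unbounded":
                can_run = True
            report.classes[rxn.id] = "uncoupled" if can_run else "directional"

    report.enzyme_classes = classify_enzymes(report, model)
    return report


def classify_enzymes(report: CouplingReport,
                     model: MetabolicModel) -> dict[str, str]:
    """Aggregate reaction coupling classes to the enzyme (EC) level.

    An enzyme takes the strongest class among its catalyzed reactions
    (full > partial > directional > uncoupled) and is blocked only if all
    of its reactions are blocked.  ECs absent from the report map to
    ``unmapped``.
    """
    out: dict[str, str] = {}
    for ec in model.enzymes:
        classes = [report.classes.get(r.id) for r in model.reactions_for_enzyme(ec)]
        classes = [c for c in classes if c is not None]
        if not classes:
            out[ec] = "unmapped"
        elif all(c == "blocked" for c in classes):
            out[ec] = "blocked"
        else:
            live = [c for c in classes if c != "blocked"]
            out[ec] = max(live, key=lambda c: _CLASS_RANK[c])
    return out
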