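"""Biomass-composition perturbation and co-fermentation yield surfaces.

Two model-interrogation screens:

* random perturbation of the biomass precursor coefficients (independent
  normals, default 30% relative standard deviation; draws with any
  negative coefficient are excluded, not redrawn), with Pearson
  correlations between each precursor's multiplier and the biomass / PDO
  yields across retained samples;
* glucose–glycerol co-fermentation: the FVA maximum of the PDO yield on
  glycerol over a grid of uptake-flux pairs, and the bisection search for
  the smallest glucose/glycerol uptake ratio achieving complete
  conversion of glycerol to PDO (yield 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._opt import TOL_ZERO, solve_lp
from .fba_engine import CultureCondition, ObjectiveSpec, _guess_exchange, apply_condition, solve_fba
from .model_core import MetabolicModel
from .variability import fva

__all__ = [
    "BiomassPerturbation",
    "CorrelationReport",
    "sample_biomass_compositions",
    "perturbation_screen",
    "cofermentation_surface",
    "minimal_conversion_ratio",
]


@dataclass
class BiomassPerturbation:
    sample_id: int
    multipliers: dict[str, float]   # precursor metabolite id -> coefficient multiplier
    seed: int


@dataclass
class CorrelationReport:
    r_biomass: dict[str, float] = field(default_factory=dict)
    r_pdo: dict[str, float] = field(default_factory=dict)
    yield_rsd: dict[str, float] = field(default_factory=dict)
    n_samples: int = 0
    n_failed: int = 0


def biomass_precursors(model: MetabolicModel) -> list[str]:
    """Metabolite ids consumed by the biomass reaction, except ATP/water
    maintenance currency."""
    rxn = model.biomass_reaction
    out = []
    for mid, coeff in sorted(rxn.stoichiometry.items()):
        if coeff >= 0:
            continue
        low = mid.lower()
        if "atp" in low or "h2o" in low or "adp" in low:
            continue
        out.append(mid)
    return out


def sample_biomass_compositions(model: MetabolicModel, n: int,
                                rsd: float = 0.30, seed: int = 0
                                ) -> list[BiomassPerturbation]:
    """Draw perturbed biomass compositions.

    Each precursor coefficient multiplier ~ Normal(1, rsd), drawn
    independently; a sample containing any non-positive multiplier is
    excluded (the retained count is len(result)).  Deterministic per seed.
    """
    if rsd < 0:
        raise ValueError("rsd must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    precursors = biomass_precursors(model)
    samples = []
    for i in range(n):
        draws = rng.normal(1.0, rsd, size=len(precursors))
        if np.any(draws <= 0):
            continue
        samples.append(BiomassPerturbation(
            sample_id=i, multipliers=dict(zip(precursors, draws)), seed=seed))
    return samples


def _rescaled_biomass_model(model: MetabolicModel,
                            pert: BiomassPerturbation) -> MetabolicModel:
    """Apply multipliers and renormalize the biomass reaction to 1 gDW.

    After perturbing the precursor coefficients, all precursor terms are
    scaled by a common factor restoring Σ coeff·M_w = 1 g/mmol, so that
    the biomass flux keeps its units (h⁻¹) and yields stay comparable
    across samples.  GAM ATP terms are left untouched.
    """
    m2 = model.copy()
    rxn = m2.biomass_reaction
    precursors = biomass_precursors(model)
    mass0 = mass1 = 0.0
    for mid in precursors:
        mw = m2.metabolite(mid).molar_mass() / 1000.0  # g/mmol
        c0 = -rxn.stoichiometry[mid]
        mass0 += c0 * mw
        mass1 += c0 * pert.multipliers.get(mid, 1.0) * mw
    scale = mass0 / mass1 if mass1 > 0 else 1.0
    # rescale the whole precursor set: shares shift, total stays 1 gDW
    for mid in precursors:
        rxn.stoichiometry[mid] *= pert.multipliers.get(mid, 1.0) * scale
    return m2


def perturbation_screen(model: MetabolicModel, condition: CultureCondition,
                        spec: ObjectiveSpec,
                        samples: list[BiomassPerturbation],
                        substrate: str | None = None,
                        pdo_exchange_id: str | None = None,
                        seed: int = 12345):
    """Yields per perturbed composition plus Pearson correlations.

    Solver failures are excluded from the correlations and counted.
    Correlations are undefined (NaN) when a yield is constant across
    samples.
    """
    import pandas as pd
    from scipy.stats import pearsonr

    sub = substrate or _guess_exchange(model, "glyc")
    pdo = pdo_exchange_id or _guess_exchange(model, "pdo")
    rows = []
    for pert in samples:
        m2 = _rescaled_biomass_model(model, pert)
        rep = solve_fba(m2, condition, spec, seed=seed)
        ok = rep.flux.status in ("optimal", "local_optimum")
        row = {"sample_id": pert.sample_id, "ok": ok,
               "Y_X_S": rep.yields.get("Y_X_S", np.nan) if ok else np.nan,
               "Y_PDO_S": (rep.flux.fluxes.get(pdo, np.nan) / pert_uptake(rep)
                           if ok and pdo else np.nan)}
        row.update({f"mult_{k}": v for k, v in pert.multipliers.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    good = table[table["ok"]]
    report = CorrelationReport(n_samples=len(good),
                               n_failed=int((~table["ok"]).sum()))
    for ycol, dest in (("Y_X_S", report.r_biomass), ("Y_PDO_S", report.r_pdo)):
        y = good[ycol].to_numpy()
        if len(good) >= 3 and np.nanstd(y) > 0:
            report.yield_rsd[ycol] = float(np.nanstd(y) / abs(np.nanmean(y)))
        else:
            report.yield_rsd[ycol] = float("nan")
        for col in [c for c in table.columns if c.startswith("mult_")]:
            x = good[col].to_numpy()
            if len(good) >= 3 and np.std(x) > 0 and np.nanstd(y) > 0:
                dest[col[5:]] = float(pearsonr(x, y).statistic)
            else:
                dest[col[5:]] = float("nan")
    return table, report


def pert_uptake(rep) -> float:
    u = rep.substrate_uptake
    return u if u > TOL_ZERO else np.nan


def cofermentation_surface(model: MetabolicModel, glucose_grid, glycerol_grid,
                           spec: ObjectiveSpec | None = None,
                           relaxation: float = 0.05, seed: int = 12345):
    """Maximum PDO yield on glycerol over a glucose × glycerol uptake grid.

    Per cell, the FVA maximum of PDO secretion divided by glycerol uptake;
    with ``spec=None`` the maximum is taken over the whole feasible space
    (no objective-optimality constraint).  Cells with zero glycerol uptake
    report yield 0; infeasible cells report NaN.
    """
    import pandas as pd

    glc = _guess_exchange(model, "glc")
    gly = _guess_exchange(model, "glyc")
    pdo = _guess_exchange(model, "pdo")
    if glc is None or gly is None or pdo is None:
        raise ValueError("model needs glucose, glycerol and PDO exchanges")
    rows = []
    for ug in glucose_grid:
        for uy in glycerol_grid:
            y = _max_pdo_yield(model, float(ug), float(uy), glc, gly, pdo,
                               spec, relaxation, seed)
            rows.append({"glucose_uptake": float(ug),
                         "glycerol_uptake": float(uy), "Y_PDO_max": y})
    return pd.DataFrame(rows)


def _max_pdo_yield(model, ug, uy, glc, gly, pdo, spec, relaxation, seed) -> float:
    if uy <= 0:
        return 0.0
    cond = CultureCondition(uptakes={glc: ug, gly: uy},
                            acetate_constraint_on=False)
    if spec is None:
        S = model.stoichiometric_matrix()
        lb, ub = apply_condition(model, cond)
        c = np.zeros(len(model.reactions))
        c[model.reaction_index(pdo)] = 1.0
        res = solve_lp(c, S, lb, ub, sense="max")
        if res.status != "optimal":
            return float("nan")
        return res.objective / uy
    try:
        ranges = fva(model, cond, spec, targets=[pdo],
                     relaxation=relaxation, seed=seed)
    except RuntimeError:
        return float("nan")
    return ranges[0].vmax / uy


def minimal_conversion_ratio(model: MetabolicModel,
                             spec: ObjectiveSpec | None = None,
                             glycerol_uptake: float = 10.0,
                             bracket: tuple[float, float] = (0.0, 2.0),
                             tol: float = 0.02, seed: int = 12345
                             ) -> float | None:
    """Smallest glucose/glycerol uptake ratio with complete PDO conversion.

    Bisection on the ratio axis to 3 decimals; complete conversion means
    max Y_PDO/glycerol ≥ 1 − tol.  Returns None when no ratio in the
    bracket achieves it.
    """
    glc = _guess_exchange(model, "glc")
    gly = _guess_exchange(model, "glyc")
    pdo = _guess_exchange(model, "pdo")
    if pdo is None:
        return None

    def achieved(ratio: float) -> bool:
        y = _max_pdo_yield(model, ratio * glycerol_uptake, glycerol_uptake,
                           glc, gly, pdo, spec, 0.05, seed)
        return (not np.isnan(y)) and y >= 1.0 - tol

    lo, hi = bracket
    if not achieved(hi):
        return None
    if achieved(lo):
        return lo
    while hi - lo > 5e-4:
        mid = 0.5 * (lo + hi)
        if achieved(mid):
            hi = mid
        else:
            lo = mid
    return round(hi, 3)
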