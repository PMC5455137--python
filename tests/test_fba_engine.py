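"""FBA objectives, acetate constraint, diagnostics and loop detection."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmflux.fba_engine import (
    AcetateConstraintParams,
    CultureCondition,
    ObjectiveSpec,
    acetate_upper_bound,
    apply_condition,
    calibrate_weight,
    hydrogen_ferredoxin_ratio,
    loopless_check,
    robustness_scan,
    solve_fba_fractional,
    solve_fba_lp,
    solve_fba_weighted,
)
from gsmflux.model_core import FluxState
from gsmflux.synthetic_data import ToySpec, toy_glycerol_model

from conftest import build_model
from oracles import grid_max_fractional


class TestAcetateBound:
    def test_zero_uptake_gives_initial_value(self):
        assert acetate_upper_bound(0.0) == pytest.approx(0.158, abs=1e-12)

    def test_large_uptake_reaches_saturation(self):
        assert acetate_upper_bound(200.0) == pytest.approx(11.5, abs=1e-3)

    def test_closed_form_high_precision_oracle(self):
        # independent arbitrary-precision evaluation of the logistic form
        u = sympy.Rational(20)
        v0 = sympy.Rational(158, 1000)
        vmax = sympy.Rational(115, 10)
        rate = sympy.Rational(859, 10000)
        exact = vmax / (1 + (vmax / v0 - 1) * sympy.exp(-rate * u))
        assert acetate_upper_bound(20.0) == pytest.approx(float(exact.evalf(40)),
                                                          rel=1e-12)

    def test_monotone_and_bounded(self):
        grid = np.linspace(0.0, 300.0, 400)
        vals = np.array([acetate_upper_bound(u) for u in grid])
        assert np.all(np.diff(vals) >= -1e-12)
        assert np.all(vals >= 0.158 - 1e-12)
        assert np.all(vals < 11.5)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0.0, 5e3, allow_nan=False),
           st.floats(0.0, 5e3, allow_nan=False))
    def test_monotonicity_property(self, u1, u2):
        # in exact arithmetic the bound stays strictly below vmax; in
        # double precision it saturates to vmax once the logistic
        # correction drops under machine epsilon (u ~ 460), so the
        # closed bound is the representable invariant
        lo, hi = sorted((u1, u2))
        assert acetate_upper_bound(lo) <= acetate_upper_bound(hi) + 1e-12
        assert 0.158 - 1e-12 <= acetate_upper_bound(lo) <= 11.5

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError):
            acetate_upper_bound(-1.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AcetateConstraintParams(v0=12.0, vmax=11.5)
        with pytest.raises(ValueError):
            AcetateConstraintParams(rate=-0.1)

    def test_alternative_prose_rate_configurable(self):
        p = AcetateConstraintParams(rate=0.0879)
        assert acetate_upper_bound(0.0, p) == pytest.approx(0.158)
        assert acetate_upper_bound(20, p) > acetate_upper_bound(20)

    def test_applied_as_exchange_upper_bound(self, toy_model):
        cond = CultureCondition(uptakes={"EX_glyc": 10.0},
                                acetate_constraint_on=True)
        _, ub = apply_condition(toy_model, cond)
        j = toy_model.reaction_index("EX_ac")
        assert ub[j] == pytest.approx(acetate_upper_bound(10.0))


def single_pathway_model(yield_coeff=0.5):
    """EX_s -> s -> biomass with stoichiometric yield per substrate."""
    return build_model(
        mets=[("s_c", "C"), ("biomass_c", "")],
        rxns=[("EX_s", {"s_c": -1}, -1000, 0),
              ("BIOMASS", {"s_c": -1 / yield_coeff, "biomass_c": 1}, 0, 1000),
              ("EX_biomass", {"biomass_c": -1}, 0, 1000)])


def micro_fractional_model():
    """Two-degree-of-freedom network for the dense-grid global oracle.

    Substrate a (uptake fixed 10) splits between an ATP-yielding oxidation,
    a plain waste route and biomass (which consumes a and ATP); a fixed
    maintenance drain pins the flux scale.
    """
    return build_model(
        mets=[("a_c", "C"), ("atp_c", "CP"), ("w_c", "CP"), ("biomass_c", "")],
        rxns=[("EX_a", {"a_c": -1}, -10, -10),
              ("ROX", {"a_c": -1, "atp_c": 1}, 0, 1000),
              ("RW", {"a_c": -1, "w_c": 1}, 0, 1000),
              ("NGAM", {"atp_c": -1, "w_c": 1}, 2.0, 2.0),
              ("BIO", {"a_c": -1, "atp_c": -1, "biomass_c": 1}, 0, 1000),
              ("EX_w", {"w_c": -1}, 0, 1000),
              ("EX_biomass", {"biomass_c": -1}, 0, 1000)],
        biomass="BIO", ngam="NGAM", ngam_rate=2.0, atp_ids=("ROX",))


class TestLPObjective:
    def test_single_pathway_growth_equals_uptake_times_yield(self):
        m = single_pathway_model(yield_coeff=0.5)
        rep = solve_fba_lp(m, CultureCondition(uptakes={"EX_s": 10.0}))
        assert rep.mu == pytest.approx(5.0)
        assert rep.yields["Y_X_S"] == pytest.approx(0.5)

    def test_closed_exchanges_with_maintenance_infeasible(self, toy_model):
        m = toy_model.copy()
        for r in m.reactions:
            if r.is_exchange:
                r.lower_bound = r.upper_bound = 0.0
        rep = solve_fba_lp(m, CultureCondition(uptakes={}))
        assert rep.flux.status == "infeasible"

    def test_toy_lp_predicts_no_pdo(self, toy_model, limitation):
        rep = solve_fba_lp(toy_model, limitation)
        assert rep.flux.status == "optimal"
        assert rep.flux.fluxes["EX_pdo"] == pytest.approx(0.0, abs=1e-6)
        # substrate acts mostly as electron donor: H2 and/or formate leave
        assert rep.flux.fluxes["EX_h2"] + rep.flux.fluxes["EX_for"] > 1.0

    def test_lp_dominates_random_feasible_points(self, toy_model, limitation):
        from scipy.optimize import linprog

        rep = solve_fba_lp(toy_model, limitation)
        S = toy_model.stoichiometric_matrix()
        lb, ub = apply_condition(toy_model, limitation)
        j_mu = toy_model.reaction_index("BIOMASS")
        rng = np.random.default_rng(42)
        vertices = []
        for _ in range(40):
            c = rng.standard_normal(S.shape[1])
            res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb, ub]), method="highs")
            if res.status == 0:
                vertices.append(res.x)
        V = np.array(vertices)
        for _ in range(1000):
            w = rng.dirichlet(np.ones(len(V)))
            v = w @ V
            assert v[j_mu] <= rep.mu + 1e-6

    def test_steady_state_and_bounds_satisfied(self, toy_model, limitation):
        rep = solve_fba_lp(toy_model, limitation)
        S = toy_model.stoichiometric_matrix()
        v = rep.flux.vector(toy_model)
        lb, ub = apply_condition(toy_model, limitation)
        assert np.max(np.abs(S @ v)) < 1e-6
        assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)


class TestCobraCrossCheck:
    """cobrapy, reading the same SBML file, is the independent reference
    for the linear FBA/FVA paths (never the implementation)."""

    @pytest.fixture
    def cobra_pair(self, tmp_path, toy_model):
        import warnings

        from gsmflux.model_core import write_model

        cobra = pytest.importorskip("cobra")
        path = tmp_path / "toy.xml"
        write_model(toy_model, path, format="sbml")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(str(path))
        cm.objective = "BIOMASS"
        return toy_model, cm

    def test_lp_growth_matches_cobra(self, cobra_pair):
        model, cm = cobra_pair
        rep = solve_fba_lp(model, CultureCondition(uptakes={}))
        assert rep.mu == pytest.approx(cm.slim_optimize(), rel=1e-9)

    def test_lp_fva_matches_cobra(self, cobra_pair):
        from cobra.flux_analysis import flux_variability_analysis

        from gsmflux.variability import fva

        model, cm = cobra_pair
        cond = CultureCondition(uptakes={})
        ours = fva(model, cond, ObjectiveSpec(kind="lp_biomass"),
                   targets=["EX_pdo", "EX_h2"], relaxation=0.05)
        theirs = flux_variability_analysis(
            cm, reaction_list=["EX_pdo", "EX_h2"], fraction_of_optimum=0.95)
        for fr in ours:
            assert fr.vmin == pytest.approx(theirs.loc[fr.reaction_id,
                                                       "minimum"], abs=1e-6)
            assert fr.vmax == pytest.approx(theirs.loc[fr.reaction_id,
                                                       "maximum"], abs=1e-6)


class TestFractionalObjective:
    def test_unique_pathway_matches_lp(self):
        m = single_pathway_model(yield_coeff=0.5)
        cond = CultureCondition(uptakes={"EX_s": 10.0})
        lp = solve_fba_lp(m, cond)
        fr = solve_fba_fractional(m, cond)
        for rid in lp.flux.fluxes:
            assert fr.flux.fluxes[rid] == pytest.approx(lp.flux.fluxes[rid],
                                                        abs=1e-5)

    def test_toy_fractional_predicts_pdo(self, toy_model, limitation):
        rep = solve_fba_fractional(toy_model, limitation)
        assert rep.flux.status == "local_optimum"
        assert rep.flux.fluxes["EX_pdo"] > 0.1

    def test_matches_dense_grid_global_oracle(self):
        m = micro_fractional_model()
        cond = CultureCondition(uptakes={"EX_a": 10.0})
        rep = solve_fba_fractional(m, cond)
        S = m.stoichiometric_matrix()
        lb, ub = apply_condition(m, cond)
        num = np.zeros(len(m.reactions))
        num[m.reaction_index("BIO")] = 1.0
        best, _ = grid_max_fractional(m, lb, ub, num, lambda v: float(v @ v),
                                      n_grid=160, t_range=30.0)
        # the grid value is a lower bound on the global optimum; the solver
        # must reach it (within grid resolution) and never fall below it
        assert rep.flux.objective_value >= best - 1e-9
        assert best >= 0.98 * rep.flux.objective_value

    def test_dominates_lp_point_and_random_feasible(self, toy_model, limitation):
        from scipy.optimize import linprog

        rep = solve_fba_fractional(toy_model, limitation)
        S = toy_model.stoichiometric_matrix()
        lb, ub = apply_condition(toy_model, limitation)
        j_mu = toy_model.reaction_index("BIOMASS")

        def obj(v):
            den = float(v @ v)
            return 0.0 if den < 1e-12 else v[j_mu] / den

        lp = solve_fba_lp(toy_model, limitation)
        assert rep.flux.objective_value >= obj(lp.flux.vector(toy_model)) - 1e-10
        rng = np.random.default_rng(7)
        vertices = []
        for _ in range(30):
            c = rng.standard_normal(S.shape[1])
            res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb, ub]), method="highs")
            if res.status == 0:
                vertices.append(res.x)
        V = np.array(vertices)
        for _ in range(300):
            w = rng.dirichlet(np.ones(len(V)))
            assert rep.flux.objective_value >= obj(w @ V) - 1e-9

    def test_blocking_h2_and_formate_reconciles_lp_and_fractional(
            self, toy_model):
        cond = CultureCondition(uptakes={"EX_glyc": 10.0},
                                acetate_constraint_on=True,
                                blocked_products=["EX_for", "EX_h2"])
        lp = solve_fba_lp(toy_model, cond)
        fr = solve_fba_fractional(toy_model, cond)
        pdo_lp = lp.flux.fluxes["EX_pdo"]
        pdo_fr = fr.flux.fluxes["EX_pdo"]
        assert pdo_fr == pytest.approx(pdo_lp, rel=0.05)
        assert abs(fr.mu - lp.mu) <= max(0.05 * abs(lp.mu), 1e-3)


class TestWeightedObjective:
    def test_w_near_one_recovers_fractional(self, toy_model, limitation):
        fr = solve_fba_fractional(toy_model, limitation)
        wt = solve_fba_weighted(toy_model, limitation, 0.999999)
        assert wt.mu == pytest.approx(fr.mu, rel=1e-3)
        assert wt.flux.fluxes["EX_pdo"] == pytest.approx(
            fr.flux.fluxes["EX_pdo"], abs=1e-2)

    def test_atp_penalty_reduces_atp_production(self, toy_model, excess):
        hi = solve_fba_weighted(toy_model, excess, 0.999999)
        lo = solve_fba_weighted(toy_model, excess, 0.04)
        assert lo.v_atp_prod <= hi.v_atp_prod + 1e-6

    @pytest.mark.parametrize("w", [0.0, 1.0, -0.2, 1.7])
    def test_w_outside_open_interval_rejected(self, toy_model, limitation, w):
        with pytest.raises(ValueError):
            solve_fba_weighted(toy_model, limitation, w)

    def test_objective_spec_validation(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(kind="weighted", w=1.0)
        with pytest.raises(ValueError):
            ObjectiveSpec(kind="unknown")


class TestRobustnessScan:
    def test_zero_uptake_zero_growth(self):
        m = toy_glycerol_model(ToySpec(ngam=0.0))
        cond = CultureCondition(uptakes={})
        table = robustness_scan(m, cond, ObjectiveSpec(kind="lp_biomass"),
                                [0.0])
        assert table["mu"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_growth_monotone_in_uptake_bound(self, toy_model):
        cond = CultureCondition(uptakes={}, fix_uptake=False)
        table = robustness_scan(toy_model, cond,
                                ObjectiveSpec(kind="lp_biomass"),
                                [3.0, 5.0, 10.0, 20.0])
        mu = table["mu"].to_numpy()
        assert (table["status"] == "optimal").all()
        assert np.all(np.diff(mu) >= -1e-8)

    def test_acetate_bound_reevaluated_per_point(self, toy_model):
        cond = CultureCondition(uptakes={}, acetate_constraint_on=True)
        table = robustness_scan(toy_model, cond,
                                ObjectiveSpec(kind="lp_biomass"),
                                [5.0, 15.0])
        assert (table["status"] == "optimal").all()


class TestHydrogenFerredoxinRatio:
    def test_equal_fluxes_give_unity(self, toy_model):
        flux = FluxState(fluxes={"HYD": 2.0, "PFOR": 2.0},
                         objective_value=0.0, status="optimal")
        assert hydrogen_ferredoxin_ratio(flux, toy_model) == pytest.approx(1.0)

    def test_silent_hydrogenase_gives_zero(self, toy_model):
        flux = FluxState(fluxes={"PFOR": 3.0}, objective_value=0.0,
                         status="optimal")
        assert hydrogen_ferredoxin_ratio(flux, toy_model) == 0.0

    def test_no_ferredoxin_formation_undefined(self, toy_model):
        flux = FluxState(fluxes={"HYD": 2.0}, objective_value=0.0,
                         status="optimal")
        with pytest.raises(ValueError):
            hydrogen_ferredoxin_ratio(flux, toy_model)

    def test_explicit_reaction_ids_override(self, toy_model):
        flux = FluxState(fluxes={"HYD": 4.0, "FNOR": -2.0, "PFOR": 2.0},
                         objective_value=0.0, status="optimal")
        alpha = hydrogen_ferredoxin_ratio(flux, toy_model,
                                          hydrogenase_ids=["HYD"],
                                          fd_producer_ids=["PFOR"])
        assert alpha == pytest.approx(2.0)


class TestCalibrateWeight:
    GRID = [0.05, 0.1, 0.2, 0.4, 0.8]

    def test_recovers_generating_weight(self, toy_model):
        import pandas as pd

        gen = []
        for u in (10.0, 30.0):
            cond = CultureCondition(uptakes={"EX_glyc": u},
                                    acetate_constraint_on=True)
            rep = solve_fba_weighted(toy_model, cond, 0.2)
            gen.append({"uptake": u, "Y_X_S": rep.yields["Y_X_S"],
                        "Y_EX_pdo": rep.yields.get("Y_EX_pdo", 0.0)})
        cond = CultureCondition(uptakes={}, acetate_constraint_on=True)
        w_star, table = calibrate_weight(toy_model, cond, pd.DataFrame(gen),
                                         self.GRID)
        i = self.GRID.index(0.2)
        assert w_star in self.GRID[max(0, i - 1):i + 2]

    def test_fractional_targets_push_w_to_grid_maximum(self, toy_model):
        import pandas as pd

        cond10 = CultureCondition(uptakes={"EX_glyc": 10.0},
                                  acetate_constraint_on=True)
        rep = solve_fba_fractional(toy_model, cond10)
        table = pd.DataFrame([{"uptake": 10.0, "Y_X_S": rep.yields["Y_X_S"],
                               "Y_EX_pdo": rep.yields.get("Y_EX_pdo", 0.0)}])
        cond = CultureCondition(uptakes={}, acetate_constraint_on=True)
        w_star, _ = calibrate_weight(toy_model, cond, table,
                                     [0.05, 0.3, 0.999])
        assert w_star == 0.999

    def test_empty_inputs_rejected(self, toy_model):
        import pandas as pd

        cond = CultureCondition(uptakes={})
        with pytest.raises(ValueError):
            calibrate_weight(toy_model, cond, pd.DataFrame(), self.GRID)
        with pytest.raises(ValueError):
            calibrate_weight(toy_model, cond,
                             pd.DataFrame([{"uptake": 1.0, "Y_X_S": 0.1}]), [])


class TestLooplessCheck:
    def futile_cycle_model(self):
        return build_model(
            mets=[("x_c", "C"), ("y_c", "C"), ("z_c", "C"), ("biomass_c", "")],
            rxns=[("R_XY", {"x_c": -1, "y_c": 1}, -1000, 1000),
                  ("R_YZ", {"y_c": -1, "z_c": 1}, -1000, 1000),
                  ("R_ZX", {"z_c": -1, "x_c": 1}, -1000, 1000),
                  ("EX_x", {"x_c": -1}, -10, 10),
                  ("BIOMASS", {"x_c": -1, "biomass_c": 1}, 0, 1000),
                  ("EX_biomass", {"biomass_c": -1}, 0, 1000)])

    def test_futile_cycle_detected(self):
        m = self.futile_cycle_model()
        flux = FluxState(fluxes={"R_XY": 5.0, "R_YZ": 5.0, "R_ZX": 5.0},
                         objective_value=0.0, status="optimal")
        cycles = loopless_check(flux, m)
        assert cycles == [["R_XY", "R_YZ", "R_ZX"]]

    def test_acyclic_flux_certified_loopless(self, toy_model, limitation):
        rep = solve_fba_fractional(toy_model, limitation)
        assert loopless_check(rep.flux, toy_model) == []

    def test_reversible_pair_two_cycle(self):
        m = build_model(
            mets=[("x_c", "C"), ("y_c", "C"), ("biomass_c", "")],
            rxns=[("R_F", {"x_c": -1, "y_c": 1}, -1000, 1000),
                  ("R_B", {"y_c": -1, "x_c": 1}, -1000, 1000),
                  ("EX_x", {"x_c": -1}, -10, 10),
                  ("BIOMASS", {"x_c": -1, "biomass_c": 1}, 0, 1000),
                  ("EX_biomass", {"biomass_c": -1}, 0, 1000)])
        flux = FluxState(fluxes={"R_F": 5.0, "R_B": 5.0},
                         objective_value=0.0, status="optimal")
        cycles = loopless_check(flux, m)
        assert cycles == [["R_B", "R_F"]]
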