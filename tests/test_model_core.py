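"""Model container, formula handling, balance checking and I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmflux.model_core import (
    MetabolicModel,
    Metabolite,
    ModelFormatError,
    ModelValidationError,
    Reaction,
    biomass_elemental_composition,
    check_balance,
    formula_to_string,
    load_model,
    model_summary,
    parse_formula,
    write_model,
)
from gsmflux.synthetic_data import random_model, toy_glycerol_model

from conftest import build_model


@pytest.mark.parametrize("formula,expected", [
    ("CH4", {"C": 1, "H": 4}),
    ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ("CH1.624O0.456N0.216", {"C": 1, "H": 1.624, "O": 0.456, "N": 0.216}),
    ("Fe2S2H2", {"Fe": 2, "S": 2, "H": 2}),
    ("", {}),
])
def test_formula_parse(formula, expected):
    assert parse_formula(formula) == pytest.approx(expected)


def test_formula_round_trip():
    for f in ("CH4", "C21H27N7O14P2", "CH1.624O0.456N0.216P0.033S0.0047"):
        assert parse_formula(formula_to_string(parse_formula(f))) == \
            pytest.approx(parse_formula(f))


@settings(max_examples=200, derandomize=True)
@given(st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe"]),
    st.one_of(st.integers(1, 500).map(float),
              st.floats(0.001, 99.0, allow_nan=False).map(lambda x: round(x, 3))),
    min_size=1, max_size=7))
def test_formula_round_trip_property(atoms):
    assert parse_formula(formula_to_string(atoms)) == pytest.approx(atoms)


def test_formula_parse_error():
    with pytest.raises(ModelFormatError):
        parse_formula("C6(H2O)6")


def test_reaction_bound_order_enforced():
    with pytest.raises(ModelValidationError):
        Reaction(id="r", lower_bound=1.0, upper_bound=-1.0)


def test_exchange_touching_two_metabolites_rejected():
    model = build_model(
        mets=[("a_c", "C"), ("b_c", "C"), ("biomass_c", "")],
        rxns=[("EX_a", {"a_c": -1}, -1, 0),
              ("BIOMASS", {"a_c": -1, "biomass_c": 1}, 0, 10),
              ("EX_biomass", {"biomass_c": -1}, 0, 10)])
    bad = model.reaction("BIOMASS")
    bad.is_exchange = True
    with pytest.raises(ModelValidationError):
        model.validate()


class TestCheckBalance:
    def test_toy_network_is_balanced(self, toy_model):
        assert check_balance(toy_model) == []

    def test_hydrogen_deficit_reported(self):
        m = build_model(
            mets=[("a_c", "CH4"), ("b_c", "CH3"), ("biomass_c", "")],
            rxns=[("EX_a", {"a_c": -1}, -1, 0),
                  ("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                  ("BIOMASS", {"b_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        bad = check_balance(m)
        assert len(bad) == 1
        assert (bad[0].reaction_id, bad[0].kind, bad[0].element) == ("R1", "atom", "H")
        assert bad[0].delta == pytest.approx(-1.0)

    def test_charge_mismatch_reported(self):
        m = build_model(
            mets=[("a_c", "C"), ("b_c", "C"), ("biomass_c", "")],
            rxns=[("EX_a", {"a_c": -1}, -1, 0),
                  ("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                  ("BIOMASS", {"b_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        m.metabolite("b_c").charge = 1
        bad = check_balance(m)
        assert len(bad) == 1
        assert bad[0].kind == "charge" and bad[0].delta == pytest.approx(1.0)

    def test_missing_formula_is_unverifiable_not_failing(self):
        m = build_model(
            mets=[("a_c", ""), ("b_c", "C"), ("biomass_c", "")],
            rxns=[("EX_a", {"a_c": -1}, -1, 0),
                  ("R1", {"a_c": -1, "b_c": 1}, 0, 10),
                  ("BIOMASS", {"b_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        bad = check_balance(m)
        assert [x.kind for x in bad] == ["unverifiable"]


class TestBiomassComposition:
    def test_glucose_only_biomass_gives_ch2o(self):
        m = build_model(
            mets=[("glc_c", "C6H12O6"), ("biomass_c", "")],
            rxns=[("EX_glc", {"glc_c": -1}, -10, 0),
                  ("BIOMASS", {"glc_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        comp = biomass_elemental_composition(m)
        assert comp == pytest.approx({"C": 1.0, "H": 2.0, "O": 1.0})

    def test_two_precursor_hand_summed(self):
        # 1x CH4 + 1x C2H2O -> total C3 H6 O1 -> per C: C H2 O1/3
        m = build_model(
            mets=[("p1_c", "CH4"), ("p2_c", "C2H2O"), ("biomass_c", "")],
            rxns=[("EX_p1", {"p1_c": -1}, -10, 0),
                  ("EX_p2", {"p2_c": -1}, -10, 0),
                  ("BIOMASS", {"p1_c": -1, "p2_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        comp = biomass_elemental_composition(m)
        assert comp == pytest.approx({"C": 1.0, "H": 2.0, "O": 1.0 / 3.0})

    def test_atom_conservation_identity(self, toy_model):
        comp = biomass_elemental_composition(toy_model)
        rxn = toy_model.biomass_reaction
        totals = {}
        for mid, coeff in rxn.stoichiometry.items():
            met = toy_model.metabolite(mid)
            if coeff > 0 and (not met.formula or "biomass" in mid):
                continue
            for el, nct in met.formula.items():
                totals[el] = totals.get(el, 0.0) - coeff * nct
        carbon = totals["C"]
        for el, per_c in comp.items():
            assert per_c * carbon == pytest.approx(totals.get(el, 0.0))

    def test_no_carbon_raises(self):
        m = build_model(
            mets=[("h2o_c", "H2O"), ("biomass_c", "")],
            rxns=[("EX_h2o", {"h2o_c": -1}, -10, 0),
                  ("BIOMASS", {"h2o_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        with pytest.raises(ModelValidationError):
            biomass_elemental_composition(m)

    def test_gam_atp_cycling_cancels(self, toy_model):
        comp = biomass_elemental_composition(toy_model)
        # the 40 mmol ATP hydrolysed per gDW return as ADP + Pi: no P in biomass
        assert comp.get("P", 0.0) == pytest.approx(0.0)
        assert comp["N"] == pytest.approx(6 / 36)


class TestModelSummary:
    def test_toy_counts(self, toy_model):
        s = model_summary(toy_model)
        assert s["transport_reactions"] == 1  # glycerol import
        assert s["exchange_reactions"] == 13
        assert s["cytosolic_reactions"] + s["transport_reactions"] + \
            s["exchange_reactions"] == s["total_reactions"]

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property_random_models(self, seed):
        m = random_model(8, 14, seed=seed)
        s = model_summary(m)
        assert s["cytosolic_reactions"] + s["transport_reactions"] + \
            s["exchange_reactions"] == s["total_reactions"] == len(m.reactions)

    def test_empty_model(self):
        m = MetabolicModel(metabolites=[], reactions=[], genes=[])
        s = model_summary(m)
        assert all(v == 0 for v in s.values())


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["sbml", "table"])
    @pytest.mark.parametrize("seed", range(10))
    def test_random_model_round_trip(self, tmp_path, fmt, seed):
        m = random_model(7, 12, seed=seed)
        path = tmp_path / f"m.{fmt}"
        write_model(m, path, format=fmt)
        m2 = load_model(path, format=fmt)
        assert [r.id for r in m2.reactions] == [r.id for r in m.reactions]
        for r, r2 in zip(m.reactions, m2.reactions):
            assert r2.stoichiometry == pytest.approx(r.stoichiometry)
            assert (r2.lower_bound, r2.upper_bound) == (r.lower_bound, r.upper_bound)
            assert r2.enzymes == r.enzymes
            assert r2.is_exchange == r.is_exchange
        assert m2.biomass_reaction_id == m.biomass_reaction_id
        assert m2.ngam_reaction_id == m.ngam_reaction_id

    @pytest.mark.parametrize("fmt", ["sbml", "table"])
    def test_toy_round_trip_field_by_field(self, tmp_path, toy_model, fmt):
        path = tmp_path / f"toy.{fmt}"
        write_model(toy_model, path, format=fmt)
        m2 = load_model(path, format=fmt)
        assert [x.id for x in m2.metabolites] == [x.id for x in toy_model.metabolites]
        for a, b in zip(toy_model.metabolites, m2.metabolites):
            assert b.formula == pytest.approx(a.formula)
            assert b.compartment == a.compartment
        assert m2.gam == toy_model.gam and m2.ngam == toy_model.ngam
        assert m2.atp_producing_ids == toy_model.atp_producing_ids
        assert sorted(m2.genes) == sorted(toy_model.genes)
        assert check_balance(m2) == []

    def test_sbml_rejects_non_integer_charge(self, tmp_path, toy_model):
        m = toy_model.copy()
        m.metabolite("pyr_c").charge = 0.5
        with pytest.raises(ModelValidationError):
            write_model(m, tmp_path / "bad.xml", format="sbml")


class TestLoadErrors:
    def test_truncated_sbml_names_problem(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<?xml version='1.0'?><sbml xmlns='http://www.sbml.org/"
                     "sbml/level3/version1/core' level='3' version='1'>"
                     "<model id='m'><listOfSpecies><species")
        with pytest.raises(ModelFormatError):
            load_model(p, format="sbml")

    def test_missing_biomass_is_validation_error(self, tmp_path):
        m = build_model(
            mets=[("a_c", "C"), ("biomass_c", "")],
            rxns=[("EX_a", {"a_c": -1}, -1, 0),
                  ("BIOMASS", {"a_c": -1, "biomass_c": 1}, 0, 10),
                  ("EX_biomass", {"biomass_c": -1}, 0, 10)])
        m.biomass_reaction_id = ""
        path = tmp_path / "m.tsv"
        write_model(m, path, format="table")
        with pytest.raises(ModelValidationError):
            load_model(path, format="table")

    def test_legacy_kinetic_law_bounds_read(self, tmp_path):
        # pre-FBC dialect: bounds as kinetic-law local parameters
        p = tmp_path / "legacy.xml"
        p.write_text("""<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
 <model id="legacy">
  <listOfCompartments><compartment id="c"/></listOfCompartments>
  <listOfSpecies>
   <species id="a_c" compartment="c"/>
   <species id="biomass_c" compartment="c"/>
  </listOfSpecies>
  <listOfReactions>
   <reaction id="EX_a" reversible="true">
    <listOfReactants><speciesReference species="a_c"/></listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="-7.5"/>
      <parameter id="UPPER_BOUND" value="0"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="BIOMASS" reversible="false">
    <listOfReactants><speciesReference species="a_c"/></listOfReactants>
    <listOfProducts><speciesReference species="biomass_c"/></listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML"><ci>FLUX_VALUE</ci></math>
     <listOfParameters>
      <parameter id="LOWER_BOUND" value="0"/>
      <parameter id="UPPER_BOUND" value="500"/>
     </listOfParameters>
    </kineticLaw>
   </reaction>
   <reaction id="EX_biomass" reversible="false">
    <listOfReactants><speciesReference species="biomass_c"/></listOfReactants>
   </reaction>
  </listOfReactions>
 </model>
</sbml>""")
        m = load_model(p, format="sbml")
        ex = m.reaction("EX_a")
        assert (ex.lower_bound, ex.upper_bound) == (-7.5, 0.0)
        assert m.reaction("BIOMASS").upper_bound == 500.0
        assert m.biomass_reaction_id == "BIOMASS"
        assert ex.is_exchange
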