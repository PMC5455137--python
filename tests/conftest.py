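import pytest

from gsmflux.fba_engine import CultureCondition, ObjectiveSpec
from gsmflux.model_core import MetabolicModel, Metabolite, Reaction, parse_formula
from gsmflux.synthetic_data import ToySpec, toy_glycerol_model


@pytest.fixture(scope="session")
def toy_model():
    return toy_glycerol_model()


@pytest.fixture(scope="session")
def toy_model_noformate():
    return toy_glycerol_model(ToySpec(formate=False))


@pytest.fixture
def limitation():
    """Glycerol-limited culture: fixed uptake 10 mmol/gDW/h."""
    return CultureCondition(uptakes={"EX_glyc": 10.0}, acetate_constraint_on=True)


@pytest.fixture
def excess():
    """Glycerol-excess culture: fixed uptake 30 mmol/gDW/h."""
    return CultureCondition(uptakes={"EX_glyc": 30.0}, acetate_constraint_on=True)


@pytest.fixture
def eq1():
    return ObjectiveSpec(kind="yield_per_flux")


def build_model(mets, rxns, biomass="BIOMASS", ngam=None, ngam_rate=0.0,
                atp_ids=(), gam=0.0):
    """Compact model builder for hand-written fixture networks.

    ``mets``: list of (id, formula, compartment) or (id, formula);
    ``rxns``: list of (id, {met: coeff}, lb, ub[, ecs]).
    """
    metabolites = []
    for m in mets:
        mid, formula = m[0], m[1]
        comp = m[2] if len(m) > 2 else "cytosol"
        metabolites.append(Metabolite(id=mid, name=mid,
                                      formula=parse_formula(formula),
                                      compartment=comp))
    reactions = []
    for r in rxns:
        rid, stoich, lb, ub = r[0], r[1], r[2], r[3]
        ecs = list(r[4]) if len(r) > 4 else []
        rxn = Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb,
                       upper_bound=ub, enzymes=ecs)
        if len(stoich) == 1 and rid != biomass:
            rxn.is_exchange = True
        reactions.append(rxn)
    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           biomass_reaction_id=biomass,
                           ngam_reaction_id=ngam or "", gam=gam,
                           ngam=ngam_rate,
                           atp_producing_ids=list(atp_ids))
    model.validate()
    return model


@pytest.fixture
def chain_model():
    """Aext -> A -> B -> Bext with biomass sink on B; everything couples."""
    return build_model(
        mets=[("a_c", "C"), ("b_c", "C"), ("biomass_c", "")],
        rxns=[
            ("EX_a", {"a_c": -1}, -10.0, 0.0),
            ("R_AB", {"a_c": -1, "b_c": 1}, 0.0, 1000.0, ["1.1.1.1"]),
            ("BIOMASS", {"b_c": -1, "biomass_c": 1}, 0.0, 1000.0),
            ("EX_biomass", {"biomass_c": -1}, 0.0, 1000.0),
        ])


@pytest.fixture
def branch_model():
    """Uptake A; A->B feeds biomass (full); A->C->Cext independent branch."""
    return build_model(
        mets=[("a_c", "C"), ("b_c", "C"), ("c_c", "C"), ("biomass_c", "")],
        rxns=[
            ("EX_a", {"a_c": -1}, -10.0, 0.0),
            ("R_AB", {"a_c": -1, "b_c": 1}, 0.0, 1000.0, ["1.1.1.1"]),
            ("R_AC", {"a_c": -1, "c_c": 1}, 0.0, 1000.0, ["2.2.2.2"]),
            ("EX_c", {"c_c": -1}, 0.0, 1000.0),
            ("BIOMASS", {"b_c": -1, "biomass_c": 1}, 0.0, 1000.0),
            ("EX_biomass", {"biomass_c": -1}, 0.0, 1000.0),
        ])
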