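"""Synthetic fixture networks for testing every analysis stage offline.

:func:`toy_glycerol_model` builds a small anaerobic glycerol-fermentation
network with the structure the analyses assume: an oxidative branch
producing ATP/NADH and the acids (acetate, butyrate, lactate), formate and
H₂; a reversible ferredoxin:NAD⁺ reductase linking the ferredoxin and NADH
pools; a reductive NADH-consuming branch from glycerol via
3-hydroxypropionaldehyde to 1,3-propanediol (PDO); a biomass reaction over
three lumped precursor pools with growth-associated maintenance (GAM); and
a non-growth maintenance (NGAM) ATP drain.  Every internal reaction is
atom- and charge-balanced; coefficients are textbook integers.

The fixture is for structural and property testing, not for quantitative
reproduction of any genome-scale network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_formula,
)

__all__ = ["ToySpec", "toy_glycerol_model", "random_model", "synthetic_expression"]


@dataclass
class ToySpec:
    """Which fermentation branches the toy network includes."""

    acetate: bool = True
    butyrate: bool = True
    lactate: bool = True
    ethanol: bool = True
    formate: bool = True
    h2: bool = True
    pdo: bool = True
    ferredoxin_reductase: bool = True
    glucose: bool = True
    gam: float = 40.0
    ngam: float = 5.0
    glycerol_uptake: float = 10.0
    seed: int = 0


_FORMULAS = {
    "glyc_e": "C3H8O3", "glyc_c": "C3H8O3", "glc_c": "C6H12O6",
    "pyr_c": "C3H4O3",
    "nad_c": "C21H26N7O14P2", "nadh_c": "C21H28N7O14P2",
    "fdox_c": "Fe2S2", "fdred_c": "Fe2S2H2",
    "atp_c": "C10H16N5O13P3", "adp_c": "C10H15N5O10P2", "pi_c": "H3PO4",
    "coa_c": "C21H36N7O16P3S", "accoa_c": "C23H38N7O17P3S",
    "co2_c": "CO2", "h2o_c": "H2O", "h2_c": "H2", "nh3_c": "NH3",
    "for_c": "CH2O2", "ac_c": "C2H4O2", "but_c": "C4H8O2",
    "lac_c": "C3H6O3", "etoh_c": "C2H6O",
    "hpa_c": "C3H6O2", "pdo_c": "C3H8O2",
    "skel_c": "C3H4O3", "ncmp_c": "C3H7NO2", "lip_c": "C4H8O2",
}


def _met(mid: str, name: str = "", compartment: str = "cytosol") -> Metabolite:
    return Metabolite(id=mid, name=name or mid,
                      formula=parse_formula(_FORMULAS.get(mid, "")),
                      charge=0, compartment=compartment)


def toy_glycerol_model(spec: ToySpec | None = None) -> MetabolicModel:
    """Build the toy anaerobic glycerol/PDO network.

    Qualitative regimes it is designed to reproduce: plain growth-rate
    maximization (LP) routes all glycerol through the oxidative branch and
    predicts zero PDO, because electrons leave as H₂/formate; maximizing
    growth per squared flux instead spreads electrons into the reductive
    branch and predicts strictly positive PDO.
    """
    spec = spec or ToySpec()
    mets = [
        _met("glyc_e", "glycerol (extracellular)", "extracellular"),
        _met("glyc_c", "glycerol"), _met("pyr_c", "pyruvate"),
        _met("nad_c", "NAD+"), _met("nadh_c", "NADH"),
        _met("atp_c", "ATP"), _met("adp_c", "ADP"), _met("pi_c", "phosphate"),
        _met("coa_c", "coenzyme A"), _met("accoa_c", "acetyl-CoA"),
        _met("co2_c", "CO2"), _met("h2o_c", "water"), _met("nh3_c", "ammonia"),
        _met("skel_c", "carbon-skeleton pool"),
        _met("ncmp_c", "nitrogen-compound pool"),
        _met("lip_c", "lipid pool"),
        Metabolite(id="biomass_c", name="biomass", formula={}, compartment="cytosol"),
    ]
    rxns: list[Reaction] = []

    def add(rid, stoich, lb, ub, ecs=(), gpr="", name="", kegg=None):
        rxns.append(Reaction(id=rid, stoichiometry=dict(stoich),
                             lower_bound=lb, upper_bound=ub,
                             enzymes=list(ecs), gpr=gpr, name=name or rid,
                             kegg_id=kegg))

    big = 1000.0
    # transport + oxidative trunk
    add("T_GLYC", {"glyc_e": -1, "glyc_c": 1}, 0, big, name="glycerol transport")
    add("GLYOX", {"glyc_c": -1, "nad_c": -2, "adp_c": -1, "pi_c": -1,
                  "pyr_c": 1, "nadh_c": 2, "atp_c": 1, "h2o_c": 1},
        0, big, ecs=["1.1.1.6", "2.7.1.29"], gpr="gdh and dhaK",
        name="glycerol oxidation to pyruvate (lumped)")
    if spec.glucose:
        mets.append(_met("glc_c", "glucose"))
        add("GLYCL", {"glc_c": -1, "nad_c": -2, "adp_c": -2, "pi_c": -2,
                      "pyr_c": 2, "nadh_c": 2, "atp_c": 2, "h2o_c": 2},
            0, big, ecs=["2.7.1.2"], gpr="glk", name="glycolysis (lumped)")

    need_fd = spec.h2 or spec.ferredoxin_reductase
    if need_fd:
        mets += [_met("fdox_c", "oxidized ferredoxin"),
                 _met("fdred_c", "reduced ferredoxin")]
        add("PFOR", {"pyr_c": -1, "coa_c": -1, "fdox_c": -1,
                     "accoa_c": 1, "co2_c": 1, "fdred_c": 1},
            0, big, ecs=["1.2.7.1"], gpr="pfor",
            name="pyruvate:ferredoxin oxidoreductase")
    if spec.h2:
        mets.append(_met("h2_c", "hydrogen"))
        add("HYD", {"fdred_c": -1, "fdox_c": 1, "h2_c": 1},
            0, big, ecs=["1.12.7.2"], gpr="hydA", name="hydrogenase")
    if spec.ferredoxin_reductase and need_fd:
        add("FNOR", {"fdred_c": -1, "nad_c": -1, "fdox_c": 1, "nadh_c": 1},
            -big, big, ecs=["1.18.1.3"], gpr="fnor",
            name="ferredoxin:NAD+ reductase (reversible)")
    if spec.formate:
        mets.append(_met("for_c", "formate"))
        add("PFL", {"pyr_c": -1, "coa_c": -1, "accoa_c": 1, "for_c": 1},
            0, big, ecs=["2.3.1.54"], gpr="pflB", name="pyruvate formate-lyase")
    if spec.acetate:
        mets.append(_met("ac_c", "acetate"))
        add("ACK", {"accoa_c": -1, "adp_c": -1, "pi_c": -1,
                    "ac_c": 1, "coa_c": 1, "atp_c": 1},
            0, big, ecs=["2.3.1.8", "2.7.2.1"], gpr="pta and ackA",
            name="acetate kinase (lumped with PTA)", kegg="R00315")
    if spec.butyrate:
        mets.append(_met("but_c", "butyrate"))
        add("BUK", {"accoa_c": -2, "nadh_c": -2, "adp_c": -1, "pi_c": -1,
                    "but_c": 1, "coa_c": 2, "nad_c": 2, "atp_c": 1, "h2o_c": 1},
            0, big, ecs=["1.1.1.157", "2.7.2.7"], gpr="hbd and buk",
            name="butyrate formation (lumped)")
    if spec.lactate:
        mets.append(_met("lac_c", "lactate"))
        add("LDH", {"pyr_c": -1, "nadh_c": -1, "lac_c": 1, "nad_c": 1},
            0, big, ecs=["1.1.1.27"], gpr="ldhA", name="lactate dehydrogenase")
    if spec.ethanol:
        mets.append(_met("etoh_c", "ethanol"))
        add("ADHE", {"accoa_c": -1, "nadh_c": -2,
                     "etoh_c": 1, "coa_c": 1, "nad_c": 2},
            0, big, ecs=["1.2.1.10"], gpr="adhE",
            name="aldehyde/alcohol dehydrogenase (lumped)")
    if spec.pdo:
        mets += [_met("hpa_c", "3-hydroxypropionaldehyde"), _met("pdo_c", "1,3-propanediol")]
        add("GDHT", {"glyc_c": -1, "hpa_c": 1, "h2o_c": 1},
            0, big, ecs=["4.2.1.30"], gpr="dhaB", name="glycerol dehydratase")
        add("PDODH", {"hpa_c": -1, "nadh_c": -1, "pdo_c": 1, "nad_c": 1},
            0, big, ecs=["1.1.1.202"], gpr="dhaT", name="PDO dehydrogenase")

    # anabolism: three lumped precursor pools
    add("SSKEL", {"pyr_c": -1, "atp_c": -1, "h2o_c": -1,
                  "skel_c": 1, "adp_c": 1, "pi_c": 1},
        0, big, ecs=["2.3.3.1"], gpr="sklS", name="carbon-skeleton pool synthesis")
    add("SNCMP", {"pyr_c": -1, "nh3_c": -1, "nadh_c": -1,
                  "ncmp_c": 1, "nad_c": 1, "h2o_c": 1},
        0, big, ecs=["2.6.1.2"], gpr="alaT", name="nitrogen-compound pool synthesis")
    add("SLIP", {"accoa_c": -2, "nadh_c": -2,
                 "lip_c": 1, "coa_c": 2, "nad_c": 2},
        0, big, ecs=["2.3.1.9"], gpr="atoB", name="lipid pool synthesis")
    add("BIOMASS", {"skel_c": -4.0, "ncmp_c": -6.0, "lip_c": -1.5,
                    "atp_c": -spec.gam, "h2o_c": -spec.gam,
                    "biomass_c": 1, "adp_c": spec.gam, "pi_c": spec.gam},
        0, big, name="biomass synthesis")
    add("NGAM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
        spec.ngam, spec.ngam, name="non-growth maintenance")

    # exchanges (negative flux = uptake)
    def ex(mid, lb, ub):
        add(f"EX_{mid[:-2]}", {mid: -1}, lb, ub)
        rxns[-1].is_exchange = True

    ex("glyc_e", -spec.glycerol_uptake, 0.0)
    if spec.glucose:
        ex("glc_c", 0.0, 0.0)
    ex("nh3_c", -big, 0.0)
    ex("h2o_c", -big, big)
    ex("co2_c", 0.0, big)
    if spec.h2:
        ex("h2_c", 0.0, big)
    if spec.formate:
        ex("for_c", 0.0, big)
    if spec.acetate:
        ex("ac_c", 0.0, big)
    if spec.butyrate:
        ex("but_c", 0.0, big)
    if spec.lactate:
        ex("lac_c", 0.0, big)
    if spec.ethanol:
        ex("etoh_c", 0.0, big)
    if spec.pdo:
        ex("pdo_c", 0.0, big)
    ex("biomass_c", 0.0, big)

    genes = sorted({g for r in rxns for g in r.gpr.replace("(", " ").replace(")", " ").split()
                    if g not in ("and", "or")})
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes,
        biomass_reaction_id="BIOMASS", ngam_reaction_id="NGAM",
        atp_producing_ids=[r for r in ("GLYOX", "GLYCL", "ACK", "BUK")
                           if any(x.id == r for x in rxns)],
        gam=spec.gam, ngam=spec.ngam, id="toy_glycerol",
    )
    model.validate()
    return model


def random_model(n_metabolites: int, n_reactions: int, seed: int = 0) -> MetabolicModel:
    """Random connected mass-balanced network for oracle-equivalence tests.

    All carrier metabolites share the formula C so that 1:1 conversions are
    trivially balanced; a chain from an uptake exchange to the biomass sink
    guarantees at least one unblocked exchange-to-exchange path, and extra
    random 1:1 conversions create branches, shortcuts and dead ends.
    Deterministic for a given seed.
    """
    if n_reactions < n_metabolites:
        raise ValueError("need n_reactions >= n_metabolites for an "
                         "underdetermined network")
    if n_metabolites < 3:
        raise ValueError("need at least 3 metabolites")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"m{i}", name=f"m{i}", formula={"C": 1.0})
            for i in range(n_metabolites)]
    mets.append(Metabolite(id="biomass_c", name="biomass", formula={}))
    rxns: list[Reaction] = []
    # backbone chain m0 -> m1 -> ... -> m_last
    chain = list(range(n_metabolites))
    for a, b in zip(chain[:-1], chain[1:]):
        rxns.append(Reaction(id=f"R{len(rxns)}",
                             stoichiometry={f"m{a}": -1.0, f"m{b}": 1.0},
                             lower_bound=0.0, upper_bound=1000.0,
                             enzymes=[f"{1 + len(rxns) % 6}.1.1.{1 + len(rxns)}"]))
    # random extra conversions (may create dead ends / parallel routes)
    while len(rxns) < n_reactions - 1:
        a, b = rng.choice(n_metabolites, size=2, replace=False)
        rev = bool(rng.random() < 0.3)
        rxns.append(Reaction(id=f"R{len(rxns)}",
                             stoichiometry={f"m{a}": -1.0, f"m{b}": 1.0},
                             lower_bound=-1000.0 if rev else 0.0,
                             upper_bound=1000.0,
                             enzymes=[f"{1 + len(rxns) % 6}.1.1.{1 + len(rxns)}"]))
    rxns.append(Reaction(id="BIOMASS",
                         stoichiometry={f"m{n_metabolites - 1}": -1.0,
                                        "biomass_c": 1.0},
                         lower_bound=0.0, upper_bound=1000.0))
    # maintenance stub (zero rate): keeps the container invariant satisfied
    # without constraining the random network
    mets += [Metabolite(id="atp_r", formula={"C": 1.0, "P": 1.0}),
             Metabolite(id="adp_r", formula={"P": 1.0}),
             Metabolite(id="w_r", formula={"C": 1.0})]
    rxns.append(Reaction(id="GEN", stoichiometry={"m0": -1.0, "adp_r": -1.0,
                                                  "atp_r": 1.0},
                         lower_bound=0.0, upper_bound=1000.0))
    rxns.append(Reaction(id="NGAM", stoichiometry={"atp_r": -1.0, "adp_r": 1.0,
                                                   "w_r": 1.0},
                         lower_bound=0.0, upper_bound=0.0))
    for mid, lb, ub in (("m0", -10.0, 0.0), ("biomass_c", 0.0, 1000.0),
                        ("w_r", 0.0, 1000.0)):
        rxns.append(Reaction(id=f"EX_{mid}", stoichiometry={mid: -1.0},
                             lower_bound=lb, upper_bound=ub, is_exchange=True))
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           genes=[], biomass_reaction_id="BIOMASS",
                           ngam_reaction_id="NGAM", atp_producing_ids=["GEN"],
                           gam=0.0, ngam=0.0, id=f"random_{seed}")
    model.validate()
    return model


def synthetic_expression(model: MetabolicModel, flux, false_pos: float = 0.0,
                         false_neg: float = 0.0, seed: int = 0,
                         tol_zero: float = 1e-6):
    """Derive an expressed-enzyme list from a flux state, with noise.

    Active enzymes (any catalyzed reaction with ``|v| > tol_zero``) are
    expressed; ``false_neg`` drops active enzymes, ``false_pos`` adds
    inactive ones.  Reproducible for a given seed.
    """
    from .omics_compare import ExpressionSet

    if not (0.0 <= false_pos <= 1.0 and 0.0 <= false_neg <= 1.0):
        raise ValueError("noise rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    active: list[str] = []
    inactive: list[str] = []
    for ec in model.enzymes:
        on = any(abs(flux.fluxes.get(r.id, 0.0)) > tol_zero
                 for r in model.reactions_for_enzyme(ec))
        (active if on else inactive).append(ec)
    expressed = [ec for ec in active if rng.random() >= false_neg]
    expressed += [ec for ec in inactive if rng.random() < false_pos]
    return ExpressionSet(source="synthetic", ecs=sorted(expressed),
                         provenance=f"synthetic(seed={seed}, fp={false_pos}, fn={false_neg})")
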