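"""Metabolic model data structures, I/O and consistency checks.

The central container is :class:`MetabolicModel`: a stoichiometric matrix
over metabolites and reactions, flux bounds in mmol·gDW⁻¹·h⁻¹ (the biomass
reaction carries h⁻¹), gene–protein–reaction (GPR) associations, EC-number
annotations, and designated biomass / non-growth maintenance (NGAM) /
ATP-producing reactions.  Models can be read and written as SBML Level 3
(FBC-style flux bounds, with a fallback for legacy files that encode bounds
as kinetic-law parameters) or as a diff-able two-table TSV dialect.

Sign convention: for exchange reactions, negative flux is uptake and
positive flux is secretion.  User-facing "uptake flux" values elsewhere in
the package are magnitudes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxState",
    "parse_formula",
    "formula_to_string",
    "load_model",
    "write_model",
    "check_balance",
    "biomass_elemental_composition",
    "model_summary",
]

#: LP residual tolerance on Σ_j S_ij v_j, mmol·gDW⁻¹·h⁻¹.
TOL_BALANCE = 1e-6
#: Atom-count tolerance for elemental balance checking.
TOL_FORMULA = 1e-4

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d+\.?\d*|\.\d+)?")


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed in the declared format."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula like ``CH1.624O0.456`` into an atom map.

    Real-valued atom counts are allowed (per-carbon biomass formulas).
    """
    if formula is None or formula == "":
        return {}
    atoms: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ModelFormatError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        count = float(m.group(2)) if m.group(2) else 1.0
        atoms[m.group(1)] = atoms.get(m.group(1), 0.0) + count
    if pos != len(formula):
        raise ModelFormatError(f"cannot parse formula {formula!r} at position {pos}")
    return atoms


def formula_to_string(atoms: dict[str, float]) -> str:
    """Inverse of :func:`parse_formula`; Hill-ish deterministic ordering."""
    order = sorted(atoms, key=lambda el: (el != "C", el != "H", el))
    parts = []
    for el in order:
        n = atoms[el]
        if abs(n) < 1e-12:
            continue
        if abs(n - round(n)) < 1e-9:
            parts.append(el + ("" if round(n) == 1 else str(int(round(n)))))
        else:
            parts.append(f"{el}{n:g}")
    return "".join(parts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, float] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "cytosol"

    def molar_mass(self) -> float:
        """Approximate molar mass in g/mol from the elemental formula."""
        return sum(_ATOMIC_MASS.get(el, 0.0) * n for el, n in self.formula.items())


_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Fe": 55.845, "K": 39.098, "Na": 22.990, "Mg": 24.305,
    "Ca": 40.078, "Cl": 35.45, "Zn": 65.38, "Mn": 54.938, "Co": 58.933,
}


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: str = ""
    enzymes: list[str] = field(default_factory=list)
    is_exchange: bool = False
    kegg_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    biomass_reaction_id: str = ""
    ngam_reaction_id: str = ""
    atp_producing_ids: list[str] = field(default_factory=list)
    gam: float = 40.0     # mmol ATP·gDW⁻¹
    ngam: float = 5.0     # mmol ATP·gDW⁻¹·h⁻¹
    id: str = "model"

    def __post_init__(self) -> None:
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        self.reindex()

    def reindex(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError("duplicate reaction ids")

    # -- lookups ----------------------------------------------------------
    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self._met_index[mid]]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self._rxn_index[rid]]

    def has_reaction(self, rid: str) -> bool:
        return rid in self._rxn_index

    def reaction_index(self, rid: str) -> int:
        return self._rxn_index[rid]

    @property
    def biomass_reaction(self) -> Reaction:
        return self.reaction(self.biomass_reaction_id)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites × reactions); S_ij < 0 means consumed."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coeff in rxn.stoichiometry.items():
                S[self._met_index[mid], j] = coeff
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], float)
        ub = np.array([r.upper_bound for r in self.reactions], float)
        return lb, ub

    def reactions_for_enzyme(self, ec: str) -> list[Reaction]:
        """Reactions annotated with EC ``ec``; dashed ECs match by prefix."""
        if ec.endswith("-") or ".-" in ec:
            prefix = ec.rstrip("-").rstrip(".")
            return [
                r for r in self.reactions
                if any(e == ec or e.startswith(prefix + ".") or e == prefix
                       for e in r.enzymes)
            ]
        return [r for r in self.reactions if ec in r.enzymes]

    @property
    def enzymes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for ec in r.enzymes:
                seen.setdefault(ec, None)
        return list(seen)

    def copy(self) -> "MetabolicModel":
        import copy as _copy
        return _copy.deepcopy(self)

    def validate(self) -> None:
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {r.id} references unknown metabolite {mid}")
            if r.is_exchange and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id} must touch exactly one metabolite")
        if self.biomass_reaction_id and self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model")
        if self.ngam_reaction_id and self.ngam_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"NGAM reaction {self.ngam_reaction_id!r} not in model")
        for rid in self.atp_producing_ids:
            if rid not in self._rxn_index:
                raise ModelValidationError(f"ATP-producing id {rid!r} not in model")


@dataclass
class FluxState:
    """One steady-state flux vector with its objective value and status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded | local_optimum

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes.get(r.id, 0.0) for r in model.reactions])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"objective_value": self.objective_value,
                       "status": self.status, "fluxes": self.fluxes}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FluxState":
        with open(path) as fh:
            d = json.load(fh)
        return cls(fluxes=d["fluxes"], objective_value=d["objective_value"],
                   status=d["status"])


# ---------------------------------------------------------------------------
# Exchange detection
# ---------------------------------------------------------------------------

def flag_exchanges(model: MetabolicModel) -> None:
    """Auto-flag single-metabolite reactions as exchanges."""
    for r in model.reactions:
        if len(r.stoichiometry) == 1 and r.id != model.biomass_reaction_id:
            r.is_exchange = True


# ---------------------------------------------------------------------------
# Balance checking and biomass composition
# ---------------------------------------------------------------------------

@dataclass
class Imbalance:
    reaction_id: str
    kind: str          # "atom" | "charge" | "unverifiable"
    element: str | None
    delta: float

    def __repr__(self) -> str:  # compact, useful in assertion messages
        return f"Imbalance({self.reaction_id}, {self.kind}, {self.element}, {self.delta:+g})"


def check_balance(model: MetabolicModel,
                  tol: float = TOL_FORMULA) -> list[Imbalance]:
    """Check atom and charge conservation of every internal reaction.

    Exchange reactions are exempt (they exist to create net system
    exchange), and so is the biomass reaction unless the biomass metabolite
    itself carries a formula.  Metabolites without a formula make a reaction
    unverifiable, which is reported but does not count as a failure.
    """
    problems: list[Imbalance] = []
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        if rxn.id == model.biomass_reaction_id:
            prods = [m for m, c in rxn.stoichiometry.items() if c > 0]
            if any(not model.metabolite(m).formula for m in prods):
                continue
        missing = [mid for mid in rxn.stoichiometry
                   if not model.metabolite(mid).formula]
        if missing:
            problems.append(Imbalance(rxn.id, "unverifiable", None, float(len(missing))))
            continue
        atoms: dict[str, float] = {}
        charge = 0.0
        for mid, coeff in rxn.stoichiometry.items():
            met = model.metabolite(mid)
            for el, n in met.formula.items():
                atoms[el] = atoms.get(el, 0.0) + coeff * n
            charge += coeff * met.charge
        for el, delta in sorted(atoms.items()):
            if abs(delta) > tol:
                problems.append(Imbalance(rxn.id, "atom", el, delta))
        if abs(charge) > tol:
            problems.append(Imbalance(rxn.id, "charge", None, charge))
    return problems


def biomass_elemental_composition(model: MetabolicModel) -> dict[str, float]:
    """Biomass elemental formula per carbon atom.

    Sums atoms over the stoichiometric consumption of the biomass
    precursors and normalizes by total carbon, giving the CH_xO_y... form
    conventionally quoted for cell dry weight.  Consumption is net:
    by-products other than biomass itself (the ADP, phosphate and protons
    returned by growth-associated ATP hydrolysis) are subtracted, so
    maintenance ATP cycling does not inflate the composition.
    """
    rxn = model.biomass_reaction
    totals: dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        met = model.metabolite(mid)
        if coeff > 0 and (not met.formula or "biomass" in met.id.lower()):
            continue  # the biomass species itself
        for el, n in met.formula.items():
            totals[el] = totals.get(el, 0.0) + (-coeff) * n
    carbon = totals.get("C", 0.0)
    if carbon <= 0:
        raise ModelValidationError("biomass precursors contain no carbon")
    return {el: n / carbon for el, n in totals.items()}


def model_summary(model: MetabolicModel) -> dict[str, int]:
    """Count genes, enzymes, metabolites and reactions by class.

    Reactions partition into cytosolic, transport (spanning compartments)
    and exchange; the three counts always sum to the total.
    """
    n_exchange = sum(1 for r in model.reactions if r.is_exchange)
    n_transport = 0
    for r in model.reactions:
        if r.is_exchange:
            continue
        comps = {model.metabolite(m).compartment for m in r.stoichiometry}
        if len(comps) > 1:
            n_transport += 1
    total = len(model.reactions)
    return {
        "genes": len(model.genes),
        "enzymes": len(model.enzymes),
        "total_reactions": total,
        "cytosolic_reactions": total - n_transport - n_exchange,
        "transport_reactions": n_transport,
        "exchange_reactions": n_exchange,
        "total_metabolites": len(model.metabolites),
    }


# ---------------------------------------------------------------------------
# Tabular (TSV) I/O
# ---------------------------------------------------------------------------

def _equation_string(rxn: Reaction) -> str:
    lhs, rhs = [], []
    for mid in sorted(rxn.stoichiometry):
        c = rxn.stoichiometry[mid]
        term = mid if abs(abs(c) - 1) < 1e-12 else f"{abs(c):g} {mid}"
        (lhs if c < 0 else rhs).append(term)
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}"


def _parse_equation(eq: str) -> dict[str, float]:
    for arrow in ("<=>", "-->", "<--", "->"):
        if arrow in eq:
            left, right = eq.split(arrow)
            break
    else:
        raise ModelFormatError(f"no arrow in equation {eq!r}")
    stoich: dict[str, float] = {}
    for side, sign in ((left, -1.0), (right, +1.0)):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coeff, mid = float(bits[0]), bits[1]
            elif len(bits) == 1:
                coeff, mid = 1.0, bits[0]
            else:
                raise ModelFormatError(f"bad equation term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coeff
    return stoich


def _write_table(model: MetabolicModel, path) -> None:
    import pandas as pd

    rxn_rows = []
    for r in model.reactions:
        rxn_rows.append({
            "id": r.id, "name": r.name, "equation": _equation_string(r),
            "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
            "gpr": r.gpr, "enzymes": ";".join(r.enzymes),
            "is_exchange": int(r.is_exchange), "kegg_id": r.kegg_id or "",
        })
    met_rows = [{"id": m.id, "name": m.name,
                 "formula": formula_to_string(m.formula),
                 "charge": m.charge, "compartment": m.compartment}
                for m in model.metabolites]
    meta = {"id": model.id, "biomass_reaction_id": model.biomass_reaction_id,
            "ngam_reaction_id": model.ngam_reaction_id,
            "atp_producing_ids": ";".join(model.atp_producing_ids),
            "gam": model.gam, "ngam": model.ngam,
            "genes": ";".join(model.genes)}
    path = str(path)
    with open(path, "w") as fh:
        fh.write("#MODEL\t" + json.dumps(meta) + "\n")
        fh.write("#REACTIONS\n")
        pd.DataFrame(rxn_rows).to_csv(fh, sep="\t", index=False)
        fh.write("#METABOLITES\n")
        pd.DataFrame(met_rows).to_csv(fh, sep="\t", index=False)


def _read_table(path) -> MetabolicModel:
    import io

    import pandas as pd

    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        meta = json.loads(lines[0].split("\t", 1)[1])
        i_rxn = lines.index("#REACTIONS")
        i_met = lines.index("#METABOLITES")
    except (IndexError, ValueError) as exc:
        raise ModelFormatError(f"{path}: not a model table ({exc})") from exc
    rxn_df = pd.read_csv(io.StringIO("\n".join(lines[i_rxn + 1:i_met])),
                         sep="\t", keep_default_na=False)
    met_df = pd.read_csv(io.StringIO("\n".join(lines[i_met + 1:])),
                         sep="\t", keep_default_na=False)
    mets = [Metabolite(id=row["id"], name=str(row["name"]),
                       formula=parse_formula(str(row["formula"])),
                       charge=int(row["charge"]),
                       compartment=str(row["compartment"]))
            for _, row in met_df.iterrows()]
    rxns = []
    for _, row in rxn_df.iterrows():
        rxns.append(Reaction(
            id=row["id"], name=str(row["name"]),
            stoichiometry=_parse_equation(str(row["equation"])),
            lower_bound=float(row["lower_bound"]),
            upper_bound=float(row["upper_bound"]),
            gpr=str(row["gpr"]),
            enzymes=[e for e in str(row["enzymes"]).split(";") if e],
            is_exchange=bool(int(row["is_exchange"])),
            kegg_id=str(row["kegg_id"]) or None,
        ))
    model = MetabolicModel(
        metabolites=mets, reactions=rxns,
        genes=[g for g in str(meta.get("genes", "")).split(";") if g],
        biomass_reaction_id=meta.get("biomass_reaction_id", ""),
        ngam_reaction_id=meta.get("ngam_reaction_id", ""),
        atp_producing_ids=[x for x in str(meta.get("atp_producing_ids", "")).split(";") if x],
        gam=float(meta.get("gam", 40.0)), ngam=float(meta.get("ngam", 5.0)),
        id=meta.get("id", "model"),
    )
    return model


# ---------------------------------------------------------------------------
# SBML I/O (libsbml, Level 3 + FBC bounds; legacy kinetic-law fallback)
# ---------------------------------------------------------------------------

_SBML_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str) -> str:
    sid = _SBML_BAD.sub("_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def _write_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    for m in model.metabolites:
        if m.charge != int(m.charge):
            raise ModelValidationError(f"metabolite {m.id}: non-integer charge")

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_sid(model.id))
    fbc = sb.getPlugin("fbc")
    fbc.setStrict(False)

    meta = {"biomass_reaction_id": model.biomass_reaction_id,
            "ngam_reaction_id": model.ngam_reaction_id,
            "atp_producing_ids": model.atp_producing_ids,
            "gam": model.gam, "ngam": model.ngam,
            "genes": model.genes}
    sb.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'><p>GSMFLUX:"
                f"{json.dumps(meta)}</p></body>")

    comps = sorted({m.compartment for m in model.metabolites}) or ["cytosol"]
    for cid in comps:
        c = sb.createCompartment()
        c.setId(_sid(cid)); c.setName(cid); c.setConstant(True); c.setSize(1.0)

    for m in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(_sid(m.id)); sp.setName(m.name or m.id)
        sp.setCompartment(_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        spf = sp.getPlugin("fbc")
        spf.setCharge(int(m.charge))
        if m.formula:
            # FBC chemicalFormula requires integer counts; real-valued
            # formulas (biomass precursors) go in the notes instead.
            f = m.formula
            if all(abs(n - round(n)) < 1e-9 for n in f.values()):
                spf.setChemicalFormula(formula_to_string(f))
            else:
                sp.setNotes("<body xmlns='http://www.w3.org/1999/xhtml'>"
                            f"<p>FORMULA:{formula_to_string(f)}</p></body>")

    bound_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            p = sb.createParameter()
            pid = f"fb_{len(bound_ids)}"
            p.setId(pid); p.setValue(value); p.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    seen_genes: set[str] = set()
    for g in model.genes:
        gp = fbc.createGeneProduct()
        gp.setId(_sid(g)); gp.setLabel(g)
        seen_genes.add(_sid(g))

    for r in model.reactions:
        rx = sb.createReaction()
        rx.setId(_sid(r.id)); rx.setName(r.name or r.id)
        rx.setReversible(r.reversible); rx.setFast(False)
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_sid(mid)); ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rf = rx.getPlugin("fbc")
        rf.setLowerFluxBound(bound_param(r.lower_bound))
        rf.setUpperFluxBound(bound_param(r.upper_bound))
        notes = {"enzymes": r.enzymes, "is_exchange": r.is_exchange,
                 "kegg_id": r.kegg_id or "", "gpr": r.gpr}
        rx.setNotes("<body xmlns='http://www.w3.org/1999/xhtml'>"
                    f"<p>GSMFLUX:{json.dumps(notes)}</p></body>")
        if r.gpr:
            gpa = rf.createGeneProductAssociation()
            # libsbml parses "and"/"or" infix into the association tree
            gpa.setAssociation(_sid_gpr(r.gpr), True, False)

    libsbml.writeSBMLToFile(doc, str(path))


def _sid_gpr(gpr: str) -> str:
    tokens = re.split(r"(\(|\)|\s+)", gpr)
    out = []
    for t in tokens:
        if t is None or t == "" or t.isspace():
            out.append(" ")
        elif t in ("(", ")") or t.lower() in ("and", "or"):
            out.append(t)
        else:
            out.append(_sid(t))
    return "".join(out)


def _notes_payload(obj, tag: str) -> str | None:
    import html

    notes = obj.getNotesString() if obj.isSetNotes() else ""
    notes = html.unescape(notes)
    m = re.search(tag + r":(\{.*?\})</", notes, re.S) or \
        re.search(tag + r":([^<]*)<", notes)
    return m.group(1) if m else None


def _read_sbml(path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}")
    sb = doc.getModel()
    if sb is None:
        raise ModelFormatError(f"{path}: no <model> element found")

    meta: dict = {}
    payload = _notes_payload(sb, "GSMFLUX")
    if payload:
        meta = json.loads(payload)

    mets = []
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        spf = sp.getPlugin("fbc")
        formula: dict[str, float] = {}
        charge = 0
        if spf is not None:
            if spf.isSetChemicalFormula():
                formula = parse_formula(spf.getChemicalFormula())
            if spf.isSetCharge():
                charge = spf.getCharge()
        fp = _notes_payload(sp, "FORMULA")
        if fp:
            formula = parse_formula(fp.strip())
        comp = sp.getCompartment()
        cobj = sb.getCompartment(comp)
        mets.append(Metabolite(id=sp.getId(), name=sp.getName() or sp.getId(),
                               formula=formula, charge=charge,
                               compartment=(cobj.getName() or comp) if cobj else comp))

    params = {sb.getParameter(i).getId(): sb.getParameter(i).getValue()
              for i in range(sb.getNumParameters())}

    rxns = []
    for j in range(sb.getNumReactions()):
        rx = sb.getReaction(j)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        lb, ub = -1000.0, 1000.0
        rf = rx.getPlugin("fbc")
        if rf is not None and rf.isSetLowerFluxBound():
            lb = params.get(rf.getLowerFluxBound(), lb)
            ub = params.get(rf.getUpperFluxBound(), ub)
        else:
            # Legacy dialect: bounds as kinetic-law local parameters.
            kl = rx.getKineticLaw()
            if kl is not None:
                for k in range(kl.getNumParameters()):
                    p = kl.getParameter(k)
                    if p.getId().upper() in ("LOWER_BOUND", "LB"):
                        lb = p.getValue()
                    elif p.getId().upper() in ("UPPER_BOUND", "UB"):
                        ub = p.getValue()
            if not rx.getReversible() and lb < 0:
                lb = 0.0
        enzymes: list[str] = []
        gpr = ""
        kegg = None
        is_exchange = False
        payload = _notes_payload(rx, "GSMFLUX")
        if payload:
            d = json.loads(payload)
            enzymes = d.get("enzymes", [])
            gpr = d.get("gpr", "")
            kegg = d.get("kegg_id") or None
            is_exchange = bool(d.get("is_exchange", False))
        rxns.append(Reaction(id=rx.getId(), name=rx.getName() or rx.getId(),
                             stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                             gpr=gpr, enzymes=enzymes, is_exchange=is_exchange,
                             kegg_id=kegg))

    genes = meta.get("genes")
    if genes is None:
        fbc = sb.getPlugin("fbc")
        genes = [fbc.getGeneProduct(i).getLabel() or fbc.getGeneProduct(i).getId()
                 for i in range(fbc.getNumGeneProducts())] if fbc else []

    model = MetabolicModel(
        metabolites=mets, reactions=rxns, genes=genes,
        biomass_reaction_id=meta.get("biomass_reaction_id", ""),
        ngam_reaction_id=meta.get("ngam_reaction_id", ""),
        atp_producing_ids=meta.get("atp_producing_ids", []),
        gam=float(meta.get("gam", 40.0)), ngam=float(meta.get("ngam", 5.0)),
        id=sb.getId() or "model",
    )
    if not model.biomass_reaction_id:
        guesses = [r.id for r in rxns if "biomass" in r.id.lower()
                   or "biomass" in r.name.lower()]
        if guesses:
            model.biomass_reaction_id = guesses[0]
    return model


def load_model(path, format: str = "auto") -> MetabolicModel:
    """Load a model from SBML or the tabular TSV dialect.

    ``format`` may be ``sbml``, ``table`` or ``auto`` (sniff by content).
    Exchange reactions are auto-flagged if the file does not flag them.
    """
    path = str(path)
    if format == "auto":
        with open(path, "rb") as fh:
            head = fh.read(200)
        format = "sbml" if b"<?xml" in head or b"<sbml" in head else "table"
    if format == "sbml":
        model = _read_sbml(path)
    elif format == "table":
        model = _read_table(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    if not any(r.is_exchange for r in model.reactions):
        flag_exchanges(model)
    if not model.biomass_reaction_id:
        raise ModelValidationError(
            f"{path}: no biomass reaction designated or recognizable")
    model.reindex()
    model.validate()
    return model


def write_model(model: MetabolicModel, path, format: str = "sbml") -> None:
    """Write a model as SBML L3/FBC or as the tabular TSV dialect.

    ``load_model(write_model(m))`` round-trips stoichiometry, bounds,
    annotations and designated-reaction metadata field by field.
    """
    model.validate()
    if format == "sbml":
        _write_sbml(model, path)
    elif format == "table":
        _write_table(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")
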