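"""Domain types for constraint-based metabolic models and their file formats.

The central object is :class:`MetabolicModel`: metabolites, reactions with
signed stoichiometry and flux bounds, and a single objective reaction
(normally biomass).  Conventions follow common constraint-based practice:

* negative stoichiometric coefficients denote consumption, positive denote
  production;
* irreversibility is encoded purely through bounds (``lower_bound >= 0``),
  never by duplicating a reversed reaction;
* exchange reactions touch exactly one metabolite and are written in the
  secretion direction (``met_e0 ->``); uptake is a negative flux enabled by
  a negative lower bound, so "set methane uptake to 14.9" means
  ``lower_bound = -14.9``;
* SEED-style compartment suffixes ("_c0", "_e0") are kept as part of the
  metabolite id and additionally parsed into the ``compartment`` field.

Flux units are mmol g-DW^-1 h^-1 throughout; the biomass reaction is scaled
so that a flux of 1 equals a specific growth rate of 1 h^-1.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace

from typing import Iterable

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "EquationParseError",
    "SBMLParseError",
    "DEFAULT_BOUND",
    "read_sbml",
    "write_sbml",
    "read_tsv_model",
    "write_tsv_model",
    "stoichiometric_matrix",
    "parse_equation",
    "format_equation",
]

logger = logging.getLogger(__name__)

#: Magnitude used for "effectively unconstrained" flux bounds.
DEFAULT_BOUND = 1000.0

_COMPARTMENT_SUFFIX = re.compile(r"_([a-z]\d+)$")


class ModelValidationError(ValueError):
    """A model violates a structural invariant (dangling reference, bad bounds...)."""


class EquationParseError(ValueError):
    """A reaction equation string could not be parsed."""


class SBMLParseError(ValueError):
    """An SBML file is malformed or lacks required structure."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            m = _COMPARTMENT_SUFFIX.search(self.id)
            self.compartment = m.group(1) if m else "c0"
        if not self.name:
            self.name = self.id

    def elements(self) -> dict[str, int]:
        """Parse the elemental formula into a {element: count} map."""
        if not self.formula:
            return {}
        out: dict[str, int] = {}
        for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", self.formula):
            if sym:
                out[sym] = out.get(sym, 0) + (int(num) if num else 1)
        return out


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_association: str | None = None
    ec_numbers: list[str] = field(default_factory=list)
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.name:
            self.name = self.id
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(
            self,
            stoichiometry=dict(self.stoichiometry),
            ec_numbers=list(self.ec_numbers),
        )


@dataclass
class MetabolicModel:
    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_id: str | None = None
    compartments: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.compartments:
            self.compartments = {m.compartment for m in self.metabolites}
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- lookups ---------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- mutation helpers -----------------------------------------------

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            objective_id=self.objective_id,
            compartments=set(self.compartments),
        )

    def set_bounds(self, rxn_id: str, lb: float, ub: float) -> None:
        if lb > ub:
            raise ModelValidationError(f"{rxn_id}: lb {lb} > ub {ub}")
        r = self.reaction(rxn_id)
        r.lower_bound, r.upper_bound = lb, ub

    def set_objective(self, rxn_id: str) -> None:
        if rxn_id not in self._rxn_index:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id}")
        self.objective_id = rxn_id

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)
        self._met_index[met.id] = met
        self.compartments.add(met.compartment)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any structural defect."""
        seen_m: set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            if m.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {m.id}: compartment {m.compartment!r} not declared"
                )
        seen_r: set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(f"reaction {r.id}: lb > ub")
            dangling = [m for m in r.stoichiometry if m not in seen_m and m not in self._met_index]
            if dangling:
                raise ModelValidationError(
                    f"reaction {r.id}: dangling metabolite reference(s) {dangling}"
                )
            if r.is_exchange and len(r.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {r.id} must touch exactly one metabolite"
                )
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ModelValidationError(
                f"objective reaction {self.objective_id!r} is not in the model"
            )


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sparse.csc_matrix:
    """Sparse stoichiometric matrix S (metabolites x reactions).

    Entry (i, j) is the signed coefficient of ``model.metabolites[i]`` in
    ``model.reactions[j]``; column order matches reaction order.
    """
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_pos[met_id])
            cols.append(j)
            data.append(float(coef))
    return sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# ---------------------------------------------------------------------------
# Elemental bookkeeping
# ---------------------------------------------------------------------------

def reaction_element_balance(model: MetabolicModel, rxn_id: str) -> dict[str, float]:
    """Net element production of a reaction (positive = created, should be ~0).

    Metabolites without a formula contribute nothing; callers decide which
    reactions (exchanges, biomass) are exempt from balance.
    """
    net: dict[str, float] = {}
    for met_id, coef in model.reaction(rxn_id).stoichiometry.items():
        for elem, count in model.metabolite(met_id).elements().items():
            net[elem] = net.get(elem, 0.0) + coef * count
    return {e: v for e, v in net.items() if abs(v) > 1e-9}


def unbalanced_reactions(
    model: MetabolicModel,
    elements: tuple[str, ...] = ("C", "H", "O", "N", "P", "S"),
    skip: Iterable[str] = (),
) -> dict[str, dict[str, float]]:
    """Map of reaction id -> element imbalance, for all non-exempt reactions."""
    skip = set(skip)
    bad: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        if r.id in skip or r.is_exchange:
            continue
        net = {e: v for e, v in reaction_element_balance(model, r.id).items()
               if e in elements}
        if net:
            bad[r.id] = net
    return bad


# ---------------------------------------------------------------------------
# Reaction-equation strings
# ---------------------------------------------------------------------------

_ARROWS_REV = ["<=>", "<->", "⇌", "↔"]
_ARROWS_IRREV = ["-->", "->", "→", "=>"]
_TERM = re.compile(r"^(?:\((\d*\.?\d+)\)|(\d*\.?\d+))?\s*(\S.*)$")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse ``"A_c0 + 2 B_c0 -> C_c0"`` into ({A_c0: -1, B_c0: -2, C_c0: 1}, irrev).

    Returns the signed stoichiometry and a reversibility flag (True if a
    reversible arrow such as ``<=>`` was used).  Coefficients may be bare
    (``2 B_c0``) or parenthesised (``(2) B_c0``).  One side may be empty,
    as in exchange reactions (``A_e0 ->``).
    """
    arrow, reversible = None, False
    for a in _ARROWS_REV:
        if a in text:
            arrow, reversible = a, True
            break
    if arrow is None:
        for a in _ARROWS_IRREV:
            if a in text:
                arrow = a
                break
    if arrow is None:
        raise EquationParseError(f"no reaction arrow found in {text!r}")
    lhs, rhs = text.split(arrow, 1)

    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s\+\s|^\+\s", side):
            term = term.strip()
            if not term:
                continue
            m = _TERM.match(term)
            if not m:
                raise EquationParseError(f"cannot parse term {term!r} in {text!r}")
            coef = float(m.group(1) or m.group(2) or 1.0)
            met = m.group(3).strip()
            if not met or " " in met:
                # a bare coefficient followed by a multi-word token is malformed
                parts = met.split()
                if len(parts) == 2 and re.fullmatch(r"\d*\.?\d+", parts[0]):
                    coef, met = coef * float(parts[0]), parts[1]
                else:
                    raise EquationParseError(f"cannot parse term {term!r} in {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise EquationParseError(f"equation {text!r} has empty net stoichiometry")
    return stoich, reversible


def _fmt_coef(c: float) -> str:
    if c == int(c):
        c = int(c)
    return "" if c == 1 else f"{c} "


def format_equation(rxn: Reaction) -> str:
    """Render a reaction as an equation string (inverse of :func:`parse_equation`)."""
    lhs = [f"{_fmt_coef(-c)}{m}" for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [f"{_fmt_coef(c)}{m}" for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ---------------------------------------------------------------------------
# Tab-separated model tables
# ---------------------------------------------------------------------------

_TSV_HEADER = [
    "id", "name", "equation", "lower_bound", "upper_bound",
    "gene_association", "ec_numbers",
]


def read_tsv_model(path: str, model_id: str | None = None) -> MetabolicModel:
    """Read a tab-separated reaction table into a model.

    Two dialects are accepted.  The full dialect has a header row
    ``id name equation lower_bound upper_bound gene_association ec_numbers``.
    The minimal dialect is headerless with positional columns
    ``id <tab> equation [<tab> rev|irrev [<tab> gene_association]]``; bounds
    then default to (0, 1000) for irreversible and (-1000, 1000) for
    reversible rows, with the arrow style (``->`` vs ``<=>``) deciding
    reversibility unless a marker column overrides it.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and any(c.strip() for c in r)]
    if not rows:
        raise EquationParseError(f"{path}: empty model table")

    has_header = [c.strip().lower() for c in rows[0][:3]] == _TSV_HEADER[:3]
    reactions: list[Reaction] = []
    mets: dict[str, Metabolite] = {}
    seen: set[str] = set()

    for lineno, row in enumerate(rows[1:] if has_header else rows,
                                 start=2 if has_header else 1):
        try:
            if has_header:
                rec = dict(zip(_TSV_HEADER, row + [""] * (len(_TSV_HEADER) - len(row))))
                rxn_id, name, eq = rec["id"].strip(), rec["name"].strip(), rec["equation"]
                stoich, rev = parse_equation(eq)
                lb = float(rec["lower_bound"]) if rec["lower_bound"].strip() else (
                    -DEFAULT_BOUND if rev else 0.0)
                ub = float(rec["upper_bound"]) if rec["upper_bound"].strip() else DEFAULT_BOUND
                gpr = rec["gene_association"].strip() or None
                ecs = [e for e in rec["ec_numbers"].split(";") if e.strip()]
            else:
                if len(row) < 2:
                    raise EquationParseError("expected at least id and equation columns")
                rxn_id, eq = row[0].strip(), row[1]
                name, ecs = rxn_id, []
                stoich, rev = parse_equation(eq)
                if len(row) >= 3 and row[2].strip():
                    marker = row[2].strip().lower()
                    if marker in ("rev", "reversible"):
                        rev = True
                    elif marker in ("irrev", "irreversible"):
                        rev = False
                    else:
                        raise EquationParseError(f"unknown reversibility marker {row[2]!r}")
                gpr = row[3].strip() if len(row) >= 4 and row[3].strip() else None
                lb = -DEFAULT_BOUND if rev else 0.0
                ub = DEFAULT_BOUND
        except EquationParseError as exc:
            raise EquationParseError(f"{path}, row {lineno}: {exc}") from exc
        if rxn_id in seen:
            raise ModelValidationError(f"{path}, row {lineno}: duplicate reaction id {rxn_id!r}")
        seen.add(rxn_id)
        for met_id in stoich:
            mets.setdefault(met_id, Metabolite(id=met_id))
        reactions.append(Reaction(
            id=rxn_id, name=name, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gene_association=gpr,
            ec_numbers=ecs, is_exchange=len(stoich) == 1,
        ))

    model = MetabolicModel(
        id=model_id or "tsv_model",
        metabolites=list(mets.values()),
        reactions=reactions,
    )
    model.validate()
    return model


def write_tsv_model(model: MetabolicModel, path: str) -> None:
    """Write the full-dialect tab-separated reaction table for *model*."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_HEADER)
        for r in model.reactions:
            w.writerow([
                r.id, r.name, format_equation(r),
                repr(r.lower_bound), repr(r.upper_bound),
                r.gene_association or "", ";".join(r.ec_numbers),
            ])


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _sanitize_sid(raw: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML model (Level 3 + fbc preferred, Level 2 accepted).

    Bounds come from the fbc flux-bounds package when present, else from
    legacy ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters; missing
    bounds fall back to defaults with a logged warning.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(
                f"{path}: line {err.getLine()}: {err.getMessage().strip()}"
            )
    sb = doc.getModel()
    if sb is None:
        raise SBMLParseError(f"{path}: no model element found")

    fbc = sb.getPlugin("fbc")

    metabolites = []
    boundary_ids = set()
    for i in range(sb.getNumSpecies()):
        sp = sb.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary_ids.add(sp.getId())
            continue
        formula, charge = None, None
        sfbc = sp.getPlugin("fbc")
        if sfbc is not None:
            if sfbc.isSetChemicalFormula():
                formula = sfbc.getChemicalFormula()
            if sfbc.isSetCharge():
                charge = sfbc.getCharge()
        metabolites.append(Metabolite(
            id=sp.getId(), name=sp.getName() or sp.getId(),
            compartment=sp.getCompartment() or "",
            formula=formula, charge=charge,
        ))
    met_ids = {m.id for m in metabolites}

    # fbc objective
    objective_id = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()

    def _param_value(pid: str) -> float | None:
        p = sb.getParameter(pid)
        return p.getValue() if p is not None else None

    reactions = []
    for i in range(sb.getNumReactions()):
        rx = sb.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            sid = sr.getSpecies()
            if sid in boundary_ids:
                continue
            stoich[sid] = stoich.get(sid, 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            sid = sr.getSpecies()
            if sid in boundary_ids:
                continue
            stoich[sid] = stoich.get(sid, 0.0) + sr.getStoichiometry()
        dangling = [m for m in stoich if m not in met_ids]
        if dangling:
            raise ModelValidationError(
                f"{path}: reaction {rx.getId()} references unknown metabolite(s) {dangling}"
            )

        lb = ub = None
        rfbc = rx.getPlugin("fbc")
        if rfbc is not None:
            if rfbc.isSetLowerFluxBound():
                lb = _param_value(rfbc.getLowerFluxBound())
            if rfbc.isSetUpperFluxBound():
                ub = _param_value(rfbc.getUpperFluxBound())
        if lb is None or ub is None:
            kl = rx.getKineticLaw()
            if kl is not None:
                for k in range(kl.getNumParameters()):
                    p = kl.getParameter(k)
                    if p.getId() == "LOWER_BOUND" and lb is None:
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND" and ub is None:
                        ub = p.getValue()
        if lb is None or ub is None:
            rev = rx.getReversible()
            lb = (-DEFAULT_BOUND if rev else 0.0) if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
            logger.warning(
                "%s: reaction %s has no explicit flux bounds; defaulting to (%g, %g)",
                path, rx.getId(), lb, ub,
            )
        if math.isinf(lb):
            lb = -DEFAULT_BOUND if lb < 0 else DEFAULT_BOUND
        if math.isinf(ub):
            ub = DEFAULT_BOUND if ub > 0 else -DEFAULT_BOUND

        gpr = None
        if rfbc is not None and rfbc.isSetGeneProductAssociation():
            assoc = rfbc.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gpr = assoc.toInfix() or None

        if not stoich:
            # every species was a boundary species: keep as a no-op exchange stub
            raise ModelValidationError(
                f"{path}: reaction {rx.getId()} has empty stoichiometry after "
                "dropping boundary species"
            )
        reactions.append(Reaction(
            id=rx.getId(), name=rx.getName() or rx.getId(),
            stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gene_association=gpr,
            is_exchange=len(stoich) == 1,
        ))

    compartments = {sb.getCompartment(i).getId() for i in range(sb.getNumCompartments())}
    model = MetabolicModel(
        id=sb.getId() or "sbml_model",
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id if objective_id in {r.id for r in reactions} else None,
        compartments=compartments or None or {m.compartment for m in metabolites},
    )
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 Version 1 with the fbc (v2) package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb = doc.createModel()
    sb.setId(_sanitize_sid(model.id))
    mplug = sb.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted(model.compartments):
        c = sb.createCompartment()
        c.setId(comp_id)
        c.setConstant(True)

    for m in model.metabolites:
        sp = sb.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialAmount(0.0)
        splug = sp.getPlugin("fbc")
        if m.formula:
            splug.setChemicalFormula(m.formula)
        splug.setCharge(int(m.charge) if m.charge is not None else 0)

    # shared bound parameters, one per distinct value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sb.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_ids: set[str] = set()
    for r in model.reactions:
        rx = sb.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        for met_id, coef in r.stoichiometry.items():
            if coef < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(met_id)
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(r.lower_bound))
        rplug.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gene_association:
            for g in re.findall(r"[A-Za-z0-9_.\-]+", r.gene_association):
                if g.lower() not in ("and", "or"):
                    gene_ids.add(g)

    for g in sorted(gene_ids):
        gp = mplug.createGeneProduct()
        gp.setId(_sanitize_sid(g))
        gp.setLabel(g)

    for r in model.reactions:
        if r.gene_association:
            rx = sb.getReaction(r.id)
            rplug = rx.getPlugin("fbc")
            gpa = rplug.createGeneProductAssociation()
            infix = re.sub(
                r"[A-Za-z0-9_.\-]+",
                lambda m: m.group(0) if m.group(0).lower() in ("and", "or")
                else _sanitize_sid(m.group(0)),
                r.gene_association,
            )
            gpa.setAssociation(infix)

    if model.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise IOError(f"failed to write SBML to {path}")
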