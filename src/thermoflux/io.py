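"""Readers and writers for the two model dialects plus medium tables.

Two on-disk forms are supported and round-trip into each other:

* a tab-delimited reaction list (columns: reaction id, name, equation,
  lower bound, upper bound, subsystem, GPR), with equations written
  ``a + 2 b --> c`` (irreversible) or ``a <==> b`` (reversible) and
  exchange reactions written one-sided (``glc_e <==>``);
* SBML Level 2 with flux bounds as kinetic-law parameters
  (``LOWER_BOUND``/``UPPER_BOUND``/``OBJECTIVE_COEFFICIENT``) and GPRs in
  reaction notes (``GENE_ASSOCIATION: ...``) — the dialect used by
  constraint-based reconstructions of this vintage.

Extracellular species are recognised by the ``_e`` id suffix; everything
else is cytosolic.  The ids ``biomass``, ``cellmass`` and ``cellulosome``
denote pseudometabolites.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import libsbml

from .gpr import parse_gpr
from .model import (
    CYTOSOL,
    DEFAULT_BOUND,
    EXTRACELLULAR,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from .model import PSEUDO_METABOLITES

logger = logging.getLogger(__name__)

__all__ = [
    "parse_tab_model",
    "parse_sbml_model",
    "write_model",
    "validate_model",
    "ValidationReport",
    "read_medium_tsv",
    "ModelParseError",
]


class ModelParseError(ValueError):
    pass


TAB_COLUMNS = ["id", "name", "equation", "lower_bound", "upper_bound", "subsystem", "gpr"]

_ARROWS = ["<==>", "<-->", "<=>", "-->", "->", "=>"]
_REVERSIBLE_ARROWS = {"<==>", "<-->", "<=>"}

_TERM = re.compile(r"^(?:\(?(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\)?\s+)?(\S+)$")


def _infer_metabolite(met_id: str) -> Metabolite:
    if met_id in PSEUDO_METABOLITES:
        return Metabolite(id=met_id, compartment=CYTOSOL, is_pseudo=True)
    comp = EXTRACELLULAR if met_id.endswith("_e") else CYTOSOL
    return Metabolite(id=met_id, compartment=comp)


def _parse_side(side: str, sign: float, stoich: Dict[str, float], row: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        m = _TERM.match(term)
        if m is None:
            raise ModelParseError(f"malformed equation term {term!r} in row {row!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coeff


def parse_reaction_equation(equation: str, row: str = "") -> Tuple[Dict[str, float], bool]:
    """Parse ``a + 2 b --> c`` into a stoichiometry map and reversibility flag."""
    for arrow in _ARROWS:
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            stoich: Dict[str, float] = {}
            _parse_side(left, -1.0, stoich, row or equation)
            _parse_side(right, +1.0, stoich, row or equation)
            if not stoich:
                raise ModelParseError(f"equation with no metabolites: {row or equation!r}")
            return stoich, arrow in _REVERSIBLE_ARROWS
    raise ModelParseError(f"no reaction arrow found in equation {row or equation!r}")


def format_reaction_equation(rxn: Reaction) -> str:
    arrow = "<==>" if rxn.reversible else "-->"

    def fmt(items):
        parts = []
        for met, c in items:
            c = abs(c)
            parts.append(met if c == 1 else f"{c:g} {met}")
        return " + ".join(parts)

    left = fmt([(m, c) for m, c in rxn.stoichiometry.items() if c < 0])
    right = fmt([(m, c) for m, c in rxn.stoichiometry.items() if c > 0])
    return f"{left} {arrow} {right}".strip()


def parse_tab_model(path, model_id: str = "model") -> MetabolicModel:
    """Read the tab-delimited reaction-list dialect.

    Metabolites are declared implicitly by their first appearance in an
    equation; a given id always maps to one Metabolite object, never a
    duplicate.  A header row is tolerated (detected by the literal
    ``id``/``reaction`` in the first column), as are ``#`` comments.
    """
    model = MetabolicModel(id=model_id)
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            first = cells[0].strip().lower()
            if lineno == 1 and first in ("id", "reaction", "reaction id", "abbreviation"):
                continue
            cells += [""] * (len(TAB_COLUMNS) - len(cells))
            rid, name, equation, lb_s, ub_s, subsystem, gpr_s = (
                c.strip() for c in cells[: len(TAB_COLUMNS)]
            )
            if not rid:
                raise ModelParseError(f"{path}: row {lineno} has no reaction id")
            try:
                stoich, reversible = parse_reaction_equation(equation, row=rid)
            except ModelParseError as exc:
                raise ModelParseError(f"{path}: row {lineno}: {exc}") from None
            lb = float(lb_s) if lb_s else (-DEFAULT_BOUND if reversible else 0.0)
            ub = float(ub_s) if ub_s else DEFAULT_BOUND
            for met_id in stoich:
                if met_id not in model.metabolites:
                    model.add_metabolite(_infer_metabolite(met_id))
            gpr = parse_gpr(gpr_s) if gpr_s else None
            model.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    lower_bound=lb,
                    upper_bound=ub,
                    name=name,
                    subsystem=subsystem,
                    gpr=gpr,
                )
            )
            n_rows += 1
    if n_rows == 0:
        raise ModelParseError(f"{path}: no reactions found (empty model file)")
    # objective: the reaction producing the biomass pseudometabolite, if unique
    candidates = [
        r.id
        for r in model.reactions.values()
        if any(
            model.metabolites[m].is_pseudo and m == "biomass" and c > 0
            for m, c in r.stoichiometry.items()
        )
        and r.kind(model) != "exchange"
    ]
    if len(candidates) == 1:
        model.objective_id = candidates[0]
    return model


def write_tab_model(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAB_COLUMNS) + "\n")
        for r in model.reactions.values():
            gpr = r.gpr.to_string() if r.gpr else ""
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.name,
                        format_reaction_equation(r),
                        f"{r.lower_bound:g}",
                        f"{r.upper_bound:g}",
                        r.subsystem,
                        gpr,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------- SBML

_SANITIZE = re.compile(r"[^A-Za-z0-9_]")


def _sid(raw: str, prefix: str) -> str:
    s = _SANITIZE.sub("_", raw)
    if not re.match(r"^[A-Za-z_]", s):
        s = "_" + s
    return prefix + s


def write_sbml_model(model: MetabolicModel, path) -> None:
    doc = libsbml.SBMLDocument(2, 1)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.id, ""))
    for comp_id in (CYTOSOL, EXTRACELLULAR):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setSize(1.0)
    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(_sid(met.id, "M_"))
        sp.setName(met.id)  # name carries the exact original id
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(False)
    for rxn in model.reactions.values():
        sr = sbml_model.createReaction()
        sr.setId(_sid(rxn.id, "R__"))
        sr.setName(rxn.id)
        sr.setReversible(rxn.reversible)
        for met, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_sid(met, "M_"))
            ref.setStoichiometry(abs(float(coeff)))
        notes = []
        if rxn.gpr is not None:
            notes.append(f"GENE_ASSOCIATION: {rxn.gpr.to_string()}")
        if rxn.subsystem:
            notes.append(f"SUBSYSTEM: {rxn.subsystem}")
        if notes:
            body = "".join(f"<p>{n}</p>" for n in notes)
            sr.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        kl = sr.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, value in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            ("OBJECTIVE_COEFFICIENT", 1.0 if rxn.id == model.objective_id else 0.0),
        ):
            p = kl.createParameter()
            p.setId(pname)
            p.setValue(float(value))
            p.setUnits("mmol_per_gDW_per_hr" if pname != "OBJECTIVE_COEFFICIENT" else "dimensionless")
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _notes_fields(notes_str: str) -> Dict[str, str]:
    out = {}
    for m in re.finditer(r"<p>\s*([A-Z_]+)\s*:\s*(.*?)\s*</p>", notes_str, re.S):
        out[m.group(1)] = m.group(2)
    return out


def parse_sbml_model(path, model_id: Optional[str] = None) -> MetabolicModel:
    """Read SBML Level 2 with COBRA-style kinetic-law flux bounds.

    Reactions lacking bound parameters receive defaults of ±1000
    mmol·gDW⁻¹·hr⁻¹ (lower 0 when flagged irreversible), with a warning.
    Species in a compartment other than ``c``/``e`` raise an error naming
    the offending code.
    """
    reader = libsbml.SBMLReader()
    doc = reader.readSBML(str(path))
    if doc.getNumErrors() > 0 and doc.getError(0).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
        raise ModelParseError(f"{path}: {doc.getError(0).getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: no model element in SBML document")
    model = MetabolicModel(id=model_id or sbml_model.getId() or "model")
    sid_to_id: Dict[str, str] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        raw = sp.getName() or sp.getId()
        comp = sp.getCompartment()
        if comp not in (CYTOSOL, EXTRACELLULAR):
            raise ModelParseError(
                f"{path}: species {raw!r} has unknown compartment code {comp!r}"
            )
        met = _infer_metabolite(raw)
        # the compartment attribute wins over the suffix heuristic
        if not met.is_pseudo:
            met.compartment = comp
        sid_to_id[sp.getId()] = raw
        model.add_metabolite(met)
    objective = None
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        rid = sr.getName() or sr.getId()
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = sid_to_id[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = sid_to_id[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        lb = ub = None
        obj_coeff = 0.0
        if sr.isSetKineticLaw():
            kl = sr.getKineticLaw()
            for k in range(kl.getNumParameters()):
                p = kl.getParameter(k)
                if p.getId() == "LOWER_BOUND":
                    lb = p.getValue()
                elif p.getId() == "UPPER_BOUND":
                    ub = p.getValue()
                elif p.getId() == "OBJECTIVE_COEFFICIENT":
                    obj_coeff = p.getValue()
        if lb is None or ub is None:
            logger.warning(
                "reaction %s: missing flux bounds in SBML, applying defaults ±%g",
                rid,
                DEFAULT_BOUND,
            )
            lb = (-DEFAULT_BOUND if sr.getReversible() else 0.0) if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        gpr = None
        subsystem = ""
        if sr.isSetNotes():
            fields = _notes_fields(sr.getNotesString())
            if fields.get("GENE_ASSOCIATION"):
                gpr = parse_gpr(fields["GENE_ASSOCIATION"])
            subsystem = fields.get("SUBSYSTEM", "")
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=subsystem,
                gpr=gpr,
            )
        )
        if obj_coeff != 0.0:
            objective = rid
    model.objective_id = objective
    return model


def write_model(model: MetabolicModel, path, format: str = "tab") -> None:
    """Serialize a model; ``format`` is ``"tab"`` or ``"sbml"``."""
    if format == "tab":
        write_tab_model(model, path)
    elif format == "sbml":
        write_sbml_model(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------- validation


@dataclass
class ValidationReport:
    orphan_metabolites: List[str] = field(default_factory=list)
    dead_end_metabolites: List[str] = field(default_factory=list)
    bound_violations: List[str] = field(default_factory=list)
    undeclared_metabolites: List[str] = field(default_factory=list)
    missing_objective: List[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.orphan_metabolites
            or self.dead_end_metabolites
            or self.bound_violations
            or self.undeclared_metabolites
            or self.missing_objective
        )

    def __bool__(self):  # truthy when problems exist
        return not self.is_empty()


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Structural audit: orphans, dead ends, bound violations.

    A dead-end metabolite can only ever be produced or only ever be
    consumed (taking reversibility into account), so any reaction
    touching it is frozen at steady state.  The report is empty exactly
    when the structural invariants hold.
    """
    report = ValidationReport()
    used = set()
    producible: Dict[str, bool] = {m: False for m in model.metabolites}
    consumable: Dict[str, bool] = {m: False for m in model.metabolites}
    for r in model.reactions.values():
        if r.lower_bound > r.upper_bound:
            report.bound_violations.append(
                f"{r.id}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
            )
        for met, coeff in r.stoichiometry.items():
            if met not in model.metabolites:
                report.undeclared_metabolites.append(f"{r.id}: {met}")
                continue
            used.add(met)
            forward = r.upper_bound > 0
            backward = r.lower_bound < 0
            if (coeff > 0 and forward) or (coeff < 0 and backward):
                producible[met] = True
            if (coeff < 0 and forward) or (coeff > 0 and backward):
                consumable[met] = True
    for m in model.metabolites:
        if m not in used:
            report.orphan_metabolites.append(m)
        elif producible[m] != consumable[m]:
            report.dead_end_metabolites.append(m)
    if model.objective_id is not None and model.objective_id not in model.reactions:
        report.missing_objective.append(model.objective_id)
    return report


# ------------------------------------------------------------- medium


def read_medium_tsv(path):
    """Read a medium table: ``exchange_id <tab> max_uptake`` (two columns)
    or ``exchange_id <tab> lower <tab> upper`` (three → fixed fluxes)."""
    from .engine import Medium

    uptakes: Dict[str, float] = {}
    fixed: Dict[str, Tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if cells[0].lower() in ("exchange", "exchange_id", "id", "reaction"):
                continue
            if len(cells) == 2:
                uptakes[cells[0]] = float(cells[1])
            else:
                fixed[cells[0]] = (float(cells[1]), float(cells[2]))
    return Medium(allowed_uptakes=uptakes, fixed_fluxes=fixed)
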