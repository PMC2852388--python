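"""In-memory representation of a constraint-based metabolic model.

A model is a list of metabolites, a list of reactions carrying sparse
stoichiometries and flux bounds (mmol·gDW⁻¹·hr⁻¹; the biomass pseudo-
reaction carries hr⁻¹), a gene list, and one objective reaction.  Two
compartments are modelled: cytosol ("c") and extracellular space ("e"),
following the convention that ids suffixed ``_e`` are extracellular.
Pseudometabolites (biomass, cellmass, cellulosome) sit outside chemistry
and are flagged.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import scipy.sparse as sp

from .gpr import Gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "StoichiometricMatrix",
    "DEFAULT_BOUND",
    "CYTOSOL",
    "EXTRACELLULAR",
]

#: default flux bound magnitude when a file specifies none (mmol/gDW/hr)
DEFAULT_BOUND = 1000.0

CYTOSOL = "c"
EXTRACELLULAR = "e"

#: ids conventionally used for pseudometabolites
PSEUDO_METABOLITES = {"biomass", "cellmass", "cellulosome"}


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = CYTOSOL
    is_pseudo: bool = False

    def __post_init__(self):
        if self.compartment not in (CYTOSOL, EXTRACELLULAR):
            raise ValueError(
                f"unknown compartment code {self.compartment!r} for metabolite {self.id!r}"
            )


@dataclass
class Reaction:
    """A reaction with sparse stoichiometry and flux bounds.

    ``stoichiometry`` maps metabolite id → coefficient s_ij, negative for
    reactants and positive for products.  Exchange pseudo-reactions carry a
    single metabolite; negative flux is uptake, positive is secretion.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str = ""
    gpr: Optional[Gpr] = None
    annotations: dict = field(default_factory=dict)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def genes(self) -> frozenset:
        return self.gpr.genes if self.gpr is not None else frozenset()

    def kind(self, model: "MetabolicModel") -> str:
        """Classify as "exchange", "transport" or "internal".

        Exchanges carry one metabolite (extracellular or pseudo); transport
        reactions span both compartments; everything else is internal.
        """
        mets = [model.metabolites[m] for m in self.stoichiometry]
        if len(mets) == 1 and (mets[0].compartment == EXTRACELLULAR or mets[0].is_pseudo):
            return "exchange"
        comps = {m.compartment for m in mets if not m.is_pseudo}
        if len(comps) > 1:
            return "transport"
        return "internal"


@dataclass
class StoichiometricMatrix:
    """The S of S·v = 0: one row per metabolite, one column per reaction."""

    rows: List[str]
    cols: List[str]
    matrix: sp.csr_matrix

    @property
    def shape(self):
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def column(self, reaction_id: str) -> Dict[str, float]:
        """Reconstruct a reaction's stoichiometry from its matrix column."""
        j = self.cols.index(reaction_id)
        col = self.matrix.getcol(j).tocoo()
        return {self.rows[i]: v for i, v in zip(col.row, col.data)}


class MetabolicModel:
    """A genome-scale (or toy) constraint-based model.

    Reactions and metabolites are kept in insertion order.  The gene list
    is the union of all GPR leaves.  ``objective_id`` names the biomass
    reaction maximised by flux balance analysis.
    """

    def __init__(
        self,
        id: str = "model",
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        objective_id: Optional[str] = None,
    ):
        self.id = id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        self.objective_id = objective_id

    # -- construction -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise KeyError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn

    # -- views ---------------------------------------------------------

    @property
    def genes(self) -> frozenset:
        out = frozenset()
        for r in self.reactions.values():
            out |= r.genes
        return out

    @property
    def objective(self) -> Reaction:
        if self.objective_id is None:
            raise ValueError("model has no objective reaction set")
        return self.reactions[self.objective_id]

    def exchanges(self) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind(self) == "exchange"]

    def reactions_of_kind(self, kind: str) -> List[Reaction]:
        return [r for r in self.reactions.values() if r.kind(self) == kind]

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel(id=self.id, objective_id=self.objective_id)
        new.metabolites = {k: _copy.copy(v) for k, v in self.metabolites.items()}
        new.reactions = {}
        for k, r in self.reactions.items():
            new.reactions[k] = Reaction(
                id=r.id,
                stoichiometry=dict(r.stoichiometry),
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                name=r.name,
                subsystem=r.subsystem,
                gpr=r.gpr,  # immutable tree, safe to share
                annotations=dict(r.annotations),
            )
        return new

    # -- matrix --------------------------------------------------------

    def stoichiometric_matrix(self) -> StoichiometricMatrix:
        rows = list(self.metabolites)
        cols = list(self.reactions)
        row_index = {m: i for i, m in enumerate(rows)}
        data, ii, jj = [], [], []
        for j, rxn in enumerate(self.reactions.values()):
            for met_id, coeff in rxn.stoichiometry.items():
                if coeff == 0:
                    continue
                ii.append(row_index[met_id])
                jj.append(j)
                data.append(float(coeff))
        mat = sp.csr_matrix(
            (data, (ii, jj)), shape=(len(rows), len(cols)), dtype=float
        )
        return StoichiometricMatrix(rows=rows, cols=cols, matrix=mat)

    # -- equality (used by round-trip tests) ---------------------------

    def equals(self, other: "MetabolicModel", tol: float = 1e-9) -> bool:
        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for mid, m in self.metabolites.items():
            o = other.metabolites[mid]
            if (m.compartment, m.is_pseudo) != (o.compartment, o.is_pseudo):
                return False
        for rid, r in self.reactions.items():
            o = other.reactions[rid]
            if abs(r.lower_bound - o.lower_bound) > tol:
                return False
            if abs(r.upper_bound - o.upper_bound) > tol:
                return False
            keys = set(r.stoichiometry) | set(o.stoichiometry)
            for k in keys:
                if abs(r.stoichiometry.get(k, 0.0) - o.stoichiometry.get(k, 0.0)) > tol:
                    return False
            g1 = r.gpr.to_string() if r.gpr else ""
            g2 = o.gpr.to_string() if o.gpr else ""
            if g1 != g2:
                return False
        return self.objective_id == other.objective_id

    def __repr__(self):
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.genes)} genes>"
        )
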