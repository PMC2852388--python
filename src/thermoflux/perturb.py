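"""In silico gene deletions via GPR logic.

Deleting a gene sets it false in every reaction's boolean
gene-protein-reaction rule; a reaction whose rule evaluates false loses
its catalyst and is constrained to zero flux.  A gene is essential when
the knocked-out model can no longer produce biomass (maximum biomass
flux below a numeric zero).  The ethanol-enhancement screen runs flux
variability analysis on a target exchange at each non-lethal knockout's
optimum and flags deletions that strictly raise both the lower and the
upper ethanol bound — those are predicted to *force*, not merely allow,
more ethanol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Set, Tuple

from .engine import FEASIBILITY_TOL, Medium, apply_medium, fba, fva
from .gpr import Gpr
from .model import MetabolicModel

logger = logging.getLogger(__name__)

__all__ = [
    "EssentialityRecord",
    "DeletionScreenRecord",
    "evaluate_gpr",
    "apply_gene_deletion",
    "reactions_disabled_by",
    "essentiality_scan",
    "ethanol_enhancement_screen",
    "ESSENTIALITY_THRESHOLD",
]

#: growth below this is "zero" — LP solvers return tiny numerics (hr⁻¹)
ESSENTIALITY_THRESHOLD = 1e-6


@dataclass
class EssentialityRecord:
    gene: str
    knockout_Z: float
    wildtype_Z: float
    essential: bool


@dataclass
class DeletionScreenRecord:
    gene: str
    disabled_reactions: Tuple[str, ...]
    knockout_Z: float
    ethanol_min: float
    ethanol_max: float
    wildtype_ethanol_min: float
    wildtype_ethanol_max: float
    enhancing: bool


def evaluate_gpr(gpr: Optional[Gpr], deleted: Iterable[str] = ()) -> bool:
    """Is a reaction still catalysable after deleting ``deleted`` genes?

    Reactions with no GPR are always active (no genetic handle on them).
    """
    if gpr is None:
        return True
    return gpr.evaluate(frozenset(deleted))


def reactions_disabled_by(model: MetabolicModel, genes: Iterable[str]) -> List[str]:
    deleted = frozenset(genes)
    return [
        r.id
        for r in model.reactions.values()
        if r.gpr is not None and not r.gpr.evaluate(deleted)
    ]


def apply_gene_deletion(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Return a copy with every reaction lost by the knockout closed to [0, 0].

    Deleting a gene unknown to the model is a no-op with a warning (it
    simply has no reaction mapped to it).  The input model is untouched.
    """
    if gene not in model.genes:
        logger.warning("gene %r not in model %s; deletion is a no-op", gene, model.id)
    new = model.copy()
    for rid in reactions_disabled_by(model, [gene]):
        new.reactions[rid].lower_bound = 0.0
        new.reactions[rid].upper_bound = 0.0
    return new


def essentiality_scan(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> List[EssentialityRecord]:
    """Knock out each gene in turn and test for growth.

    Constraints are rebuilt from the untouched wild-type model between
    genes, so the scan is stateless and order-independent.  Raises if
    the wild type itself cannot grow.
    """
    base = apply_medium(model, medium) if medium is not None else model
    wt = fba(base)
    if not wt.optimal or wt.objective_value <= threshold:
        raise RuntimeError(
            "wild-type model does not grow under the given medium; "
            f"status={wt.status}, Z={wt.objective_value}"
        )
    records = []
    for gene in sorted(base.genes):
        ko = apply_gene_deletion(base, gene)
        sol = fba(ko)
        z = sol.objective_value if sol.optimal else 0.0
        records.append(
            EssentialityRecord(
                gene=gene,
                knockout_Z=z,
                wildtype_Z=wt.objective_value,
                essential=z < threshold,
            )
        )
    return records


def ethanol_enhancement_screen(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    target: str = "EX_etoh",
    optimum_fraction: Tuple[float, float] = (1.0, 1.0),
    threshold: float = ESSENTIALITY_THRESHOLD,
) -> List[DeletionScreenRecord]:
    """FVA of a secretion target across all non-lethal single knockouts.

    For every non-lethal gene deletion, the target exchange is minimised
    and maximised with growth pinned to the knockout optimum, and the
    record is flagged ``enhancing`` when both bounds strictly exceed the
    wild-type bounds at the wild-type optimum.
    """
    base = apply_medium(model, medium) if medium is not None else model
    if target not in base.reactions:
        raise KeyError(f"target exchange {target!r} not in model")
    wt_range = fva(base, [target], optimum_fraction=optimum_fraction)[0]
    records = []
    for gene in sorted(base.genes):
        ko = apply_gene_deletion(base, gene)
        sol = fba(ko)
        if not sol.optimal or sol.objective_value < threshold:
            continue  # lethal: not a candidate strain
        rng = fva(ko, [target], optimum_fraction=optimum_fraction)[0]
        enhancing = (
            rng.min_flux > wt_range.min_flux + FEASIBILITY_TOL
            and rng.max_flux > wt_range.max_flux + FEASIBILITY_TOL
        )
        records.append(
            DeletionScreenRecord(
                gene=gene,
                disabled_reactions=tuple(reactions_disabled_by(base, [gene])),
                knockout_Z=sol.objective_value,
                ethanol_min=rng.min_flux,
                ethanol_max=rng.max_flux,
                wildtype_ethanol_min=wt_range.min_flux,
                wildtype_ethanol_max=wt_range.max_flux,
                enhancing=enhancing,
            )
        )
    return records
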