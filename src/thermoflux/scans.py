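"""Environmental analyses: constraint layering, media supplementation,
secretion tradeoff surfaces, and the cellulosome production burden.

These scans wrap the LP core to answer the questions asked of a
fermentation model: how do predictions change as measured by-product
fluxes are layered on; which medium additions raise the attainable
ethanol:biomass yield; how does fixing one secretion (e.g. H₂) reshape
the optimum of another (e.g. ethanol); and how much growth does carrying
the cellulosome cost.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .biomass import set_cellulosome_fraction
from .engine import (
    FEASIBILITY_TOL,
    Medium,
    apply_medium,
    fba,
    flux_bounds,
    fva,
)
from .model import EXTRACELLULAR, MetabolicModel, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "LayeredPrediction",
    "SupplementationResult",
    "constraint_layering",
    "media_supplementation_scan",
    "tradeoff_scan",
    "cellulosome_burden",
]

#: FVA window for "at the maximum growth rate" queries
AT_OPTIMUM = (1.0, 1.0)


@dataclass
class LayeredPrediction:
    label: str
    constraints: List[Tuple[str, float, float]]  # cumulative (reaction, lo, hi)
    Z: Optional[float]  # None when infeasible
    status: str
    byproduct_ranges: Dict[str, Tuple[float, float]] = field(default_factory=dict)


@dataclass
class SupplementationResult:
    supplements: Tuple[str, ...]
    Z: Optional[float]
    status: str
    ethanol_min: Optional[float]
    ethanol_max: Optional[float]
    ethanol_yield: Optional[float]  # mmol ethanol per gDW biomass


def constraint_layering(
    model: MetabolicModel,
    base_medium: Optional[Medium],
    layers: Sequence[Tuple[str, Dict[str, Tuple[float, float]]]],
    byproducts: Iterable[str] = (),
    optimum_fraction: Tuple[float, float] = (0.99, 1.0),
) -> List[LayeredPrediction]:
    """Apply measured flux constraints cumulatively and predict growth.

    ``layers`` is an ordered list of (label, {reaction: (lo, hi)}).
    Each prediction reports FBA growth under all constraints up to and
    including its layer plus FVA ranges for the named by-products; an
    infeasible layer is recorded and the scan continues.  Growth is
    non-increasing along the list, since each layer only adds
    constraints.
    """
    base = apply_medium(model, base_medium) if base_medium is not None else model.copy()
    missing = [
        rid for _, cons in layers for rid in cons if rid not in base.reactions
    ]
    if missing:
        raise KeyError(f"layer constraints reference unknown reactions: {sorted(set(missing))}")
    out: List[LayeredPrediction] = []
    cumulative: Dict[str, Tuple[float, float]] = {}
    work = base
    for label, cons in list(layers) or [("unconstrained", {})]:
        work = work.copy()
        for rid, (lo, hi) in cons.items():
            work.reactions[rid].lower_bound = lo
            work.reactions[rid].upper_bound = hi
            cumulative[rid] = (lo, hi)
        sol = fba(work)
        if not sol.optimal:
            out.append(
                LayeredPrediction(
                    label=label,
                    constraints=[(r, lo, hi) for r, (lo, hi) in cumulative.items()],
                    Z=None,
                    status=sol.status,
                )
            )
            continue
        ranges = {}
        if byproducts:
            for fr in fva(work, byproducts, optimum_fraction=optimum_fraction):
                ranges[fr.reaction_id] = (fr.min_flux, fr.max_flux)
        out.append(
            LayeredPrediction(
                label=label,
                constraints=[(r, lo, hi) for r, (lo, hi) in cumulative.items()],
                Z=sol.objective_value,
                status="optimal",
                byproduct_ranges=ranges,
            )
        )
    return out


def _exchange_for(model: MetabolicModel, met: str) -> Optional[str]:
    """Find (or create) the exchange reaction for a metabolite id.

    The extracellular form ``<met>_e`` must already exist in the model —
    inventing transporters would change the network — so a metabolite
    with no extracellular form is skipped with a warning.
    """
    candidates = [
        r.id
        for r in model.exchanges()
        if next(iter(r.stoichiometry)) in (met, f"{met}_e")
    ]
    if candidates:
        return candidates[0]
    ext = f"{met}_e" if f"{met}_e" in model.metabolites else None
    if ext is None:
        logger.warning("metabolite %r has no extracellular form; supplement skipped", met)
        return None
    ex_id = f"EX_{met}"
    model.add_reaction(Reaction(ex_id, {ext: -1.0}, 0.0, 1000.0))
    return ex_id


def media_supplementation_scan(
    model: MetabolicModel,
    base_medium: Optional[Medium],
    candidates: Sequence[str],
    pair_depth: int = 1,
    uptake: float = 20.0,
    target: str = "EX_etoh",
    growth_threshold: float = 1e-6,
) -> List[SupplementationResult]:
    """Simulate medium additions singly and (optionally) in pairs.

    A supplemented metabolite's exchange is constrained to
    [−uptake, 0] mmol·gDW⁻¹·hr⁻¹: it may be consumed freely up to the
    cap but can no longer be produced — the thermodynamic block that
    makes e.g. acetate supplementation equivalent to deleting the
    acetate-producing branch.  For each condition the maximum growth
    rate and the ethanol range at that optimum are reported, along with
    the ethanol:biomass yield (max ethanol flux ÷ Z).
    """
    if pair_depth not in (1, 2):
        raise ValueError("pair_depth must be 1 or 2")
    base = apply_medium(model, base_medium) if base_medium is not None else model.copy()
    combos: List[Tuple[str, ...]] = [(c,) for c in candidates]
    if pair_depth == 2:
        combos += [tuple(p) for p in itertools.combinations(candidates, 2)]
    results: List[SupplementationResult] = []
    for combo in combos:
        work = base.copy()
        ex_ids = []
        skipped = False
        for met in combo:
            ex = _exchange_for(work, met)
            if ex is None:
                skipped = True
                break
            ex_ids.append(ex)
        if skipped:
            continue
        for ex in ex_ids:
            work.reactions[ex].lower_bound = -abs(uptake)
            work.reactions[ex].upper_bound = 0.0
        sol = fba(work)
        if not sol.optimal or sol.objective_value <= growth_threshold:
            results.append(
                SupplementationResult(combo, None, sol.status if not sol.optimal else "no_growth",
                                      None, None, None)
            )
            continue
        rng = fva(work, [target], optimum_fraction=AT_OPTIMUM)[0]
        results.append(
            SupplementationResult(
                supplements=combo,
                Z=sol.objective_value,
                status="optimal",
                ethanol_min=rng.min_flux,
                ethanol_max=rng.max_flux,
                ethanol_yield=rng.max_flux / sol.objective_value,
            )
        )
    return results


def tradeoff_scan(
    model: MetabolicModel,
    medium: Optional[Medium],
    rxn_a: str,
    rxn_b: str,
    grid: Optional[Sequence[float]] = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Phenotype table for fixing one secretion flux across its range.

    ``rxn_a`` is fixed at each grid value (default: ``n_points`` evenly
    spaced values across its feasible range with no growth constraint);
    the maximum growth rate, the FVA range of ``rxn_b`` at that optimum,
    and all non-zero exchange fluxes of one optimal flux distribution
    are recorded per point.
    """
    base = apply_medium(model, medium) if medium is not None else model.copy()
    for rid in (rxn_a, rxn_b):
        if rid not in base.reactions:
            raise KeyError(f"reaction {rid!r} not in model")
    if grid is None:
        vr = flux_bounds(base, [rxn_a])[0]
        if n_points < 2:
            grid = [vr.min_flux]
        else:
            step = (vr.max_flux - vr.min_flux) / (n_points - 1)
            grid = [vr.min_flux + i * step for i in range(n_points)]
    rows = []
    exchange_ids = [r.id for r in base.exchanges()]
    for value in grid:
        work = base.copy()
        work.reactions[rxn_a].lower_bound = value
        work.reactions[rxn_a].upper_bound = value
        sol = fba(work)
        if not sol.optimal:
            rows.append(
                {rxn_a: value, "Z": float("nan"), "status": sol.status,
                 f"{rxn_b}_min": float("nan"), f"{rxn_b}_max": float("nan"),
                 "exchange_fluxes": {}}
            )
            continue
        rng = fva(work, [rxn_b], optimum_fraction=AT_OPTIMUM)[0]
        nonzero = {
            rid: sol.fluxes[rid]
            for rid in exchange_ids
            if abs(sol.fluxes.get(rid, 0.0)) > FEASIBILITY_TOL
        }
        rows.append(
            {rxn_a: value, "Z": sol.objective_value, "status": "optimal",
             f"{rxn_b}_min": rng.min_flux, f"{rxn_b}_max": rng.max_flux,
             "exchange_fluxes": nonzero}
        )
    return pd.DataFrame(rows)


def cellulosome_burden(
    model: MetabolicModel,
    medium: Optional[Medium],
    fractions: Sequence[float] = (0.0, 0.20),
) -> pd.DataFrame:
    """Growth rate as a function of the cellulosome mass fraction.

    Reports FBA growth per fraction and the relative change versus the
    fraction-0 baseline; the burden of expressing the cellulosome is
    the growth lost to its amino-acid and ATP demand.
    """
    rows = []
    baseline = None
    for f in fractions:
        variant = set_cellulosome_fraction(model, f)
        work = apply_medium(variant, medium) if medium is not None else variant
        sol = fba(work)
        z = sol.objective_value if sol.optimal else float("nan")
        if f == 0:
            baseline = z
        rows.append({"fraction": f, "Z": z, "status": sol.status})
    if baseline is None:
        sol0 = fba(
            apply_medium(set_cellulosome_fraction(model, 0.0), medium)
            if medium is not None
            else set_cellulosome_fraction(model, 0.0)
        )
        baseline = sol0.objective_value if sol0.optimal else float("nan")
    df = pd.DataFrame(rows)
    df["relative_change"] = (df["Z"] - baseline) / baseline
    return df
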