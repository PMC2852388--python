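"""The constraint-based analysis core.

Flux balance analysis (FBA) solves the linear program

    maximize    Z = v_objective
    subject to  S · v = 0
                a_i ≤ v_i ≤ b_i   for every reaction i,

where S is the stoichiometric matrix and v the flux vector in
mmol·gDW⁻¹·hr⁻¹ (hr⁻¹ on the biomass reaction).  Flux variability
analysis (FVA) then minimises and maximises each reaction flux with the
biomass flux pinned to a window of its optimum, characterising the
alternate-optima space.  A brute-force vertex-enumeration optimiser for
tiny networks serves as an independent oracle, and a loop detector finds
futile cycles — internal reactions able to carry flux with every
exchange closed.

Alternate optima are acknowledged, not hidden: only the objective value
Z and FVA ranges are contractual; any returned flux vector is one of
possibly many optimal distributions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "Medium",
    "FbaSolution",
    "FluxRange",
    "apply_medium",
    "fba",
    "fva",
    "flux_bounds",
    "brute_force_optimum",
    "detect_futile_cycles",
    "FEASIBILITY_TOL",
]

#: contract-level feasibility tolerance on ‖S·v‖∞ and bound violations
FEASIBILITY_TOL = 1e-6


@dataclass
class Medium:
    """A chemical environment expressed as exchange-bound assignments.

    ``allowed_uptakes`` maps exchange ids to a maximum uptake magnitude
    (the exchange lower bound becomes −magnitude); ``fixed_fluxes`` pins
    a reaction to a measured (lower, upper) window and overrides
    everything else.  Exchanges not mentioned at all are closed to
    uptake (lower bound 0) but left free to secrete.
    """

    allowed_uptakes: Dict[str, float] = field(default_factory=dict)
    fixed_fluxes: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for ex, mag in self.allowed_uptakes.items():
            if mag < 0:
                raise ValueError(f"uptake magnitude for {ex!r} must be ≥ 0, got {mag}")
        for rid, (lo, hi) in self.fixed_fluxes.items():
            if lo > hi:
                raise ValueError(f"fixed flux range for {rid!r} has lower {lo} > upper {hi}")


@dataclass
class FbaSolution:
    objective_value: float
    fluxes: Dict[str, float]
    status: str  # "optimal" | "infeasible" | "unbounded"

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    reaction_id: str
    min_flux: float
    max_flux: float
    optimum_fraction: Tuple[float, float] = (0.99, 1.0)


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of the model constrained to the given environment.

    Every exchange reaction not named by the medium has its lower bound
    raised to 0 (no uptake); named uptakes get lower bound −magnitude;
    fixed fluxes override both bounds.  Unknown ids are an error.
    """
    known = set(model.reactions)
    missing = [
        rid
        for rid in list(medium.allowed_uptakes) + list(medium.fixed_fluxes)
        if rid not in known
    ]
    if missing:
        raise KeyError(f"medium references unknown reaction ids: {sorted(missing)}")
    new = model.copy()
    for rxn in new.exchanges():
        if rxn.id in medium.fixed_fluxes:
            continue
        if rxn.id in medium.allowed_uptakes:
            rxn.lower_bound = -abs(medium.allowed_uptakes[rxn.id])
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for rid, (lo, hi) in medium.fixed_fluxes.items():
        new.reactions[rid].lower_bound = lo
        new.reactions[rid].upper_bound = hi
    return new


def _lp_arrays(model: MetabolicModel):
    sm = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions.values()]
    return sm, bounds


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(model: MetabolicModel, c: np.ndarray, sm=None, bounds=None):
    if sm is None:
        sm, bounds = _lp_arrays(model)
    res = linprog(
        c,
        A_eq=sm.matrix,
        b_eq=np.zeros(sm.shape[0]),
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    return res, sm


def fba(model: MetabolicModel, objective: Optional[str] = None) -> FbaSolution:
    """Maximise the objective reaction's flux by linear programming."""
    obj_id = objective or model.objective_id
    if obj_id is None or obj_id not in model.reactions:
        raise KeyError(f"objective reaction {obj_id!r} not in model")
    cols = list(model.reactions)
    c = np.zeros(len(cols))
    c[cols.index(obj_id)] = -1.0  # linprog minimises
    res, sm = _solve(model, c)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FbaSolution(objective_value=float("nan"), fluxes={}, status=status)
    fluxes = dict(zip(cols, res.x))
    return FbaSolution(objective_value=-res.fun, fluxes=fluxes, status="optimal")


def fva(
    model: MetabolicModel,
    reactions: Optional[Iterable[str]] = None,
    optimum_fraction: Tuple[float, float] = (0.99, 1.0),
    objective: Optional[str] = None,
) -> List[FluxRange]:
    """Per-reaction flux min/max with the objective pinned near its optimum.

    The objective flux is constrained to ``[lo·Z*, hi·Z*]`` where Z* is
    the FBA optimum; two LPs are solved per queried reaction.
    """
    obj_id = objective or model.objective_id
    sol = fba(model, objective=obj_id)
    if not sol.optimal:
        raise RuntimeError(f"FVA requires a solvable model; FBA status was {sol.status}")
    lo, hi = optimum_fraction
    z = sol.objective_value
    work = model.copy()
    work.reactions[obj_id].lower_bound = min(lo * z, hi * z)
    work.reactions[obj_id].upper_bound = max(lo * z, hi * z)
    sm, bounds = _lp_arrays(work)
    cols = list(work.reactions)
    targets = list(reactions) if reactions is not None else cols
    out = []
    for rid in targets:
        j = cols.index(rid)
        c = np.zeros(len(cols))
        c[j] = 1.0
        res_min, _ = _solve(work, c, sm, bounds)
        c[j] = -1.0
        res_max, _ = _solve(work, c, sm, bounds)
        if res_min.status != 0 or res_max.status != 0:
            raise RuntimeError(f"FVA subproblem for {rid!r} did not solve")
        out.append(
            FluxRange(
                reaction_id=rid,
                min_flux=float(res_min.fun) + 0.0,
                max_flux=float(-res_max.fun) + 0.0,
                optimum_fraction=optimum_fraction,
            )
        )
    return out


def flux_bounds(
    model: MetabolicModel, reactions: Optional[Iterable[str]] = None
) -> List[FluxRange]:
    """Feasible flux range per reaction with no objective constraint."""
    sm, bounds = _lp_arrays(model)
    cols = list(model.reactions)
    out = []
    for rid in (list(reactions) if reactions is not None else cols):
        j = cols.index(rid)
        c = np.zeros(len(cols))
        c[j] = 1.0
        res_min, _ = _solve(model, c, sm, bounds)
        c[j] = -1.0
        res_max, _ = _solve(model, c, sm, bounds)
        if res_min.status != 0 or res_max.status != 0:
            raise RuntimeError(f"flux bound subproblem for {rid!r} did not solve")
        out.append(
            FluxRange(rid, float(res_min.fun) + 0.0, float(-res_max.fun) + 0.0, optimum_fraction=(0.0, 1.0))
        )
    return out


# ------------------------------------------------- brute-force oracle


def brute_force_optimum(
    model: MetabolicModel,
    objective: Optional[str] = None,
    max_reactions: int = 20,
    tol: float = 1e-9,
) -> Tuple[Optional[float], str]:
    """Exhaustively enumerate vertices of {v : S·v = 0, a ≤ v ≤ b}.

    All flux bounds are finite, so the feasible set is a bounded
    polyhedron: if non-empty it has vertices, and the LP optimum is
    attained at one.  Every vertex fixes n − rank(S) fluxes at a bound
    with the rest solved from the steady-state system; we enumerate all
    such choices with ``numpy.linalg.lstsq`` and keep feasible ones.
    Entirely independent of the LP solver — this is the oracle FBA is
    checked against on small networks.

    Returns ``(Z, "optimal")`` or ``(None, "infeasible")``.  Columns
    frozen at zero by their bounds are removed before counting against
    ``max_reactions``.
    """
    import scipy.linalg as sla

    cols_all = list(model.reactions)
    sm = model.stoichiometric_matrix()
    dense = sm.dense()
    lbs = np.array([r.lower_bound for r in model.reactions.values()])
    ubs = np.array([r.upper_bound for r in model.reactions.values()])
    if not (np.all(np.isfinite(lbs)) and np.all(np.isfinite(ubs))):
        raise ValueError("brute_force_optimum requires finite bounds")
    if np.any(lbs > ubs):
        return None, "infeasible"
    # columns frozen at zero by their bounds contribute nothing: drop them
    free = [j for j in range(len(cols_all)) if not (lbs[j] == 0 and ubs[j] == 0)]
    if len(free) > max_reactions:
        raise ValueError(
            f"network too large for vertex enumeration: {len(free)} free reactions "
            f"(limit {max_reactions})"
        )
    A_full = dense[:, free]
    lo, up = lbs[free], ubs[free]
    n = len(free)
    obj_id = objective or model.objective_id
    j_obj = free.index(cols_all.index(obj_id)) if cols_all.index(obj_id) in free else None
    if j_obj is None:
        # objective frozen at zero: feasibility still needs checking
        pass

    # reduce S·v = 0 to an independent-row system (QR with column
    # pivoting on Aᵀ picks a row basis); dependent rows are implied
    # because the right-hand side is built from A's own columns
    _, R, piv = sla.qr(A_full.T, pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    r = int(np.sum(diag > (diag.max() if diag.size else 0) * 1e-12))
    A = A_full[piv[:r], :]
    k = n - r
    best = None
    feasible = False

    # all 2^k assignments of the nonbasic fluxes to a bound
    grid = np.array(list(itertools.product((0, 1), repeat=k)), dtype=float).T  # (k, 2^k)
    for nonbasic in itertools.combinations(range(n), k):
        basic = [j for j in range(n) if j not in nonbasic]
        A_b = A[:, basic]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sla.LinAlgWarning)
                lu = sla.lu_factor(A_b)
        except (ValueError, sla.LinAlgError):
            continue
        if np.min(np.abs(np.diag(lu[0]))) < 1e-10:
            continue  # singular basis: this vertex is reachable via another basis
        nb = list(nonbasic)
        V_nb = lo[nb, None] * (1 - grid) + up[nb, None] * grid  # (k, 2^k)
        rhs = -A[:, nb] @ V_nb if k else np.zeros((r, 1))
        X = sla.lu_solve(lu, rhs)  # (r, 2^k)
        V = np.empty((n, X.shape[1]))
        V[nb, :] = V_nb
        V[basic, :] = X
        ok = (
            np.all(V >= lo[:, None] - 1e-7, axis=0)
            & np.all(V <= up[:, None] + 1e-7, axis=0)
            & (np.max(np.abs(A_full @ V), axis=0, initial=0.0) <= 1e-6)
        )
        if not np.any(ok):
            continue
        feasible = True
        z = np.max(V[j_obj, ok]) if j_obj is not None else 0.0
        if best is None or z > best:
            best = float(z)
    if not feasible:
        return None, "infeasible"
    return best, "optimal"


# -------------------------------------------------------- loop finder


def detect_futile_cycles(
    model: MetabolicModel,
    maintenance_ids: Sequence[str] = ("R_ATPM", "ATPM"),
    tol: float = FEASIBILITY_TOL,
) -> set:
    """Find internal loops: reactions able to carry flux with no exchange.

    All exchange bounds are closed to [0, 0] (and the non-growth ATP
    maintenance drain with them — a maintenance flux is not a loop);
    each remaining reaction is then minimised and maximised with no
    objective constraint.  Any reaction whose range is not {0} can run
    in a thermodynamically impossible closed cycle.
    """
    work = model.copy()
    for rxn in work.exchanges():
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    for rid in maintenance_ids:
        if rid in work.reactions:
            work.reactions[rid].lower_bound = 0.0
            work.reactions[rid].upper_bound = 0.0
    sm, bounds = _lp_arrays(work)
    cols = list(work.reactions)
    loops = set()
    for j, rid in enumerate(cols):
        lb, ub = bounds[j]
        if lb == 0 and ub == 0:
            continue
        c = np.zeros(len(cols))
        c[j] = -1.0
        res_max, _ = _solve(work, c, sm, bounds)
        if res_max.status == 0 and -res_max.fun > tol:
            loops.add(rid)
            continue
        c[j] = 1.0
        res_min, _ = _solve(work, c, sm, bounds)
        if res_min.status == 0 and res_min.fun < -tol:
            loops.add(rid)
    return loops
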