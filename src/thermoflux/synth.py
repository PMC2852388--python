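"""Small stoichiometric networks with known optima, for verification.

The fermentation toy mirrors, in miniature, the redox wiring that drives
ethanol/hydrogen tradeoffs in anaerobic cellulolytic fermentation:
glycolysis yields ATP and NADH, pyruvate branches to formate- or
ferredoxin-producing acetyl-CoA routes, and NADH can be discharged via
ethanol, lactate, or (through ferredoxin) hydrogen.  Yields are small
integers so every optimum can be verified by hand and by the
vertex-enumeration oracle.
"""

from __future__ import annotations

import numpy as np

from .gpr import GprLeaf
from .model import MetabolicModel, Metabolite, Reaction, CYTOSOL, EXTRACELLULAR

__all__ = ["make_linear_chain", "make_fermentation_toy", "make_random_model"]


def _met(model: MetabolicModel, mid: str, pseudo: bool = False):
    comp = EXTRACELLULAR if mid.endswith("_e") else CYTOSOL
    model.add_metabolite(Metabolite(id=mid, compartment=comp, is_pseudo=pseudo))


def make_linear_chain(
    n: int, yield_coeff: float = 1.0, uptake: float = 10.0
) -> MetabolicModel:
    """An unbranched pathway EX_s → s → m₁ → … → mₙ → biomass.

    The closed-form optimum is Z = uptake · yield_coeff (zero when the
    yield is zero), which makes the chain the simplest oracle fixture.
    """
    if n < 1:
        raise ValueError("chain length must be ≥ 1")
    model = MetabolicModel(id=f"chain{n}")
    _met(model, "s_e")
    _met(model, "s")
    for i in range(1, n + 1):
        _met(model, f"m{i}")
    _met(model, "biomass", pseudo=True)
    model.add_reaction(Reaction("EX_s", {"s_e": -1.0}, lower_bound=-abs(uptake), upper_bound=0.0))
    model.add_reaction(Reaction("St", {"s_e": -1.0, "s": 1.0}, 0.0, 1000.0, gpr=GprLeaf("g_St")))
    prev = "s"
    for i in range(1, n + 1):
        model.add_reaction(
            Reaction(f"R{i}", {prev: -1.0, f"m{i}": 1.0}, 0.0, 1000.0, gpr=GprLeaf(f"g_R{i}"))
        )
        prev = f"m{i}"
    # objective flux = biomass production rate, so the chain's optimum is
    # uptake · yield_coeff; a zero yield closes the reaction outright
    if yield_coeff > 0:
        model.add_reaction(
            Reaction("BIO", {prev: -1.0 / yield_coeff, "biomass": 1.0}, 0.0, 1000.0)
        )
    else:
        model.add_reaction(Reaction("BIO", {prev: -1.0, "biomass": 1.0}, 0.0, 0.0))
    model.add_reaction(Reaction("EX_biomass", {"biomass": -1.0}, 0.0, 1000.0))
    model.objective_id = "BIO"
    return model


def make_fermentation_toy() -> MetabolicModel:
    """The branched fermentation network used throughout the test suite.

    Stoichiometry (all irreversible, glucose uptake capped at 10):

    * GLYC: glc → 2 pyr + 2 atp + 2 nadh          (glycolysis)
    * PFL:  pyr → accoa + formate                  (pyruvate formate lyase)
    * POR:  pyr → accoa + co2 + fdred              (pyruvate:Fd oxidoreductase)
    * ADH:  accoa + 2 nadh → etoh                  (ethanol branch)
    * ACK:  accoa → ac + atp                       (acetate branch, extra ATP)
    * LDH:  pyr + nadh → lac                       (lactate branch)
    * HYD:  fdred → h2                             (hydrogenase)
    * NFO:  nadh → fdred                           (NADH:Fd oxidoreductase)
    * BIO:  pyr + 4 atp → biomass

    At the wild-type optimum the acetate branch supplies the extra ATP
    (Z = 8, ethanol 0).  Deleting the hydrogenase removes the last
    non-fermentative NADH sink, forcing ethanol production (Z = 6,
    ethanol pinned at 10) — the toy version of redox-driven ethanol
    enhancement.  One gene per non-exchange reaction.
    """
    model = MetabolicModel(id="ferm_toy")
    _met(model, "glc_e")
    for mid in ("glc", "pyr", "atp", "nadh", "fdred", "accoa"):
        _met(model, mid)
    for mid in ("etoh_e", "ac_e", "lac_e", "for_e", "co2_e", "h2_e"):
        _met(model, mid)
    _met(model, "biomass", pseudo=True)

    def rxn(rid, stoich, lb=0.0, ub=1000.0, gene=True):
        gpr = GprLeaf(f"g_{rid}") if gene else None
        model.add_reaction(Reaction(rid, stoich, lb, ub, gpr=gpr))

    model.add_reaction(Reaction("EX_glc", {"glc_e": -1.0}, -10.0, 0.0))
    rxn("GLCt", {"glc_e": -1.0, "glc": 1.0})
    rxn("GLYC", {"glc": -1.0, "pyr": 2.0, "atp": 2.0, "nadh": 2.0})
    rxn("PFL", {"pyr": -1.0, "accoa": 1.0, "for_e": 1.0})
    rxn("POR", {"pyr": -1.0, "accoa": 1.0, "co2_e": 1.0, "fdred": 1.0})
    rxn("ADH", {"accoa": -1.0, "nadh": -2.0, "etoh_e": 1.0})
    rxn("ACK", {"accoa": -1.0, "ac_e": 1.0, "atp": 1.0})
    rxn("LDH", {"pyr": -1.0, "nadh": -1.0, "lac_e": 1.0})
    rxn("HYD", {"fdred": -1.0, "h2_e": 1.0})
    rxn("NFO", {"nadh": -1.0, "fdred": 1.0})
    rxn("BIO", {"pyr": -1.0, "atp": -4.0, "biomass": 1.0}, gene=False)
    for mid in ("etoh_e", "ac_e", "lac_e", "for_e", "co2_e", "h2_e", "biomass"):
        ex_id = "EX_" + mid.removesuffix("_e")
        model.add_reaction(Reaction(ex_id, {mid: -1.0}, 0.0, 1000.0))
    model.objective_id = "BIO"
    return model


def make_random_model(
    n_mets: int = 5, n_rxns: int = 4, density: float = 0.5, seed: int = 0
) -> MetabolicModel:
    """A random small network with a planted feasible growth pathway.

    A linear chain from one uptake to biomass guarantees FBA feasibility
    with a known floor; ``n_rxns`` extra random reactions with integer
    coefficients in {−2, −1, 1, 2} are then drawn among the planted
    metabolites (so no dead ends appear).  Identical seeds give
    byte-identical models — these fixtures exist so that the LP engine
    can be checked against exhaustive vertex enumeration.
    """
    if n_mets < 1 or n_rxns < 0:
        raise ValueError("n_mets must be ≥ 1 and n_rxns ≥ 0")
    rng = np.random.default_rng(seed)
    yield_coeff = float(rng.choice([0.5, 1.0, 2.0]))
    uptake = float(rng.integers(2, 11))
    model = make_linear_chain(n=n_mets, yield_coeff=yield_coeff, uptake=uptake)
    model.id = f"random_{seed}"
    inner = ["s"] + [f"m{i}" for i in range(1, n_mets + 1)]
    n_extra = int(round(n_rxns * density)) if density < 1 else n_rxns
    for k in range(n_extra):
        size = int(rng.integers(2, min(4, len(inner)) + 1))
        mets = rng.choice(inner, size=size, replace=False)
        stoich = {}
        for idx, met in enumerate(mets):
            coeff = float(rng.choice([1.0, 2.0]))
            sign = -1.0 if idx == 0 else float(rng.choice([-1.0, 1.0]))
            stoich[str(met)] = sign * coeff
        if all(c < 0 for c in stoich.values()) or all(c > 0 for c in stoich.values()):
            # keep reactions balanced in direction so no dead end appears
            last = str(mets[-1])
            stoich[last] = -stoich[last]
        reversible = bool(rng.random() < 0.3)
        lb = -float(rng.integers(1, 6)) if reversible else 0.0
        ub = float(rng.integers(1, 6))
        model.add_reaction(
            Reaction(f"RND{k}", stoich, lb, ub, gpr=GprLeaf(f"g_RND{k}"))
        )
    return model
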