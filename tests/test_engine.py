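"""The LP core: FBA, FVA, the vertex-enumeration oracle, loop detection."""

import numpy as np
import pytest

from thermoflux.engine import (
    FEASIBILITY_TOL,
    Medium,
    apply_medium,
    brute_force_optimum,
    detect_futile_cycles,
    fba,
    flux_bounds,
    fva,
)
from thermoflux.model import MetabolicModel, Metabolite, Reaction
from thermoflux.perturb import apply_gene_deletion
from thermoflux.synth import make_linear_chain, make_random_model


def test_wildtype_optimum_matches_hand_derivation(toy):
    # pyruvate balance 20 = Z + x and ATP balance 20 + x = 4 Z give Z = 8
    sol = fba(toy)
    assert sol.optimal
    assert sol.objective_value == pytest.approx(8.0, abs=1e-6)


def test_fba_agrees_with_vertex_enumeration_oracle(toy):
    z, status = brute_force_optimum(toy)
    assert status == "optimal"
    assert fba(toy).objective_value == pytest.approx(z, abs=1e-6)


def test_optimal_solution_is_steady_state_and_within_bounds(toy):
    sol = fba(toy)
    sm = toy.stoichiometric_matrix()
    v = np.array([sol.fluxes[r] for r in sm.cols])
    assert np.max(np.abs(sm.matrix @ v)) <= FEASIBILITY_TOL
    for rid, rxn in toy.reactions.items():
        assert rxn.lower_bound - FEASIBILITY_TOL <= sol.fluxes[rid] <= rxn.upper_bound + FEASIBILITY_TOL


def test_all_exchanges_closed_means_no_growth(toy):
    closed = apply_medium(toy, Medium())
    assert fba(closed).objective_value == pytest.approx(0.0, abs=1e-9)


def test_medium_opens_named_uptakes_only(toy):
    m = apply_medium(toy, Medium(allowed_uptakes={"EX_glc": 4.0}))
    assert m.reactions["EX_glc"].lower_bound == -4.0
    for r in m.exchanges():
        if r.id != "EX_glc":
            assert r.lower_bound == 0.0
    # halved uptake halves the optimum (LP scale equivariance)
    assert fba(m).objective_value == pytest.approx(0.4 * 8.0, abs=1e-6)


def test_medium_fixed_fluxes_override_bounds(toy):
    m = apply_medium(
        toy, Medium(allowed_uptakes={"EX_glc": 10.0}, fixed_fluxes={"EX_h2": (0.0, 0.0)})
    )
    assert m.reactions["EX_h2"].upper_bound == 0.0
    assert fba(m).objective_value == pytest.approx(6.0, abs=1e-6)


def test_unknown_exchange_id_in_medium_is_an_error(toy):
    with pytest.raises(KeyError, match="EX_nope"):
        apply_medium(toy, Medium(allowed_uptakes={"EX_nope": 1.0}))


def test_infeasible_model_reports_status(toy):
    bad = toy.copy()
    # force glucose uptake but close the transporter
    bad.reactions["EX_glc"].upper_bound = -5.0
    bad.reactions["GLCt"].upper_bound = 0.0
    sol = fba(bad)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


def test_ethanol_is_zero_across_all_wildtype_optima(toy):
    rng = fva(toy, ["EX_etoh"], optimum_fraction=(1.0, 1.0))[0]
    assert rng.min_flux == pytest.approx(0.0, abs=1e-6)
    assert rng.max_flux == pytest.approx(0.0, abs=1e-6)


def test_hydrogenase_deletion_forces_ethanol(toy):
    # redox balance 20 = 2·v_ADH + v_LDH pins ethanol at 10 when Z = 6
    ko = apply_gene_deletion(toy, "g_HYD")
    assert fba(ko).objective_value == pytest.approx(6.0, abs=1e-6)
    z, _ = brute_force_optimum(ko)
    assert z == pytest.approx(6.0, abs=1e-6)
    rng = fva(ko, ["EX_etoh"], optimum_fraction=(1.0, 1.0))[0]
    assert rng.min_flux == pytest.approx(10.0, abs=1e-6)
    assert rng.max_flux == pytest.approx(10.0, abs=1e-6)


def test_fva_sandwich_contains_an_optimal_flux_vector(toy):
    sol = fba(toy)
    for fr in fva(toy, optimum_fraction=(0.99, 1.0)):
        assert fr.min_flux <= fr.max_flux + 1e-9
        assert fr.min_flux - 1e-6 <= sol.fluxes[fr.reaction_id] <= fr.max_flux + 1e-6


def test_reaction_into_dead_end_has_zero_fva_range(toy):
    m = toy.copy()
    m.add_metabolite(Metabolite("junk"))
    m.add_reaction(Reaction("TO_JUNK", {"pyr": -1.0, "junk": 1.0}, 0, 1000))
    rng = fva(m, ["TO_JUNK"])[0]
    assert (rng.min_flux, rng.max_flux) == (pytest.approx(0.0, abs=1e-9),) * 2


def test_chain_closed_form_and_scale_equivariance():
    m = make_linear_chain(n=3, yield_coeff=0.5, uptake=10.0)
    assert fba(m).objective_value == pytest.approx(5.0, abs=1e-9)
    z, _ = brute_force_optimum(m)
    assert z == pytest.approx(5.0, abs=1e-6)
    doubled = make_linear_chain(n=3, yield_coeff=0.5, uptake=20.0)
    assert fba(doubled).objective_value == pytest.approx(10.0, abs=1e-9)
    assert fba(make_linear_chain(n=1, yield_coeff=0.0)).objective_value == pytest.approx(0.0, abs=1e-9)


def test_oracle_reports_infeasible_like_fba():
    m = MetabolicModel(metabolites=[Metabolite("x_e", compartment="e"), Metabolite("x")])
    m.add_reaction(Reaction("EX_x", {"x_e": -1.0}, -5.0, -5.0))  # forced uptake
    m.add_reaction(Reaction("T", {"x_e": -1.0, "x": 1.0}, 0, 0))  # no sink
    m.objective_id = "T"
    assert brute_force_optimum(m) == (None, "infeasible")
    assert fba(m).status == "infeasible"


def test_oracle_refuses_oversized_networks():
    m = make_random_model(n_mets=8, n_rxns=30, density=1.0, seed=0)
    with pytest.raises(ValueError, match="too large"):
        brute_force_optimum(m, max_reactions=10)


def test_adding_a_constraint_never_increases_growth(toy):
    z0 = fba(toy).objective_value
    constrained = toy.copy()
    constrained.reactions["EX_h2"].upper_bound = 5.0
    assert fba(constrained).objective_value <= z0 + 1e-9


def test_planted_two_cycle_is_reported():
    m = MetabolicModel(metabolites=[Metabolite("a"), Metabolite("b")])
    m.add_reaction(Reaction("FWD", {"a": -1.0, "b": 1.0}, 0, 1000))
    m.add_reaction(Reaction("BACK", {"b": -1.0, "a": 1.0}, 0, 1000))
    assert detect_futile_cycles(m) == {"FWD", "BACK"}


def test_toy_network_has_no_futile_cycles(toy):
    assert detect_futile_cycles(toy) == set()


def test_maintenance_drain_is_not_a_loop(toy):
    m = toy.copy()
    m.add_metabolite(Metabolite("adp"))
    m.add_reaction(Reaction("R_ATPM", {"atp": -1.0, "adp": 1.0}, 1.0, 1000))
    m.add_reaction(Reaction("ADK", {"adp": -1.0, "atp": 1.0}, 0, 1000))
    # R_ATPM + ADK form a closable pair, but maintenance is exempt by design
    assert detect_futile_cycles(m) == set()


def test_flux_bounds_cover_whole_feasible_range(toy):
    fr = flux_bounds(toy, ["EX_h2"])[0]
    assert fr.min_flux == pytest.approx(0.0, abs=1e-6)
    assert fr.max_flux == pytest.approx(32.0, abs=1e-6)  # POR 12 + NFO 20


def test_fba_matches_cobrapy_on_the_toy(toy):
    """Independent cross-check against cobrapy + GLPK on the same network."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("toy")
    mets = {
        mid: cobra.Metabolite(mid, compartment=m.compartment)
        for mid, m in toy.metabolites.items()
    }
    for rid, rxn in toy.reactions.items():
        cr = cobra.Reaction(rid)
        cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
    cm.objective = "BIO"
    cm.solver = "glpk"
    z_cobra = cm.optimize().objective_value
    assert fba(toy).objective_value == pytest.approx(z_cobra, abs=1e-6)
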