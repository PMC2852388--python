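"""Environmental scans: layering, supplementation, tradeoffs, burden."""

import math

import pytest

from thermoflux.engine import Medium, fba
from thermoflux.scans import (
    cellulosome_burden,
    constraint_layering,
    media_supplementation_scan,
    tradeoff_scan,
)


def test_empty_layer_list_equals_plain_fba(toy):
    out = constraint_layering(toy, None, [])
    assert len(out) == 1
    assert out[0].Z == pytest.approx(fba(toy).objective_value, abs=1e-9)


def test_growth_is_non_increasing_across_layers(toy):
    layers = [
        ("uptake", {"EX_glc": (-10.0, -10.0)}),
        ("h2 capped", {"EX_h2": (0.0, 10.0)}),
        ("acetate capped", {"EX_ac": (0.0, 5.0)}),
    ]
    out = constraint_layering(toy, None, layers, byproducts=["EX_etoh", "EX_for"])
    zs = [p.Z for p in out]
    assert all(z is not None for z in zs)
    assert all(zs[i] >= zs[i + 1] - 1e-9 for i in range(len(zs) - 1))
    assert all(set(p.byproduct_ranges) == {"EX_etoh", "EX_for"} for p in out)
    # constraints accumulate
    assert len(out[-1].constraints) == 3


def test_infeasible_layer_is_recorded_and_scan_continues(toy):
    layers = [
        ("ok", {"EX_glc": (-10.0, -10.0)}),
        ("impossible", {"EX_etoh": (50.0, 50.0)}),  # beyond attainable ethanol
        ("back to ok", {}),
    ]
    out = constraint_layering(toy, None, layers)
    assert out[0].status == "optimal"
    assert out[1].status == "infeasible" and out[1].Z is None
    assert len(out) == 3


def test_unknown_layer_reaction_is_an_error(toy):
    with pytest.raises(KeyError, match="EX_bogus"):
        constraint_layering(toy, None, [("x", {"EX_bogus": (0.0, 0.0)})])


def test_acetate_supplementation_blocks_acetate_and_raises_yield(toy):
    """[−20, 0] exchange bounds forbid acetate production, rerouting
    acetyl-CoA to ethanol exactly as an acetate-kinase knockout would."""
    results = media_supplementation_scan(toy, None, ["ac"], pair_depth=1)
    (res,) = results
    assert res.Z == pytest.approx(5.0, abs=1e-6)  # same optimum as ΔACK
    assert res.ethanol_max == pytest.approx(5.0, abs=1e-6)
    assert res.ethanol_yield == pytest.approx(1.0, abs=1e-6)


def test_yield_consistency(toy):
    for res in media_supplementation_scan(toy, None, ["ac", "lac"], pair_depth=2):
        if res.Z is not None:
            assert res.ethanol_yield * res.Z == pytest.approx(res.ethanol_max, abs=1e-6)


def test_supplement_without_inward_path_matches_baseline(toy):
    # h2 can be "supplied" but nothing consumes it: [−20, 0] only blocks secretion
    base_z = fba(toy).objective_value
    (res,) = media_supplementation_scan(toy, None, ["h2"], pair_depth=1)
    assert res.Z == pytest.approx(6.0, abs=1e-6)  # secretion block = ΔHYD phenotype
    # whereas a metabolite absent from the model entirely is skipped
    assert media_supplementation_scan(toy, None, ["xylose"], pair_depth=1) == []


def test_pair_depth_two_enumerates_unordered_pairs(toy):
    results = media_supplementation_scan(toy, None, ["ac", "lac", "for"], pair_depth=2)
    combos = {r.supplements for r in results}
    assert ("ac",) in combos and ("ac", "lac") in combos
    assert len([c for c in combos if len(c) == 2]) == 3


def test_tradeoff_explicit_grid_point_matches_direct_solve(toy):
    df = tradeoff_scan(toy, None, "EX_h2", "EX_etoh", grid=[20.0])
    fixed = toy.copy()
    fixed.reactions["EX_h2"].lower_bound = fixed.reactions["EX_h2"].upper_bound = 20.0
    assert df["Z"].iloc[0] == pytest.approx(fba(fixed).objective_value, abs=1e-9)


def test_hydrogen_ethanol_tradeoff_shape(toy):
    df = tradeoff_scan(toy, None, "EX_h2", "EX_etoh", n_points=9)
    assert (df["status"] == "optimal").all()
    # at the global maximum-growth point ethanol production is zero
    best = df.loc[df["Z"].idxmax()]
    assert best["EX_etoh_max"] == pytest.approx(0.0, abs=1e-6)
    # blocking H2 escape forces ethanol
    h2_zero = df.iloc[0]
    assert h2_zero["EX_h2"] == pytest.approx(0.0, abs=1e-9)
    assert h2_zero["EX_etoh_min"] == pytest.approx(10.0, abs=1e-6)


def test_tradeoff_growth_is_concave_along_the_grid(toy):
    """Max Z as a function of a fixed RHS flux is concave: every interior
    grid point lies above the chord of its neighbours (midpoint test)."""
    df = tradeoff_scan(toy, None, "EX_h2", "EX_etoh", n_points=11)
    z = df["Z"].to_numpy()
    for i in range(1, len(z) - 1):
        assert z[i] >= (z[i - 1] + z[i + 1]) / 2 - 1e-6


def test_blocking_h2_reroutes_acetyl_coa_to_formate(toy):
    """Fixing H2 escape at zero removes the ferredoxin sink, so all
    acetyl-CoA must come through pyruvate formate lyase: formate export
    is forced above anything reachable at the wild-type optimum.  Also
    closing ethanol leaves lactate as the only NADH sink, which consumes
    every pyruvate — growth collapses to zero."""
    df = tradeoff_scan(toy, None, "EX_h2", "EX_etoh", grid=[0.0])
    assert not math.isnan(df["Z"].iloc[0])
    forced_formate = df["exchange_fluxes"].iloc[0].get("EX_for", 0.0)
    from thermoflux.engine import fva

    wt_formate_max = fva(toy, ["EX_for"], optimum_fraction=(1.0, 1.0))[0].max_flux
    assert forced_formate > wt_formate_max + 1.0
    blocked = toy.copy()
    blocked.reactions["EX_etoh"].upper_bound = 0.0
    blocked_df = tradeoff_scan(blocked, None, "EX_h2", "EX_etoh", grid=[0.0])
    assert blocked_df["Z"].iloc[0] == pytest.approx(0.0, abs=1e-6)


def test_cellulosome_burden_monotone():
    from test_biomass import _cellulosome_toy

    df = cellulosome_burden(_cellulosome_toy(), None, fractions=[0.0, 0.1, 0.2, 0.4])
    assert df["Z"].is_monotonic_decreasing
    assert df.loc[df["fraction"] == 0.0, "relative_change"].iloc[0] == pytest.approx(0.0)
    assert (df["relative_change"] <= 1e-12).all()
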