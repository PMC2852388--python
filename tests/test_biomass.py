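"""Biomass and cellulosome objective construction."""

import pytest

from thermoflux.biomass import (
    AMINO_ACID_RESIDUE_MASSES,
    CellulosomeSpec,
    CompositionTable,
    build_biomass_reaction,
    build_cellulosome_reaction,
    build_lumped_species_reaction,
    monomer_distribution_from_sequences,
    set_cellulosome_fraction,
)
from thermoflux.engine import fba
from thermoflux.model import MetabolicModel, Metabolite, Reaction


def test_single_sequence_counting():
    assert monomer_distribution_from_sequences(["GG"], [1.0]) == {"G": 1.0}


def test_weighted_residue_counting():
    dist = monomer_distribution_from_sequences(["GA", "AA"], [1.0, 1.0])
    assert dist == {"G": pytest.approx(0.25), "A": pytest.approx(0.75)}
    # doubling one peptide's abundance shifts the distribution accordingly
    dist2 = monomer_distribution_from_sequences(["GA", "AA"], [2.0, 1.0])
    assert dist2["G"] == pytest.approx(2 / 6)


def test_unknown_residue_letter_is_named_in_error():
    with pytest.raises(ValueError, match="'B'"):
        monomer_distribution_from_sequences(["AB"], [1.0])


def test_pure_glycine_protein_coefficient_by_hand():
    # 1000 mg/gDW / 57.05 g/mol residue mass ≈ 17.53 mmol/gDW of glycine
    table = CompositionTable("protein", 1.0, {"G": 1.0})
    rxn = build_biomass_reaction([table], AMINO_ACID_RESIDUE_MASSES, gam=0.0)
    expected = 1000.0 / AMINO_ACID_RESIDUE_MASSES["G"]
    assert rxn.stoichiometry["G"] == pytest.approx(-expected, rel=1e-9)
    assert rxn.stoichiometry["cellmass"] == 1.0


def test_only_nonzero_categories_are_drained():
    tables = [
        CompositionTable("protein", 0.0, {"G": 1.0}),
        CompositionTable("ions_and_metabolites", 1.0, {"k": 0.5, "mg2": 0.5}),
    ]
    rxn = build_biomass_reaction([tables[0], tables[1]], {"G": 57.05, "k": 39.1, "mg2": 24.3})
    drained = {m for m, c in rxn.stoichiometry.items() if c < 0}
    assert drained == {"k", "mg2"}


def test_mass_closure_one_gram_per_unit_cellmass():
    """Σ coefficient·monomer mass over drains = 1000 mg per unit cellmass."""
    tables = [
        CompositionTable("protein", 0.55, {"G": 0.4, "A": 0.35, "L": 0.25}),
        CompositionTable("RNA", 0.20, {"amp": 0.3, "gmp": 0.3, "cmp": 0.2, "ump": 0.2}),
        CompositionTable("lipids_and_cell_wall", 0.25, {"lipid": 1.0}),
    ]
    masses = dict(AMINO_ACID_RESIDUE_MASSES, amp=329.2, gmp=345.2, cmp=305.2, ump=306.2, lipid=700.0)
    rxn = build_biomass_reaction(tables, masses, gam=40.0)
    drained_mass = sum(
        -c * masses[m]
        for m, c in rxn.stoichiometry.items()
        if c < 0 and m in masses
    )
    assert drained_mass == pytest.approx(1000.0, rel=1e-3)


def test_mass_fractions_must_sum_to_one():
    with pytest.raises(ValueError, match="sum"):
        build_biomass_reaction(
            [CompositionTable("protein", 0.5, {"G": 1.0})], AMINO_ACID_RESIDUE_MASSES
        )


def test_missing_molar_mass_is_an_error():
    with pytest.raises(ValueError, match="mystery"):
        build_biomass_reaction(
            [CompositionTable("protein", 1.0, {"mystery": 1.0})], {}
        )


def test_polyglycine_cellulosome_unit():
    rxn = build_cellulosome_reaction(CellulosomeSpec(peptides=[("GGGG", 1.0)]))
    assert rxn.stoichiometry["G"] == pytest.approx(-1.0)
    assert rxn.stoichiometry["atp"] == pytest.approx(-1.0)
    assert rxn.stoichiometry["adp"] == pytest.approx(1.0)
    assert rxn.stoichiometry["cellulosome"] == 1.0
    assert rxn.annotations["residue_mass"] == pytest.approx(AMINO_ACID_RESIDUE_MASSES["G"])


def test_equal_abundance_equal_length_peptides_split_evenly():
    rxn = build_cellulosome_reaction(CellulosomeSpec(peptides=[("GG", 1.0), ("AA", 1.0)]))
    assert rxn.stoichiometry["G"] == pytest.approx(-0.5)
    assert rxn.stoichiometry["A"] == pytest.approx(-0.5)
    # residue coefficients sum to one mole of average residue
    total = -sum(c for m, c in rxn.stoichiometry.items() if m in ("G", "A"))
    assert total == pytest.approx(1.0, abs=1e-9)


def test_cellulosome_spec_validation():
    with pytest.raises(ValueError):
        CellulosomeSpec(peptides=[])
    with pytest.raises(ValueError):
        CellulosomeSpec(peptides=[("GG", 0.0)])
    with pytest.raises(ValueError):
        CellulosomeSpec(peptides=[("GG", 1.0)], mass_fraction=1.0)


def test_lumped_species_single_component_is_one_to_one():
    rxn = build_lumped_species_reaction({"fa1": 1.0}, "avg_fa")
    assert rxn.stoichiometry == {"fa1": -1.0, "avg_fa": 1.0}


def test_lumped_species_mole_fractions_become_coefficients():
    rxn = build_lumped_species_reaction({"fa1": 0.6, "fa2": 0.4}, "avg_fa")
    assert rxn.stoichiometry["fa1"] == pytest.approx(-0.6)
    assert rxn.stoichiometry["fa2"] == pytest.approx(-0.4)


def test_lumped_species_mass_fractions_convert_via_molar_mass():
    rxn = build_lumped_species_reaction(
        {"fa1": 0.5, "fa2": 0.5}, "avg_fa", fraction_type="mass",
        molar_masses={"fa1": 100.0, "fa2": 200.0},
    )
    # equal masses, 2:1 mole ratio
    assert rxn.stoichiometry["fa1"] == pytest.approx(-2 / 3)
    assert rxn.stoichiometry["fa2"] == pytest.approx(-1 / 3)


def test_lumped_species_rejects_negative_fraction():
    with pytest.raises(ValueError):
        build_lumped_species_reaction({"fa1": 1.2, "fa2": -0.2}, "avg_fa")


def _cellulosome_toy():
    """Chain model whose biomass drains cellmass (+ optional cellulosome).

    One unit of cellmass costs 1 substrate; one gram of cellulosome
    (10 mmol at 100 g/mol residue mass) costs 2 substrate + 10 ATP, so
    shifting biomass toward cellulosome is strictly costly and the
    growth response has the closed form Z = 10 / (1.5 + 6 f).
    """
    m = MetabolicModel(id="cellu_toy")
    for mid in ("s_e", "s", "atp", "cellmass", "cellulosome", "biomass"):
        m.add_metabolite(
            Metabolite(mid, compartment="e" if mid.endswith("_e") else "c",
                       is_pseudo=mid in ("cellmass", "cellulosome", "biomass"))
        )
    m.add_reaction(Reaction("EX_s", {"s_e": -1.0}, -10.0, 0.0))
    m.add_reaction(Reaction("St", {"s_e": -1.0, "s": 1.0}, 0, 1000))
    m.add_reaction(Reaction("CAT", {"s": -1.0, "cellmass": 1.0}, 0, 1000))
    m.add_reaction(Reaction("ATPGEN", {"s": -1.0, "atp": 2.0}, 0, 1000))
    cellu = Reaction("R_CELLULOSOME", {"s": -0.2, "atp": -1.0, "cellulosome": 1.0}, 0, 1000,
                     annotations={"residue_mass": 100.0})
    m.add_reaction(cellu)
    m.add_reaction(Reaction("R_BIOMASS_TOTAL", {"cellmass": -1.0, "atp": -1.0, "biomass": 1.0}, 0, 1000))
    m.add_reaction(Reaction("EX_biomass", {"biomass": -1.0}, 0, 1000))
    m.objective_id = "R_BIOMASS_TOTAL"
    return m


def test_zero_fraction_removes_cellulosome_drain_entirely():
    m = _cellulosome_toy()
    m0 = set_cellulosome_fraction(m, 0.0)
    assert "cellulosome" not in m0.objective.stoichiometry
    assert m0.objective.stoichiometry["cellmass"] == -1.0
    assert fba(m0).objective_value == pytest.approx(fba(m).objective_value, abs=1e-9)


def test_growth_burden_is_monotone_in_cellulosome_fraction():
    m = _cellulosome_toy()
    zs = [fba(set_cellulosome_fraction(m, f)).objective_value for f in (0.0, 0.1, 0.2, 0.4)]
    assert all(zs[i] >= zs[i + 1] - 1e-9 for i in range(len(zs) - 1))
    assert zs[0] > zs[-1]  # strictly costly at 40%


def test_fraction_bounds_are_enforced():
    m = _cellulosome_toy()
    for bad in (-0.1, 1.0, 1.5):
        with pytest.raises(ValueError):
            set_cellulosome_fraction(m, bad)


def test_fraction_requires_pseudometabolites(toy):
    with pytest.raises(KeyError):
        set_cellulosome_fraction(toy, 0.2)
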