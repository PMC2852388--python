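"""Construction of lumped biomass and cellulosome objective reactions.

The biomass pseudo-reaction drains monomer precursors in proportion to
their experimentally determined contribution to cell mass.  Dry weight
is split into macromolecular categories (protein, RNA, DNA, lipids and
cell wall, ions and metabolites); within each category a monomer mole
distribution (e.g. amino-acid frequencies counted over every open
reading frame) converts the category's mass fraction into mmol·gDW⁻¹
drain coefficients.

The cellulosome — the multi-enzyme cellulose-degrading complex that can
reach ~20% of cell dry mass — is represented as a pseudometabolite: one
mole of "cellulosome" is one mole of its average amino-acid residue,
with the residue distribution weighted by proteomic peptide abundances,
and one ATP hydrolysed per residue built and exported (both tunable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Data.IUPACData import protein_weights

from .model import MetabolicModel, Reaction

__all__ = [
    "CompositionTable",
    "CellulosomeSpec",
    "AMINO_ACID_RESIDUE_MASSES",
    "WATER_MASS",
    "monomer_distribution_from_sequences",
    "build_biomass_reaction",
    "build_cellulosome_reaction",
    "build_lumped_species_reaction",
    "set_cellulosome_fraction",
]

WATER_MASS = 18.0153  # g/mol, lost in peptide-bond formation

#: average residue masses: free amino acid minus one water (g/mol)
AMINO_ACID_RESIDUE_MASSES: Dict[str, float] = {
    aa: mw - WATER_MASS for aa, mw in protein_weights.items()
}

FRACTION_TOL = 1e-6


@dataclass
class CompositionTable:
    """One macromolecular category of the dry-weight budget."""

    category: str  # protein | RNA | DNA | lipids_and_cell_wall | ions_and_metabolites
    mass_fraction: float  # g per gDW
    monomer_distribution: Dict[str, float]  # monomer id -> mole fraction

    def __post_init__(self):
        total = sum(self.monomer_distribution.values())
        if self.monomer_distribution and abs(total - 1.0) > FRACTION_TOL:
            raise ValueError(
                f"monomer distribution of {self.category!r} sums to {total}, not 1"
            )


@dataclass
class CellulosomeSpec:
    """Peptide constituents of the cellulosome with proteomic abundances."""

    peptides: List[Tuple[str, float]]  # (residue sequence, relative abundance)
    atp_per_residue: float = 1.0  # mol ATP per mol average residue
    mass_fraction: float = 0.20  # of total cell mass, when expressed

    def __post_init__(self):
        if not self.peptides:
            raise ValueError("cellulosome spec needs at least one peptide")
        for seq, ab in self.peptides:
            if ab <= 0:
                raise ValueError(f"peptide abundance must be > 0, got {ab}")
        if not (0 <= self.mass_fraction < 1):
            raise ValueError(f"mass_fraction must be in [0, 1), got {self.mass_fraction}")


def monomer_distribution_from_sequences(
    sequences: Sequence[str],
    weights: Optional[Sequence[float]] = None,
    alphabet: Optional[Iterable[str]] = None,
) -> Dict[str, float]:
    """Weighted monomer mole fractions from a set of sequences.

    fraction(m) = Σ_k w_k·count(m, seq_k) / Σ_k w_k·len(seq_k).  With all
    weights 1 this is plain genome/ORF counting; with proteomic
    abundances it weights each peptide's residues by its abundance.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    if weights is None:
        weights = [1.0] * len(sequences)
    if len(weights) != len(sequences):
        raise ValueError("weights must match sequences in length")
    allowed = set(alphabet) if alphabet is not None else set(AMINO_ACID_RESIDUE_MASSES)
    counts: Dict[str, float] = {}
    total = 0.0
    for seq, w in zip(sequences, weights):
        for ch in seq:
            if ch not in allowed:
                raise ValueError(f"unknown residue letter {ch!r}")
            counts[ch] = counts.get(ch, 0.0) + w
            total += w
    return {m: c / total for m, c in counts.items()}


def build_biomass_reaction(
    tables: Sequence[CompositionTable],
    monomer_masses: Mapping[str, float],
    gam: float = 0.0,
    reaction_id: str = "R_BIOMASS",
    product_id: str = "cellmass",
    energy_ids: Mapping[str, str] = None,
) -> Reaction:
    """Assemble the lumped biomass drain from composition tables.

    Each monomer is consumed at 1000 · mass_fraction · mole_fraction /
    (category's mole-weighted mean monomer mass) mmol per gDW, so one
    flux unit drains exactly one gram of dry weight into 1 unit of the
    ``cellmass`` pseudometabolite.  ``gam`` adds growth-associated ATP
    maintenance (ATP + H₂O → ADP + Pi) in mmol·gDW⁻¹.
    """
    total_mass = sum(t.mass_fraction for t in tables)
    if abs(total_mass - 1.0) > FRACTION_TOL:
        raise ValueError(f"category mass fractions sum to {total_mass}, not 1")
    stoich: Dict[str, float] = {}
    for t in tables:
        if t.mass_fraction == 0 or not t.monomer_distribution:
            continue
        mean_mass = 0.0
        for monomer, frac in t.monomer_distribution.items():
            if monomer not in monomer_masses:
                raise ValueError(f"no molar mass given for monomer {monomer!r}")
            mean_mass += frac * monomer_masses[monomer]
        for monomer, frac in t.monomer_distribution.items():
            if frac == 0:
                continue
            coeff = 1000.0 * t.mass_fraction * frac / mean_mass
            stoich[monomer] = stoich.get(monomer, 0.0) - coeff
    if gam:
        ids = dict(atp="atp", adp="adp", pi="pi", h2o="h2o")
        if energy_ids:
            ids.update(energy_ids)
        stoich[ids["atp"]] = stoich.get(ids["atp"], 0.0) - gam
        stoich[ids["h2o"]] = stoich.get(ids["h2o"], 0.0) - gam
        stoich[ids["adp"]] = stoich.get(ids["adp"], 0.0) + gam
        stoich[ids["pi"]] = stoich.get(ids["pi"], 0.0) + gam
    stoich[product_id] = stoich.get(product_id, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="biomass composition drain",
        subsystem="biomass",
    )


def build_cellulosome_reaction(
    spec: CellulosomeSpec,
    reaction_id: str = "R_CELLULOSOME",
    product_id: str = "cellulosome",
    amino_acid_ids: Optional[Mapping[str, str]] = None,
    energy_ids: Mapping[str, str] = None,
) -> Reaction:
    """Synthesis/export of one mole of average cellulosome residue.

    Amino acids are drained in the abundance-weighted residue
    distribution (coefficients summing to exactly 1 mol residue per mol
    of cellulosome); ``atp_per_residue`` ATP is hydrolysed to ADP + Pi
    per building block.  The mean residue mass (g/mol) is stored in the
    reaction's annotations under ``"residue_mass"`` — it is the formula
    mass of the cellulosome pseudometabolite.
    """
    seqs = [p[0] for p in spec.peptides]
    abundances = [p[1] for p in spec.peptides]
    dist = monomer_distribution_from_sequences(seqs, abundances)
    residue_mass = sum(f * AMINO_ACID_RESIDUE_MASSES[aa] for aa, f in dist.items())
    aa_map = dict(amino_acid_ids) if amino_acid_ids else {}
    stoich: Dict[str, float] = {}
    for aa, frac in dist.items():
        met = aa_map.get(aa, aa)
        stoich[met] = stoich.get(met, 0.0) - frac
    ids = dict(atp="atp", adp="adp", pi="pi")
    if energy_ids:
        ids.update(energy_ids)
    if spec.atp_per_residue:
        stoich[ids["atp"]] = stoich.get(ids["atp"], 0.0) - spec.atp_per_residue
        stoich[ids["adp"]] = stoich.get(ids["adp"], 0.0) + spec.atp_per_residue
        stoich[ids["pi"]] = stoich.get(ids["pi"], 0.0) + spec.atp_per_residue
    stoich[product_id] = stoich.get(product_id, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="average cellulosome residue synthesis and export",
        subsystem="biomass",
        annotations={"residue_mass": residue_mass},
    )


def build_lumped_species_reaction(
    components: Mapping[str, float],
    product_id: str,
    reaction_id: Optional[str] = None,
    fraction_type: str = "mole",
    molar_masses: Optional[Mapping[str, float]] = None,
) -> Reaction:
    """One reaction synthesizing 1 mol of an "average" molecular species.

    Components are precursor → fraction.  Mass (% w/w) fractions are
    converted to mole fractions via component molar masses before
    normalisation, because stoichiometry is molar.
    """
    if any(f < 0 for f in components.values()):
        raise ValueError("component fractions must be non-negative")
    total = sum(components.values())
    if abs(total - 1.0) > FRACTION_TOL:
        raise ValueError(f"component fractions sum to {total}, not 1")
    fracs = dict(components)
    if fraction_type == "mass":
        if molar_masses is None:
            raise ValueError("mass fractions require component molar masses")
        moles = {c: f / molar_masses[c] for c, f in fracs.items()}
        tot = sum(moles.values())
        fracs = {c: m / tot for c, m in moles.items()}
    elif fraction_type != "mole":
        raise ValueError(f"unknown fraction_type {fraction_type!r}")
    stoich = {c: -f for c, f in fracs.items() if f > 0}
    stoich[product_id] = 1.0
    return Reaction(
        id=reaction_id or f"R_{product_id.upper()}_AVG",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name=f"average {product_id} synthesis",
    )


def set_cellulosome_fraction(
    model: MetabolicModel,
    fraction: float,
    residue_mass: Optional[float] = None,
    cellmass_id: str = "cellmass",
    cellulosome_id: str = "cellulosome",
) -> MetabolicModel:
    """Re-weight the biomass objective between cellmass and cellulosome.

    The objective reaction drains the two pseudometabolites in mass
    proportions (1−f) : f.  One unit of cellmass weighs 1 g by
    construction; f grams of cellulosome are f·1000/M mmol where M is
    the mean residue mass (taken from the cellulosome reaction's
    ``residue_mass`` annotation unless given).  ``fraction=0`` removes
    the cellulosome drain entirely.  Returns a modified copy.
    """
    if not (0 <= fraction < 1):
        raise ValueError(f"cellulosome fraction must be in [0, 1), got {fraction}")
    if cellmass_id not in model.metabolites or cellulosome_id not in model.metabolites:
        raise KeyError(
            f"model must contain {cellmass_id!r} and {cellulosome_id!r} pseudometabolites"
        )
    if residue_mass is None:
        for rxn in model.reactions.values():
            if rxn.stoichiometry.get(cellulosome_id, 0.0) > 0:
                residue_mass = rxn.annotations.get("residue_mass")
                if residue_mass is not None:
                    break
        if residue_mass is None:
            raise ValueError(
                "mean residue mass not found on any cellulosome-producing reaction; "
                "pass residue_mass explicitly"
            )
    new = model.copy()
    obj = new.objective
    obj.stoichiometry[cellmass_id] = -(1.0 - fraction)
    if fraction == 0:
        obj.stoichiometry.pop(cellulosome_id, None)
    else:
        obj.stoichiometry[cellulosome_id] = -fraction * 1000.0 / residue_mass
    return new
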