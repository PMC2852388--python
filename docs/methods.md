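# Methods

## Model and assumptions

`thermoflux` analyses metabolism under the quasi-steady-state
assumption: over the timescale of interest, intracellular metabolite
concentrations are constant, so the net production of every metabolite
is zero, `S·v = 0`. Thermodynamics enters only through irreversibility
(a lower bound of zero on reactions taken to be one-way); there are no
ΔG-based constraints, kinetics, or dynamic simulation. Two compartments
are modelled, cytosol and extracellular space, with exchange
pseudo-reactions (`met_e ↔ ∅`) moving material across the system
boundary under the convention negative flux = uptake, positive =
secretion. Pseudometabolites — `biomass`, `cellmass`, `cellulosome` —
sit outside chemistry and carry the objective bookkeeping.

Flux balance analysis maximises the biomass flux Z by linear
programming; flux variability analysis characterises the degenerate
optimum by minimising and maximising each flux with Z constrained to
`[lo·Z*, hi·Z*]`. Alternate optima are treated as first-class: a single
returned flux vector is explicitly one of many, and only Z and FVA
ranges are contractual outputs.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| default flux bounds | ±1000 | mmol·gDW⁻¹·hr⁻¹ | "unconstrained" reactions; also applied when an SBML file lacks bound parameters (with a warning) |
| FVA optimum window | (0.99, 1.00) | fraction of Z* | the default window; "at the maximum growth rate" queries (the deletion screen, yield calculations, tradeoff scans) use (1.00, 1.00) |
| essentiality threshold | 1e-6 | hr⁻¹ | knockout growth below this counts as zero (LP solvers return tiny numerics, never exact zeros) |
| supplementation bounds | [−20, 0] | mmol·gDW⁻¹·hr⁻¹ | a supplemented metabolite may be consumed up to the cap but not produced — production is considered thermodynamically blocked by its external abundance |
| cellulosome `atp_per_residue` | 1 | mol ATP / mol residue | assembly + export cost of one average building block |
| cellulosome `mass_fraction` | 0.20 | g/g cell mass | share of dry weight when the cellulosome is expressed; 0 removes the drain entirely |
| tradeoff grid | 50 points | — | evenly spaced across the FVA-viable range of the fixed exchange |
| LP tolerances | 1e-9 solver / 1e-6 contract | — | HiGHS defaults at the solver; `FEASIBILITY_TOL` at the API contract |

## Biomass and cellulosome construction

Dry weight is split into macromolecular categories (protein, RNA, DNA,
lipids and cell wall, ions and metabolites), each with a mass fraction
and a monomer mole distribution (obtained, for protein/RNA/DNA, by
counting residues over ORFs or the genome). The drain coefficient of a
monomer is `1000 · mass_fraction · mole_fraction / m̄` mmol·gDW⁻¹,
where `m̄` is the category's mole-weighted mean monomer mass; one flux
unit therefore drains exactly 1 g of dry weight into one unit of
`cellmass` (mass closure is a tested invariant, ±0.1%). Residue masses
are peptide-bond-corrected (free amino acid minus one water), taken
from Biopython's average molecular weights. Growth-associated ATP
maintenance is a parameter, not re-derived: when a supplied model
already embeds it in the biomass row, that value stands.

The cellulosome is modelled as a pseudometabolite whose unit is one
mole of average amino-acid residue. Peptide sequences are weighted by
proteomic relative abundances to give the residue distribution; the
synthesis reaction drains amino acids with coefficients summing to
exactly 1 and hydrolyses `atp_per_residue` ATP to ADP + Pi. The mean
residue mass (g/mol) is stored on the reaction and used to convert the
mass split of the objective — `(1−f)` g cellmass : `f` g cellulosome —
into molar coefficients (`f·1000/m̄_res` mmol cellulosome per unit of
biomass). Lumped "average species" reactions (e.g. a representative
1-acyl-glycerol 3-phosphate from a measured fatty-acid pool) convert
% w/w inputs to mole fractions via component molar masses first,
because stoichiometry is molar.

## The vertex-enumeration oracle

Every flux is finitely bounded, so the feasible set is a bounded
polyhedron; if non-empty it has vertices and the LP optimum is attained
at one. A vertex fixes at least `n − rank(S)` fluxes at a bound with
the rest solved from the steady-state system. The oracle reduces `S` to
a row basis (QR with column pivoting on `Sᵀ`; dependent rows are
implied because the right-hand side is built from S's own columns),
then enumerates every choice of non-basic set and bound assignment,
solving all `2^k` assignments of one basis in a single LU solve.
Candidates violating bounds or the full balance (at 1e-7/1e-6) are
discarded; the best feasible objective is the optimum, and an empty
feasible set is reported as infeasible. Columns frozen at zero by their
bounds are removed before the size check (refusal above ~20 free
reactions). The oracle shares no code path with the LP solver — it is
the independent reference the engine is tested against on 200 seeded
random networks per run.

## Futile-cycle detection

With every exchange closed to `[0, 0]`, no reaction can carry
steady-state flux unless it participates in an internal loop — a
thermodynamically impossible cycle that a curated model must not
contain. The detector closes all exchanges, also closes the non-growth
ATP maintenance drain (ids `R_ATPM`/`ATPM`; a maintenance flux is not a
loop), and min/maximises every remaining reaction with no objective
constraint, reporting those whose range is not {0}.

## What the synthetic networks emulate — and what they do not

The fermentation toy reproduces, with integer yields chosen so every
optimum is hand-checkable (2 ATP and 2 NADH per glucose, 4 ATP per
biomass), the redox logic of clostridial fermentation: an
ATP-yielding acetate branch, NADH sinks through ethanol, lactate and —
via ferredoxin — H₂, and a formate-producing alternative to the
ferredoxin route. Its oracle-confirmed phenotypes: wild-type Z = 8
with ethanol pinned at zero across all optima; hydrogenase or NADH:Fd
oxidoreductase knockouts drop Z to 6 and force ethanol to exactly 10;
an acetate-kinase knockout (or acetate supplementation, which is
computationally identical) drops Z to 5 and raises the ethanol ceiling
to 5 while the floor stays 0, because NADH can still drain through the
ferredoxin/hydrogenase route; fixing H₂ escape at zero forces all
acetyl-CoA production through pyruvate formate lyase (formate ≥ 14);
closing both H₂ and ethanol leaves lactate as the only NADH sink, which
consumes every pyruvate, so growth collapses to zero.

Random networks plant a feasible linear pathway from one uptake to
biomass and add sparse random reactions with integer coefficients in
{−2, −1, 1, 2} among the planted metabolites, keeping vertex
enumeration exact and the validation report clean (no dead ends).

What passing these tests does **not** show: genome-scale numerical
behaviour (condition numbers, degeneracy at hundreds of reactions),
realistic biomass composition, or any property that depends on the
specific curation of a real reconstruction. The toys verify
correctness of the algorithms, not biological accuracy of predictions;
analyses of a real organism require its reconstruction as an input
file.

## Numerical and design choices

* LP backend: `scipy.optimize.linprog` (HiGHS) with presolve; statuses
  map to `optimal`/`infeasible`/`unbounded`.
* FVA windows with Z* = 0 collapse to exactly [0, 0]; windows are
  ordered min/max so negative objectives cannot invert bounds.
* `apply_medium` closes only uptake (exchange lower bounds); secretion
  stays open unless a fixed flux says otherwise. Fixed fluxes override
  everything.
* Supplementation never invents transporters: a candidate metabolite
  without an extracellular form in the model is skipped with a warning,
  since a free transporter would change the network being studied.
* GPR parsing gives `and` precedence over `or` and logs a warning for
  unparenthesized mixed expressions, which supplementary-file dialects
  are inconsistent about. Reactions with no GPR are always active.
* "Enhancing" deletions must strictly raise *both* FVA bounds of the
  target — raising only the ceiling merely permits, rather than forces,
  more product.
* The deletion screen groups output per gene; genes disabling identical
  reaction sets are distinguishable via the `disabled_reactions` field.
* Serialization: the tab dialect writes `-->`/`<==>` arrows inferred
  from the lower bound; SBML species names carry exact original ids so
  sanitization cannot corrupt a round trip.
* Problem sizes in the acceptance script (200 random 4-metabolite
  networks, the 18-reaction toy, a 9-reaction glycine cell) were chosen
  as the smallest networks that exercise every code path while keeping
  exhaustive vertex enumeration exact.

## Known limitations

* No charge or elemental balancing: the formats do not require species
  formulas, so mass closure is only enforced where the biomass builder
  computes it.
* SBML support targets the Level 2 bounds-in-kinetic-law dialect; the
  Level 3 FBC extension is not read or written (ids remain compatible).
* The vertex oracle is exponential by design and refuses networks
  beyond ~20 free reactions; it is a verification tool, not a solver.
* Single deletions only; no combinatorial knockouts or bilevel strain
  design.
* Pseudometabolite recognition is by conventional id
  (`biomass`/`cellmass`/`cellulosome`); custom pseudo ids survive in
  memory but lose their flag through serialization.
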