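# thermoflux

Constraint-based analysis of cellulolytic fermentation metabolism.

Anaerobes such as *Clostridium thermocellum* hydrolyse cellulose and
ferment it to a branched product spectrum — ethanol, acetate, formate,
lactate, H₂, CO₂ — making them candidates for consolidated bioethanol
production. Which products dominate is governed by the cell's
reduction–oxidation balance: every NADH produced in glycolysis must be
re-oxidised through ethanol, lactate, or (via reduced ferredoxin and a
hydrogenase) H₂. `thermoflux` is a toolkit for studying such networks
with genome-scale constraint-based models: it is aimed at metabolic
engineers who want to ask *which gene deletions or medium changes force
more ethanol?* and at modellers who need every stage of that analysis
to be independently verifiable on small networks.

## The core computation

Flux balance analysis (FBA) treats metabolism at steady state as a
linear program over the flux vector **v** (mmol·gDW⁻¹·hr⁻¹):

```
maximize    Z = v_biomass
subject to  S · v = 0
            aᵢ ≤ vᵢ ≤ bᵢ   for every reaction i
```

where `S` is the stoichiometric matrix (one row per metabolite, one
column per reaction, entries s_ij) and the bounds encode
irreversibility, uptake limits and measured fluxes. Because optima are
usually degenerate, flux variability analysis (FVA) re-solves two LPs
per reaction with `Z` pinned to a window of its optimum, yielding the
range of each flux over all optimal states. On top of this core the
package provides:

* **model IO** — a tab-delimited reaction-list dialect and SBML Level 2
  (COBRA-style bounds in kinetic laws, GPRs in notes), round-tripping
  exactly;
* **GPR logic and knockouts** — boolean gene–protein–reaction rules
  (`and` = complex subunits, `or` = isozymes), genome-wide essentiality
  scans, and a screen for deletions that *force* higher ethanol
  secretion (both FVA bounds strictly raised);
* **biomass construction** — composition-table-driven biomass drains,
  plus a cellulosome term: one mole of cellulosome is one mole of its
  abundance-weighted average amino-acid residue, with a tunable ATP
  cost per residue and mass fraction (default 20% of cell mass);
* **environmental scans** — progressive constraint layering against
  measurements, media supplementation at [−20, 0] exchange bounds,
  H₂/ethanol tradeoff surfaces, cellulosome burden curves;
* **EC-based model comparison** — Venn partitions of reaction content
  across reconstructions with the multi-EC reconciliation rule;
* **an independent oracle** — exhaustive vertex enumeration of
  {v : S·v = 0, a ≤ v ≤ b} for networks of ≤ ~20 reactions, against
  which the LP engine is verified on every synthetic fixture.

## Worked example

The bundled fermentation toy (18 reactions, integer yields) mirrors the
redox wiring of clostridial fermentation. `examples/01_fba_fermentation_toy.py`
prints:

```
maximum growth rate Z = 8.000 (flux on the biomass reaction)
exhaustive vertex-enumeration oracle agrees: Z = 8.000

one optimal flux distribution (non-zero exchanges):
  EX_glc        -10.000  (uptake)
  EX_ac          12.000  (secretion)
  EX_for         12.000  (secretion)
  EX_h2          20.000  (secretion)
  EX_biomass      8.000  (secretion)

ethanol secretion across ALL optima: [0.000, 0.000]
```

At maximum growth the cell makes acetate (for its extra ATP) and dumps
electrons as H₂ — ethanol is zero across *all* optima. Knock out the
hydrogenase gene (`examples/02_gene_knockouts.py`) and the redox balance
flips: growth falls to 6 while ethanol is pinned at exactly 10, because
ethanol is now the obligatory NADH sink:

```
  g_HYD    Z =  6.00  ethanol [10.00, 10.00] <-- enhancing
  g_NFO    Z =  6.00  ethanol [10.00, 10.00] <-- enhancing
  g_ACK    Z =  5.00  ethanol [ 0.00,  5.00]
```

Only the two redox-sink knockouts raise *both* ethanol bounds; blocking
acetate raises the attainable ceiling but not the floor. The remaining
examples cover media supplementation and the H₂/ethanol tradeoff,
biomass/cellulosome construction, and EC-based model comparison.

A thin CLI mirrors the common shell workflows:

```bash
cthm synth --generator ferm --out toy.tsv
cthm fba --model toy.tsv --fix EX_h2:0:0
cthm deletions --model toy.tsv --target EX_etoh
cthm loops --model toy.tsv
```

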