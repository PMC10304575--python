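# Methods

## 1. Model formulation

A metabolic model is a set of metabolites (id, compartment, optional Hill
formula and charge) and reactions (signed stoichiometry, flux bounds, GPR
string, subsystem), plus one objective reaction. The stoichiometric matrix
`S` (metabolites × reactions) is derived from the reactions on demand and is
identical after any write/read round trip.

Conventions (fixed package-wide):

- Fluxes are in **mmol/larva/day**; the biomass flux is a specific growth
  rate in 1/day.
- Negative stoichiometric coefficients are substrates, positive products.
- Boundary (exchange/demand) reactions touch exactly one metabolite;
  **uptake is negative flux**, so an uptake limit `u` is applied as
  `lower_bound = -u`.
- Bounds absent from a file default to **±1000 mmol/larva/day**.

**Flux balance analysis (FBA)** solves
`max c·v  s.t.  S v = 0,  lb ≤ v ≤ ub`
with `c` the indicator of the objective reaction. **Flux variability
analysis (FVA)** then minimizes/maximizes each requested flux subject to the
additional row `c·v ≥ fraction × optimum` (default fraction 0.9).

All optimization goes through one narrow contract
(`larvaflux.linear.solve_lp`) backed by `scipy.optimize.linprog`
(HiGHS, primal/dual feasibility tolerances 1e-9), so results are
solver-agnostic by construction. Optimal solutions are checked for steady
state (`max |S v| ≤ 1e-6`, relative to the largest flux); infeasibility and
unboundedness are reported through statuses, never silently.

## 2. Biomass objective

Composition assays give macromolecule classes in g/100 g dry weight, an
amino-acid profile in mg/100 g protein, and a fatty-acid profile in
g/100 g fat. Construction steps:

1. Drop non-synthesized classes (`water`, `ash`, `carbohydrates_other`) and
   renormalize the remainder to sum to 1 (enforced to 1e-9).
2. Expand the amino-acid class over the profile, and the fat class over two
   triacylglycerol species — TAG-A (C12:0/C14:0/C16:0) and TAG-B
   (C16:1/C18:1/C18:2) — using the declared 0.49/0.51 split (the split
   recomputed from the profile's chain-mass sums, 45.6 vs 46.54 g/100 g
   fat, is 0.495/0.505 and is available via `declared_split=None`).
3. Insert membrane cholesterol, which insects cannot synthesize de novo, at
   a donor-model mass ratio (default 0.02), rescaling the rest by 1 − r.
4. Convert mass fractions to molar coefficients:
   `coef_i = fraction_i × larva_dry_weight / molar_mass_i` with molar
   masses in g/mmol, so one unit of biomass flux consumes exactly one larva
   dry weight of precursors (mass closure tested to 1e-9 g).

Defaults: final wet weight 0.028 g/larva, dry weight = 30% of wet weight =
0.0084 g. Amino-acid molar masses are derived from their formulas; cystine
is the oxidized dimer (C6H12N2O4S2).

## 3. Diet-derived exchange bounds

The feeding trial applied 846 g glucose (fully consumed) and 1870 g
egg-white protein (560 g consumed) over 9 days. The printed per-larva
population counts are mutually inconsistent, so the larva count is
back-computed from the consumed amino-acid masses and the measured
mg/larva/day column (mean over the twenty amino acids, ≈5357); this choice
is what makes the mg → mmol conversions reproduce the measured molar rates
(lysine 0.012, glycine 0.013, valine 0.017, tryptophan 0.002
mmol/larva/day) to three decimals.

`apply_diet` is a pure function: listed exchanges get `lower_bound =
-limit`, unlisted exchanges are closed to uptake unless whitelisted (water,
O2, CO2, phosphate, sulfate, ammonia, protons), and secretion bounds are
untouched. Cholesterol gets a small fixed allowance (0.004 mmol/larva/day)
covering the sterol demand.

## 4. Synthetic network

The generator emulates the published larval model's *shape* without copying
any of its (unpublished) internal stoichiometry: three compartments
(extracellular/cytosol/mitochondrion), exchange + transport pairs for all
nutrients, and lumped internal chemistry:

| reaction | lumped stoichiometry (before auto H/O closure) |
|---|---|
| GLYCPDH | glc + 2 ADP + 2 Pi + 4 NAD + 2 CoA → 2 acetyl-CoA + 2 CO2 + 2 ATP + 4 NADH |
| ACCOAOX | acetyl-CoA + 4 NAD + ADP + Pi → 2 CO2 + CoA + 4 NADH + ATP |
| RESP (mito) | NADH + ½ O2 + 2 ADP + 2 Pi → NAD + 2 ATP (P/O = 2) |
| THD | NADH + NADP → NAD + NADPH |
| CYTB5R | NADH + 2 ferricytochrome-b5 → NAD + 2 ferrocytochrome-b5 |
| FAS_fa(n:d) | n/2 acetyl-CoA + (n−2) NADPH + (n/2−1) ATP (+ per double bond: 2 ferrocyt-b5 + O2) → fatty acid + ... |
| TAGS_* | glycerol + 3 acyl chains + 3 ATP → TAG |
| ATPM | ATP → ADP + Pi (non-enforced hydrolysis valve) |

Every generated internal reaction is elementally balanced: the builder
closes hydrogen and oxygen with explicit `h`/`h2o` species and refuses to
emit a reaction whose other elements do not cancel. Cofactor formulas
follow the BiGG conventions. The biomass pseudo-reaction is the only
unbalanced internal reaction (its product is a formula-less `biomass_c`).

Because the network contains **no amino-acid interconversion**, the FBA
optimum has the closed form
`μ* = min_i (uptake_i / biomass_coefficient_i)` over the dietary
precursors, provided glucose covers the carbon/energy demand with slack —
which `analytic_bottleneck` verifies analytically (glucose demand per unit
biomass from carbon accounting plus NADH/NADPH/ATP budgets, shortfalls
covered by fully oxidizing extra glucose at 12 NADH + 4 ATP per glucose).
On default parameters the bottleneck is the glutamate/glutamine pair
(μ* = 3.4695/day) and the LP reproduces it exactly; glucose runs at ~96.5%
of its uptake limit. Diet and biomass derive from the same protein profile,
so all twenty amino acids are nearly co-limiting — doubling any single one
changes nothing, and doubling glucose changes nothing by construction.

The seed permutes reaction order and populates optional decoy reactions
only; it never alters core topology, so all seeds share the same optimum.
Removing CYTB5R blocks both desaturation-dependent fatty acids and, through
TAG-B, all growth.

Known QC signature of the generated network: 0% dead-end metabolites; the
proton exchange/transport pair is reported blocked (every internal reaction
is H-balanced, so no net proton ever crosses the boundary); "unbalanced"
reactions are exactly the boundary pseudo-reactions plus biomass.

## 5. Quality control

- **Dead ends**: metabolites only producible or only consumable given
  bound-derived reaction directionalities.
- **Blocked**: per-reaction flux max/min over the steady-state cone both
  within ±1e-9 of zero; by default all exchanges are first opened to ±1000
  (community convention) so blockage reflects topology, not diet; the
  as-given-bounds mode is available.
- **Mass balance**: per-element net sums from Hill formulas; reactions with
  missing or pseudo-element formulas count as unbalanced ("unparseable").
- Percentages are reported to two decimals with supporting id lists.

## 6. Carbon-conversion efficiency

For each fatty-acid drain, the drain rate is the FVA maximum at 90% of the
optimum and uptake rates are the applied diet limits. Two orientations are
reported: `printed = 100 × Σ(Ci·uptake_i)/(Cf·drain)` and
`efficiency = 100 × (Cf·drain)/Σ(Ci·uptake_i)`; their product is 10000
whenever both are defined. Carbon counts come from metabolite formulas in
the model and can be overridden for formula-less species. Under doubled
glucose the efficiency ratio obeys the exact identity
`efficiency_ratio = drain_ratio / carbon_in_ratio`; on the synthetic
network the freed acetyl-CoA surplus makes every drain maximum rise more
than total dietary carbon, so the measured efficiency increases.

## 7. Verification strategy

- **Independent oracles**: FBA/FVA extrema are compared (1e-7) against a
  brute-force vertex-enumeration oracle on random finite-bounded networks
  of ≤8 reactions (FVA via a slack-variable reduction of the
  objective-retention row); written SBML/JSON files are re-read with
  `cobra` and re-optimized with GLPK, reproducing the optimum to 1e-6
  relative. cobra is never used in the implementation.
- **Analytic ground truth**: the generator's closed-form bottleneck, the
  mass-closure identity, the efficiency-orientation duality, and
  relaxation monotonicity (doubling any uptake never decreases an LP
  optimum) over 100 seeded networks.
- **Measured-table bookkeeping**: saturated/monounsaturated/
  polyunsaturated sums, modeled-acid coverage, and all published molar
  uptake rates are recomputed from the raw tables.

## 8. Numerical choices and limitations

- HiGHS with 1e-9 feasibility tolerances; steady-state acceptance at
  1e-6 (relative); FVA min/max pairs within solver jitter are swapped
  rather than failed.
- JSON and tabular round trips are numerically bitwise exact (`repr`
  serialization); SBML stores doubles at 15 significant digits, exact to
  ~1 part in 1e15.
- Percent rounding is half-away-from-zero (so 19.8 → 20, 0.5 → 1).
- Out of scope: amino-acid interconversion and degradation pathways,
  isotope-resolved carbon tracing, gap filling/repair of dead ends,
  pathway lumping algorithms (lumped reactions are taken as given), and
  GPR boolean evaluation (rules are stored and round-tripped, not
  evaluated).
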