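# Methods

## Model and assumptions

The core model is steady-state flux balance analysis: internal metabolite
concentrations are constant (S·v = 0), reaction directionality is the
only thermodynamic information used, and growth is represented by a
pseudo-reaction consuming biomass precursors in fixed ratios and
producing one unit of population. Fixed ratios presume the cellular
composition does not change over the growth phase analyzed; the linear
analyte-vs-OD fits are the empirical check of that assumption.

Boundary conditions come in four classes, chosen per metabolite:
ubiquitous compounds (CO₂, H₂O, Na⁺, Cl⁻, K⁺, H⁺ by default) exchange
freely in both directions; the carbon source and O₂ are parameters, fixed
as equality constraints (an option relaxes them to ≤ bounds for
sensitivity work); secretion-only exchanges let any metabolite accumulate
in the medium (overflow metabolism) but never enter; abundant compounds
(sulfate, phosphate, trace ions) have free uptake only. Because the whole
constraint set is linear and homogeneous, scaling both parameterized
uptakes by k scales every feasible flux — hence the analysis depends on
the acetate:O₂ *ratio* and a single arbitrary total-uptake scale
(default 10).

Exchange reactions are written as export reactions ({met: −1}), so
secretion is positive flux and uptake negative. Exchange reactions for
metabolites in no boundary class are closed (flux 0): nothing else
crosses the boundary.

## Balance auditing

Stoichiometric coefficients and element counts are exact rationals
(`fractions.Fraction`), so balance sums carry no float error and verdicts
are exact. A reaction is BALANCED iff every element delta and the charge
delta are zero; if any participant lacks a formula or charge annotation
the verdict is UNVERIFIABLE — "cannot check" is deliberately distinct
from "fails the check", because curated networks typically carry a few
reactions with unknown reactants. No automatic proton/water slack is
applied: deltas are reported verbatim, since the annotated ionization
states (here, the dominant microspecies at pH 9) are expected to balance
as given. Exchange and growth reactions cross the system boundary and are
skipped (marked as such) rather than counted.

Gene–reaction rules are boolean trees (AND for obligatory complex
partners, OR for isoenzymes), with a fixed grammar: identifiers, AND, OR,
parentheses, AND binding tighter than OR. Empty logic evaluates to False
under every gene set — a reaction with no genetic support is never
"satisfied". Evidence is a genetic class (SPECIFIC / GENERAL_ONLY / NONE)
plus independent literature and gap-fill flags; gap-fill implies no other
support by definition.

## Growth-reaction construction

Composition regressions are least squares constrained through the origin
(zero biomass at zero optical density); an intercept mode exists as an
option. Slope standard errors use n−1 degrees of freedom.

Parameters that matter, with defaults:

| parameter | default | units | role |
|---|---|---|---|
| TOC slope | 18.2 | mmol C / OD·L | bulk carbon per biomass unit |
| nucleotide fraction of TOC | 0.2 | – | sizes the nucleotide pool |
| mean C per nucleotide | 9.66 | atoms | converts pool carbon to moles |
| `split_fraction_AT` | 0.634 | – | AT share of the nucleotide pool |
| reference minor components | archaeol 20.0, GalNAc 2.2, GlcNAc 2.2, Gal 9.6, Glc 9.6, ATP 2.0 | µmol / OD·L | non-measured components |
| salt (Na⁺/K⁺ and Cl⁻) | 2813.4 each | µmol / OD·L | intracellular ion content |
| maintenance energy | 0 | µmol ATP / ΔOD·ml | ATP hydrolysis per biomass unit |

Two nucleotide-sizing modes are provided — fixed fraction of TOC
(default) and residual carbon after all other components — because the
two are only equivalent when the rest of the composition is complete and
exact. Note a deliberate naming caution: `split_fraction_AT` defaults to
0.634 and gives the *larger* share to the A and T/U pairs (81.6 vs 47.1
µmol/OD·L out of a 257.4 pool), which reproduces the committed
composition ratio even though the genome's GC content is the 63.4%
figure; the parameter is therefore named for what it does (the AT share),
not for GC, and is freely settable.

Unmeasurable amino acids are estimated from molar proteome frequencies
(one copy per gene) supplied as an input table — the package never parses
a genome. Combined pools are split proportionally to those frequencies
and conserve their totals exactly.

Maintenance is folded into the growth reaction as an ATP-hydrolysis term
proportional to growth flux (ATP + H₂O → ADP + Pi), not as a constant
flux: the parameter is defined per unit biomass produced. The canonical
biomass unit is OD·L; maintenance quoted per ΔOD·ml converts by ×1000.
The respiration-based estimate is maintenance = (µmol O₂ per ΔOD·ml) ×
(O atoms per O₂) × (P:O ratio); `atoms_per_o2` defaults to 2 (P:O defined
per oxygen atom) with the per-O₂ reading available as an option, since
either convention appears in practice.

## Phenotype sweep

The grid defaults to 81 acetate fractions (0.10–0.90, step 0.01;
quotients 1:9–9:1) × 21 maintenance values (0–100, step 5). One LP is
solved per cell; the growth reaction is rebuilt once per maintenance row.
Proven infeasibility (the solver's certificate) is recorded as such;
any numerical failure raises instead of masquerading as infeasible.
Optimality-curve ties within a 1e−9 relative band are reported as a
plateau interval with the midpoint as scalar representative.
Near-optimality of an observed ratio uses the nearest grid row (linear
interpolation optional) and scores an infeasible observation 0.

Feasibility per row is a contiguous interval (a consequence of the LP
value's concavity in the uptake vector); the suite asserts contiguity,
row-wise monotonicity in maintenance, scale invariance in total uptake,
and stability of bounds under grid refinement.

## Carbon accounting

Units are µmol throughout; concentrations convert through the culture
volume (mM × ml = µmol). Acetate disappearance is differenced between
consecutive samples without smoothing (optional monotone regression is a
non-default); an interval where acetate rises is flagged, warned about
and contributes zero uptake rather than negative. The RER defaults to
1.0, the theoretical value for complete acetate oxidation, and is
configurable. The delta fate is reported neutrally — it may be secretion
or measurement error; the ledger does not attribute it.

## Numerical choices

* LP backend: scipy's HiGHS, behind a minimal solve interface so other
  backends can be registered. Problems can be dumped as CPLEX-LP text for
  external audit.
* Steady-state tolerance: OPTIMAL solutions must satisfy |S·v| ≤ 1e−7
  absolute after scaling each row to unit maximum; worse residuals
  downgrade to a numerical-failure status. INFEASIBLE is only reported
  when the solver proves it.
* Alternate optima: the objective value is the contract; the returned
  flux vector is one optimal vertex, with no lexicographic tie-breaking.
* The vertex-enumeration oracle activates every subset of finite bound
  constraints of the right cardinality and solves the resulting linear
  systems exactly; it refuses instances with more than 8 degrees of
  freedom after equality elimination and assumes the optimum is attained
  at a vertex (true for the pointed toy instances it serves). It shares
  no code path with the LP backend.
* SBML serialization writes formula/charge/gene-association/evidence in
  COBRA-style notes (the convention of constraint-based models of this
  vintage); coefficients round-trip exactly when they have finite decimal
  expansions. Missing annotations read back as UNKNOWN.

## What the synthetic generators emulate — and what they do not

The AC-CORE toy stylizes aerobic acetate metabolism into activation
(1 ATP), complete oxidation (2 O₂ → 2 CO₂ + 4 ATP) and biomass formation
(1 acetyl + 2 ATP), with an explicit ATP sink so surplus-energy states
stay feasible (a toy-only construct: curated networks dissipate surplus
through their own cycles, so no sink is added to them). Its substrate
formulas are constructed so the same exact audit machinery passes, with
ATP/ADP/HPO₃ forming a conserved moiety. Closed forms for the toy: growth
g = a − w/2; feasibility a ≥ w/2 and 2w ≥ a + (2+m)·g; optimal fraction
a*/T = (6+m)/(12+3m). These are re-derived independently by the vertex
oracle in the tests.

The growth-experiment simulator produces series whose cumulative carbon
fates equal the configured fractions by construction (defaults: 35%
incorporated, 63% respired, RER 1, TOC slope 18.2 mmol C/OD·L, 35 ml
culture, exponential OD from 0.1 at 0.02 h⁻¹ over 156 h — a slow-growing
extremophile batch culture). Noise is independent Gaussian per channel;
O₂ noise is applied to interval increments (floored at 0) so cumulative
O₂ stays monotone. The generators do not model autocorrelated sensor
drift, lag/stationary phases, evaporation, or the topology of a real
683-reaction network — so passing tests demonstrate correctness of the
analysis machinery and identifiability under the stated conditions, not
robustness to every artifact of real cultures.

Problem sizes used in the tests and the acceptance script — 81-fraction
sweeps with 3–5 maintenance rows, 14–30-sample experiments, 20-sample
composition panels, 25-point oracle grids — are chosen so each check
isolates one property at full numerical precision while the whole suite
stays quick to iterate on.

## Known limitations

* No flux variability analysis, MOMA/ROOM, thermodynamic or integer
  constraints; no gene-deletion simulation (gene logic is consumed as
  data).
* The curated reconstruction's own files are not redistributed; the
  acceptance checks against its published statistics require the user to
  supply the export (see README).
* Tabular input is delimited text; binary spreadsheets must be exported
  first.
* The oracle does not detect unbounded instances; it is an oracle for
  bounded toy problems, not a general solver.
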