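# Methods

## The constraint-based model

All predictions come from linear programs over the steady-state flux cone

    maximize  v_growth
    subject to  S v = 0,   lb <= v <= ub,

where `S` is the stoichiometric matrix with one balance row per
non-boundary metabolite and `v_growth` is the flux through the biomass
reaction.  The biomass reaction consumes each precursor X_i at c_i mmol per
unit of biomass flux and hydrolyzes GAM ATP equivalents; NGAM is a separate
drain reaction whose flux is fixed (`lb = ub`), so it binds regardless of
growth.  Boundary species (SBML `boundaryCondition`, or per-file id-suffix
conventions, since published models differ) get no balance row; exchange
reactions therefore appear as single-ended columns.

Assumptions inherited from the framework: steady state (no metabolite
accumulation), a growth objective (biomass yield maximization), and bounds
as the only kinetic information.  Degenerate alternate optima are the rule,
not the exception; plain `solve_fba` consequently guarantees only the
objective value, never individual fluxes.

## Geometric mode

`geometric_fba` resolves the degeneracy by computing the flux distribution
central to the optimal face:

1. pin the objective at the plain-FBA optimum (equality within 1e-9 — an
   equality rather than a `>=` cut, so every subsequent LP really lives on
   the optimal face);
2. compute FVA ranges `[lo_i, hi_i]` for all reactions over the current
   face;
3. find the feasible `v` minimizing the total L1 deviation from the range
   midpoints (auxiliary-variable LP);
4. stop when every flux is within `tol` of its midpoint; otherwise shrink
   each unconverged range to its middle half `[lo + w/4, hi - w/4]` and
   repeat.

The middle-half contraction halves every range per iteration, so
convergence needs at most ~log2(width/tol) ≈ 31 iterations for the default
tolerance 1e-6 and the ±1000 bound convention; `max_iter` defaults to 50
and non-convergence raises an error carrying the last iterate.  The
interval-hull alternative (shrinking to the span between the L1 iterate and
the midpoint) was rejected: when the L1 projection is itself degenerate —
e.g. three or more interchangeable pathways, where moving one unit of flux
between parallel routes leaves the L1 objective unchanged — it commits to
an arbitrary vertex and destroys the symmetry of the result.  The
middle-half rule contracts the *box*, not the iterate, is
permutation-equivariant, and splits n interchangeable pathways exactly
equally (verified for n = 2, 3, 4).

Tolerances: LP feasibility 1e-7 (`FEAS_TOL`), geometric tolerance 1e-6,
objective pin 1e-9.  Infinite or missing bounds are encoded as ±1000 flux
units so every LP is bounded — a unit convention, not physics; results that
run into that cap (futile-cycle circulation, for instance) are capped by
convention, not by the network.

FVA at `optimum_fraction = 1` uses the same equality pin; fractions in
(0, 1) relax it to `v_growth >= fraction * optimum`, and 0 removes it,
which is also how blocked-reaction detection works.

The LP backend is scipy's HiGHS (`scipy.optimize.linprog`), wrapped in a
single `solve_lp` helper that fixes the contract (equalities, bounds,
optional inequality block, min/max sense) and is deterministic given a
fixed input ordering.

## Biomass handling

Weight normalization rescales all coefficients by the single factor
`k = 1 / sum_i(c_i * MW_i / 1000)` so one unit of biomass flux equals 1 g
dry weight; it is idempotent and scale-invariant, and it is the step that
makes compositions published in different unit conventions comparable
before they are swapped between models.  GAM is a scalar attached to the
composition but *not* a weighed component: swapping compositions between
models never silently changes the maintenance cost, and `normalize_by_weight`
rescales GAM only on explicit request.

Perturbed compositions (the ±30 % scans) are deliberately **not**
re-normalized — the point of the scan is to vary one coefficient while the
rest of the recipe stays fixed.  A perturbed composition's
grams-per-flux-unit therefore drifts from 1; `total_mass()` reports the
effective value.

Producibility of a component in a model is decided by LP: a temporary
export drain for the metabolite is maximized under the scenario
constraints, and the component counts as producible when the optimum
exceeds 1e-6.  Cross-model component intersection keeps the ids producible
in *every* model and reports the per-model exclusions.

ATP hydrolysis for GAM is configurable per model via `GAMRecipe`
(ATP + H2O -> ADP + Pi + H, cytosolic by default); entries set to `None`
are skipped, which is how toy networks with a bare energy-currency
metabolite attach maintenance.

`build_biomass_reaction` accepts any positive coefficients; whether a
composition is weight-normalized first is the caller's explicit step, since
the toy fixtures intentionally use raw coefficients with closed-form
optima.

## Scenario matrix and statistics

A scenario is one (model, composition) pair under the shared constraint
set: carbon uptake capped at 10 flux units as sole carbon/energy source,
N/S/P exchanges open, NGAM fixed at 2.02, products freely exportable, and
GAM at 53.26 held constant across all scenarios.  Scenario ids follow the
`<Model>-<BOF>` convention and the pairing of a model with its own
composition is the reference scenario.

Dispersion is the per-reaction standard deviation of central fluxes across
a scenario group, summarized by its median.  The sample (n−1) estimator is
the default — with three scenarios per group the n vs n−1 choice matters,
so it is surfaced as `ddof`.  NaN entries (reactions absent from a model)
are excluded pairwise, and a reaction needs two observed values to
contribute.

FVA overlap classification calls a reaction *non-overlapping* across
scenarios only when its intervals are pairwise disjoint over **all**
compared scenarios, with touching endpoints counted as overlapping; the
per-pair detail is returned alongside the verdicts because the pairwise-all
rule is a convention, not the only defensible one.  Label-level ranges for
lumped reactions are the componentwise interval sums — a conservative
(superset) interval for the summed flux.

The 33-step central-carbon map ships as an editable YAML template
(`data/central_carbon_map_template.yaml`); per-model reaction ids, and
lumping choices such as representing the electron transport chain as
AOX/COX pairs versus separate complexes, live in that file, not in code.
Labels whose ids are absent from a model are reported as NaN, never as 0.

## Sensitivity analyses

Single-component scans multiply one coefficient by 0.7 or 1.3 (the
conventional ±30 % band), re-solve, and record the growth change in percent
of the reference growth.  Correlations between growth response and
coefficient size use the magnitude `|Δ%|` with up/down records pooled by
default (signed variants are available), against either the fractional
carbon coefficient `c_i nC_i / Σ c_j nC_j` or the weight fraction
`c_i MW_i / Σ c_j MW_j`.  Zero variance on either axis is reported as
*undefined*, not coerced to r = 0.  When molecular weight is proportional
to carbon count across components the two bases coincide exactly — the
limit in which "similar correlations on both bases" becomes an identity.

The maintenance scan solves four configurations — none, GAM only, NGAM
only, both — and reports each growth as a signed percent difference from
the "both" scenario.  A model whose differences all vanish (within 1e-6) is
flagged maintenance-insensitive; a free energy-generating cycle produces
exactly this signature.

## Synthetic networks

The generators define the test-scale study conditions:

* **Canonical toy** (`make_toy`): uptake ≤ 10 of a glucose-like substrate,
  n parallel catabolic routes each yielding 3 energy units, a drain fixed
  at 2, biomass = 0.5 substrate + 1 energy.  Closed form
  `v* = (y·u − ngam) / (y·c_G + c_E)` = 11.2 under the defaults; parallel
  copies make the optimum degenerate without moving it.  Negative `v*` is
  constructed anyway and flagged infeasible-by-design.
* **Futile cycle** (`make_futile_cycle_model`): a two-carrier loop with an
  energy-generating branch (10 energy units per turn, so its capacity at
  the ±1000 cap exceeds any toy demand) and a free circulation branch
  (making the loop flux degenerate at the optimum).  Maintenance becomes
  non-binding and growth collapses to `uptake / c_G` = 20.
* **Branched toy** (`make_branched_toy`): n precursors each synthesized
  from k_i substrate + e_i energy, weighing 180·k_i g/mol with 6·k_i
  carbons.  Closed-form optimum
  `v* = (y·u − ngam) / (y·Σc_i k_i + Σc_i e_i + gam)`; because synthesis
  cost is carbon-dominated, growth responses to single-coefficient
  perturbations track the fractional carbon (and weight) coefficient,
  which is what the correlation analyses measure.
* **Random compositions** (`make_random_composition`): `class_mix` gives
  target *weight shares* per macromolecule class (compositions in this
  field are reported as weight percentages, so that is what a class mix
  should pin down); counts are allocated by largest remainder, coefficients
  drawn log-uniformly over one decade, MW in 60–800 g/mol, carbon counts in
  2–40, then each class is rescaled to its target share and the whole is
  weight-normalized.  Fully reproducible from the seed; no global random
  state anywhere.

What the toys do *not* emulate: compartmentalization beyond labels,
cofactor stoichiometry (NADH/NADPH distinctions), elemental formulas by
default (mass-balance audits are opt-in), and the 500–3500-reaction scale
of published reconstructions.  Passing tests on these fixtures validate the
algorithms and bookkeeping — LP correctness, centering, normalization,
statistics — not the biology of any particular genome-scale model.

## Problem sizes and runtime choices

The shipped analyses use fixtures of ≤ 30 reactions, a 100-network random
sweep for the solver-vs-enumeration comparison (networks capped at 8
reactions so exhaustive vertex enumeration stays exact), a 3 × 3 scenario
matrix, and 8-component branched networks for the correlation block.  At
these sizes the whole test suite and the acceptance script each complete in
seconds on one core.

On the toy scale the acceptance script's maintenance numbers are dominated
by GAM: 53.26 ATP equivalents per biomass unit is enormous relative to a
two-component biomass, so removing maintenance changes growth by orders of
magnitude more than in a genome-scale model, where biomass synthesis
itself consumes most of the carbon.  The futile-cycle contrast (exactly 0 %
effect) is unaffected by this scale difference.

## Known limitations

* No gene–protein–reaction logic, annotation handling, gap-filling, MILP,
  loopless FBA, pFBA/MOMA or quadratic objectives.
* `validate_model`'s blocked-reaction check opens every exchange to the
  magnitude cap; reactions blocked only under specific media are not
  distinguished from structurally blocked ones.
* Geometric FBA's centrality is defined relative to the midpoint-contraction
  procedure above; other centering conventions (Chebyshev center, analytic
  center) would pick different, equally defensible points on wide faces.
* Element-balance auditing requires formulas on every participant of a
  reaction; partially annotated reactions are skipped, not flagged.
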