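# Methods

## Flux balance analysis

The pipeline solves the standard steady-state LP: maximize c·v subject to
S·v = ẋ, Vmin ≤ v ≤ Vmax, with ẋ = 0 for internal metabolites and ẋ free
for boundary metabolites. The stoichiometric system is assembled sparsely
with one mass-balance row per non-boundary metabolite; species flagged as
boundary (SBML `boundaryCondition`, or membership in a compartment declared
as boundary) get no row, and their net production rate S_b·v is reported as
the accumulation readout of a solution.

Solver: HiGHS through `scipy.optimize.linprog`, with primal/dual
feasibility tolerances of 1e-9 and a mass-balance acceptance tolerance of
1e-6 (asserted as an invariant on every optimal solution in the tests).
Variable order is the model's reaction order, so results are deterministic
on a given machine.

**Alternate optima.** FBA optima are degenerate: the objective value is
unique, the flux vector is not. The default solve returns the plain LP
vertex, matching common practice with simplex-based solvers. With
`resolve_degeneracy=True` a secondary LP minimizes Σ|v| (split-variable
formulation v = p − q, p,q ≥ 0) subject to c·v fixed at the optimum; this
parsimonious vertex is what the samplers and the L1 columns of the scan
tables report, because any flux that *can* be zero at the optimum *is*
zero there, making tracked non-objective fluxes reproducible. Reported
lactate/succinate/PDH values at an ATP optimum should always be read with
this caveat; scan tables can carry both the plain and the L1 value side by
side so the difference is visible rather than hidden.

**Sign convention.** Exchange reactions are single-sided
(`metabolite →`): positive flux = export/accumulation, uptake cap U =
lower bound −U. "Unconstraining" an uptake therefore lowers the lower
bound to −B with the large bound B = 1000 µmol min⁻¹ gDW⁻¹ (conventional
FBA default, configurable everywhere it is used).

## Scenario protocols

* **Condition presets.** Oxygen uptake caps: normoxia 19.8, hypoxia 1.9,
  anoxia 0 µmol min⁻¹ gDW⁻¹. The hypoxic level is exposed as the explicit
  value 1.9 (the level used in reported simulations) rather than computed
  as 10% of 19.8 (= 1.98); the titration grid itself always uses exact
  fractions of the base cap.
* **Oxygen titration.** Eleven levels at fractions 1.0, 0.9, …, 0.0 of the
  base cap (both endpoints included); each level re-solves the ATP
  maximization and records the objective plus tracked fluxes. Infeasible
  levels are recorded with their status and the scan continues.
* **PDH titration.** The condition is applied first; PDH's maximum flux
  capacity is measured by a dedicated LP with PDH as the objective (an
  unbounded capacity is clamped to B with a warning); then the upper bound
  is capped at 100% … 0% of capacity. Zero capacity (e.g. anoxia: no
  electron acceptor regenerates mitochondrial NAD⁺) produces a one-row
  degenerate table with a warning instead of ten identical rows.
* **Amino-acid relaxation.** Uptakes are raised for an explicitly
  configured id list; a name-matching heuristic against the 20
  proteinogenic amino acids exists as a fallback and always logs what it
  matched, since published models rarely share exchange naming schemes.

Monotonicity properties (objective non-increasing along both titrations,
relaxed-uptake conditions never scoring below their constrained
counterparts) follow from LP feasible-set nesting and are asserted as
invariants, not tuned.

## PCA of flux datasets

Rows are reactions ("individuals"), columns are conditions ("variables").
Reactions inactive in every condition (|v| ≤ 1e-9, i.e. solver-precision
zero) are dropped before analysis. Default preprocessing is centering plus
scaling to unit sample variance (correlation PCA); covariance PCA is
available via `standardize=False`. The decomposition is the SVD of the
preprocessed matrix: eigenvalues are squared singular values divided by
n−1 (they then sum to the number of conditions), scores are UΣ, and
variable loadings are computed directly as Pearson correlations between
each original column and each score vector, which keeps them meaningful
even for covariance PCA.

Numerical conventions, fixed for determinism:

* component signs are chosen so the largest-magnitude loading of each
  component is positive (SVD signs are arbitrary);
* components beyond the numerical rank (eigenvalue ≤ 1e-12 of the leading
  one) are dropped;
* the contribution of reaction i to component k is
  100·score²ᵢₖ / Σᵢ score²ᵢₖ, which sums to exactly 100% per component
  (the denominator equals (n−1)·eigenvalueₖ; normalizing by n·eigenvalueₖ
  instead would not sum to 100 under the n−1 eigenvalue convention);
* contribution tables are ranked by PC1 with reaction id as tiebreak.

Condition–condition Pearson correlations carry two-sided p-values from the
t-distribution on n−2 degrees of freedom, flagged at p < 0.001; constant
columns yield undefined correlations reported as missing with a warning.

## The synthetic network

The toy generator emulates the pathway backbone a hypoxia simulation
exercises — glucose uptake and transport, lumped glycolysis
(2 ATP + 2 NADH + 2 pyruvate per glucose), lactate dehydrogenase and
export, pyruvate transport, PDH, a lumped TCA cycle
(3 NADH + 1 FADH₂ + 1 ATP per acetyl-CoA), the malate–aspartate shuttle,
and a two-entry respiratory chain with P/O ratios 2.5 (NADH) and
1.5 (FADH₂), each entry consuming ½ O₂ — in three compartments
(extracellular, cytosol, mitochondrial matrix). Adenine nucleotides are
not tracked and mitochondrial ATP is pooled with cytosolic ATP (the
adenine translocase is assumed non-limiting), so the ATP demand — the
objective — is a genuine single-sided sink and counts among the five
boundary reactions. The minimal variant has 16 metabolites and
14 reactions.

Per pyruvate oxidized: 5 mitochondrial NADH (1 shuttle-imported + 1 PDH +
3 TCA) + 1 FADH₂ + 1 substrate-level ATP = 15 ATP and 3 O₂, giving the
closed form ATP(g, q) = 2g + 15·min(2g, q/3) and lactate export
2g − min(2g, q/3). The defaults g = 1, q = 6 describe a fully aerobic cell
(32 ATP per glucose, the textbook value at these P/O ratios). The
`succinate` variant splits the TCA lump before and after succinate and
adds a succinate exchange; partial oxidation yields 11 ATP per 2 O₂
versus 15 per 3 O₂ for full oxidation, so the LP exports succinate exactly
when oxygen rather than carbon is limiting — the toy analogue of hypoxic
succinate accumulation. Its piecewise optimum
(2g + 11q/2, then 8g + 4q, then 32g) is derived from the two active
constraints and cross-checked against an independent solver in the tests.
The succinate lump discards the 4-carbon skeleton after the FAD/NAD
oxidation step, so strict carbon accounting holds only in the minimal
variant.

What a green toy-model test does **not** establish: behaviour of genuinely
multi-fuel networks (fatty-acid β-oxidation, glutaminolysis, the pentose
phosphate pathway are absent), realistic PDH robustness (here *all*
oxidative ATP flows through PDH, so closing PDH collapses ATP to the
glycolytic floor, unlike curated models where alternative fuels keep the
decline within a few percent), or any published model's specific flux
values — reproducing those requires that model's SBML file as input.

The flux-dataset sampler solves the toy model across oxygen fractions with
degeneracy resolution on, then optionally applies multiplicative Gaussian
noise (default off; 5% in the examples, a typical flux-estimate scatter)
to nonzero fluxes under a caller-supplied seed; zero fluxes stay exactly
zero so the active-reaction filter is unaffected by noise.

## SBML I/O

Files are written as Level 3 Version 1 with the fbc-v2 package (shared
constant bound parameters, an active maximization objective), which
round-trips byte-identically through this module and loads in cobrapy.
Reading accepts Level 2 COBRA-style kinetic-law parameters
(`LOWER_BOUND`/`UPPER_BOUND`/`OBJECTIVE_COEFFICIENT`) as well as fbc;
missing bounds fall back to reversibility-based defaults ([−B, B] or
[0, B]) with a logged warning. Identifiers are case-sensitive and never
renamed; bounds are never rescaled.

## Known limitations

* Flux variability analysis, dynamic FBA, quadratic objectives and
  gene–protein–reaction rules are out of scope.
* Regulatory effects (e.g. kinase inhibition of PDH) can only be imposed
  through flux bounds; an ATP-maximizing LP by itself predicts no change
  from regulation that does not bind at the optimum.
* Plot rendering is out of scope: PCA and scan results are emitted as
  tables (CSV/DataFrames) and flux maps as Escher-compatible JSON.
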