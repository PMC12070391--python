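# Methods

## The diel construction

A genome-scale metabolic model is the pair (S, bounds) of a stoichiometric
matrix and flux bounds, solved at steady state S·v = 0. The diel
transformation rewrites a non-diel model M into a model with two complete
copies of M — a day phase and a night phase — coupled through a storage
pool, so that one LP spans a full light/dark cycle. The construction is
purely structural; each step is a pure function from model to model and
never deletes an entity, which makes the arithmetic exactly checkable:
after duplication every count is 2×, after pool creation a generic model
has gained 1 compartment, |S| metabolites and 2·|S| exchange reactions for
a storage set S.

Step order is fixed: duplicate → storage pool → night photon block →
nitrate ratio (optional) → biomass merge (optional). The pool must exist
before photons are blocked, otherwise the intermediate model would have no
night carbon source and the pipeline would pass through an infeasible
state; with this order the model stays feasible after every step (asserted
in the test suite on the toy fixture).

Key choices, all configurable:

* **Suffixing** applies to ids *and* display names (`Glucose_c` →
  `Glucose_c_Day`, `Glucose_c_Night`); ids stay unique, names stay
  readable. Re-running duplication on a diel model raises on the suffix
  collision rather than quadrupling.
* **Exchange reactions are duplicated like any other reaction**: both
  phases can exchange all nutrients; only photons (step 3) and the nitrate
  proportion (step 4) are constrained.
* **Storage-pool exchanges** are reversible with bounds ±1000
  mmol·gDW⁻¹·h⁻¹ (the conventional "unbounded" magnitude of published
  GEMs; configurable). Naming is deterministic: compartment `sp`
  (`sp_<tissue>` for multi-tissue), species `X_sp`, reactions
  `SP_X_Day`/`SP_X_Night`. Positive `SP_X_Day` flux deposits into the
  pool; positive `SP_X_Night` flux withdraws into the night phase; at
  steady state the two are equal, so their common sign is the net
  crossing direction.
* **Multi-tissue matching**: tissues are matched to storage metabolites by
  case-insensitive substring of the metabolite or compartment id; an
  explicit per-tissue list overrides matching. A tissue that matches
  nothing is an error, not a silent no-op.
* **The nitrate ratio is a coupling constraint**, q·v_day − p·v_night = 0
  for ratio p:q (default 3:2), not a pair of fixed bounds: the proportion
  is pinned while the absolute uptake remains free. Reactions must be
  oriented uptake-positive (upper bound > 0); export-oriented reactions
  are rejected with a message asking for re-orientation rather than
  silently flipped. The orientation check is bounds-based only — whether a
  species is "extracellular" is not decidable from opaque identifiers.
  SBML FBC has no native cross-reaction constraint, so these are
  serialized in a namespaced model-level annotation block and re-hydrated
  on read, keeping the diel model a single self-describing file.
* **Biomass merge weights** default to 0.5/0.5 — one unit of total biomass
  consumes half a unit of each phase's precursors (coefficient-wise
  weighted sum of the two phase stoichiometries). The split is exposed as
  `biomass_weights` (must sum to 1) because unequal splits are plausible
  for some tissues. The merged reaction operates directly on the phase
  precursors; no intermediate biomass pseudo-metabolites are introduced.
* **Photoperiod duration is not modelled**: maintenance-type reactions are
  duplicated unscaled. Scaling maintenance flux by phase length would be a
  natural sixth step and the config structure leaves room for it.

## Solving and validation quantities

FBA maximizes the configured objective with GLPK through COBRApy/optlang;
coupling constraints are attached to the solver problem so every solve and
every sampler run respects them. Parsimonious FBA (minimize Σ|v| at the
fixed optimum) is **on by default** for all reported quantities because
flux directions at a degenerate optimum are otherwise arbitrary. The
fixtures are additionally constructed so that reported directions are
forced by network structure (below), not by solver tie-breaking.

Quantum yield is v_RuBisCO / |v_photon| — mol CO₂ fixed per mol photons.
The denominator enters by magnitude so the quantity is independent of the
exchange sign convention; the sign of the carboxylation flux is preserved.
QY is a flux ratio, hence invariant under uniform scaling of all bounds
(property-tested). A photon flux below 10⁻⁶ makes QY undefined and raises.

All "equals zero" assertions use an absolute tolerance of 10⁻⁶, the
package's own choice for double-precision LP results; bounds and
mass-balance residuals of optimal solutions and of every sampled flux
vector are held to the same tolerance.

## Differential flux analysis

Sampling uses the artificial-centering hit-and-run sampler over the full
flux polytope (not at the fixed optimum), with configurable thinning
(default 100, i.e. every 100th step is kept; the sample count refers to
post-thinning samples) and a mandatory integer seed — no implicit global
RNG state anywhere, so the whole chain is bit-reproducible given (model,
n, seed, alpha, threshold).

Per (day, night) reaction pair the two sampled flux rows are compared with
a two-sided Mann–Whitney U test — rank-based and distribution-free, since
sampled flux marginals are bounded and often far from normal. A pair whose
two rows are completely tied is assigned p = 1 (no evidence of a shift);
Kolmogorov–Smirnov is available behind `method="ks"`. P-values are
Benjamini–Hochberg corrected across all pairs at α = 0.05. Calibration is
tested on synthetic null pairs: at 200 pairs × 100 samples the significant
fraction stays within 0.05 + 3·SE.

Pathway enrichment is the upper-tail hypergeometric probability
P(X ≥ k) with universe N = pathway-labelled reaction *pairs* (a pair's
label is its day copy's, inherited from the original reaction), K the
pathway's pair count, n the significant pairs, k the significant pairs in
the pathway. Unlabelled reactions are excluded from the universe.
Pathway labels are read from reaction notes (`SUBSYSTEM:` convention) or
from cobra-parsed group/subsystem annotations.

The PCA overlap metric projects the significant pairs' day and night
sample rows (rows = points, samples = features) onto the first two
principal components. Standard column (feature) centering is used and
**no variance scaling**: scaling each sample column to unit variance would
erase the flux-magnitude separation between a high-flux day copy and a
silent night copy, which is exactly what the metric measures. A pair
overlaps when its two points are within Euclidean distance 1 (default) in
(PC1, PC2); the overlap fraction is reported together with the two
explained-variance ratios.

## The synthetic plant GEM

The toy fixture emulates the structural features the pipeline consumes,
not biological realism: photon/CO₂/nitrate/phosphate uptake and water
export; a light reaction `8 photon → 2 NADPH + 3 ATP + Fd_red`; RuBisCO
carboxylation `CO₂ + 2 NADPH + 3 ATP → sugar + H₂O`; sucrose and starch
interconversion; ferredoxin-dependent amino-acid synthesis from nitrate;
respiration (`sugar → 4 ATP + CO₂`); an ATP maintenance drain with a
forced minimum of 0.1; a biomass drain (`sugar + 0.5 AA + 2 ATP +
0.1 Pi`); and pathway-labelled filler reactions spanning three pathways.
Defaults: 6 filler reactions, starch cycle on, QY target 0.125.

Three design points make the fixture's validation outcomes analytic:

* the light reaction's 2:3 NADPH:ATP output exactly matches fixation's
  demand and nothing else consumes NADPH, so every photon reaching the
  optimum funnels through fixation and QY = 1/(photons per fixation) —
  `qy_target` values whose reciprocal is not an integer are rejected;
* nitrogen assimilation needs reduced ferredoxin, available only from the
  light reaction (surplus is re-oxidized by a sink), so night amino-acid
  synthesis is impossible: night biomass must draw sugar and amino acids
  from the pool (day→night flows forced), and under the 3:2 ratio the
  night phase's obligatory nitrate uptake has no night consumer and must
  cross the pool to the day phase (night→day flow forced). Removing the
  ratio removes that flow;
* dead-end filler reactions sample identically zero in both phases,
  exercising the not-significant branch of the differential test.

The two-tissue variant duplicates the core per tissue (leaf photosynthetic,
root not: its photon uptake is bounded to zero), with sucrose/amino-acid
transport leaf→root and nitrate transport root→leaf, two photon uptakes,
two nitrate uptakes and two biomass reactions.

What the fixture does **not** emulate: realistic network size (tens of
reactions vs thousands), elementally balanced stoichiometry, gene rules at
scale, compartmental transport costs, or alternate pathways creating broad
degenerate optima. Passing tests therefore demonstrate correctness of the
construction and of the analysis chain, not predictive accuracy on any
real pGEM; full-scale behaviour (e.g. enrichment counts on a real
*Arabidopsis* model) depends on the input model's own annotations.

## Problem sizes used in tests and the acceptance script

Desk scale throughout, as the package's own test-design choice: the toy
GEM has 21 reactions (51 after the pipeline), ACHR sampling uses 100
samples at thinning 100 for reports (smaller thinning in unit tests),
differential-test calibration uses 200 null pairs × 100 samples, and the
hypergeometric implementation is verified against exact rational
arithmetic for all parameter tuples with universe ≤ 25 plus literal
subset enumeration for universes ≤ 9.

## Known limitations

* Linear objectives only; no dFBA, kinetics, or photoperiod scaling.
* SBML Level 3 + FBC v2 only (no Level 2, kinetic laws, or events).
* The coupling-constraint annotation is this package's schema; other
  tools will preserve but not interpret it.
* Reaction/metabolite identification (photon, nitrate, biomass, storage)
  is entirely user-supplied; there is deliberately no name-based
  auto-detection.
* ACHR mixing on very elongated polytopes may need larger thinning than
  the default for near-uniform coverage; the determinism contract is
  unaffected.
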