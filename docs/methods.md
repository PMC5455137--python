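# Methods

## Steady-state model and conventions

A metabolic network is a stoichiometric matrix *S* (metabolites ×
reactions) with flux bounds in mmol·gDW⁻¹·h⁻¹ (the biomass reaction in
h⁻¹). Exchange reactions touch exactly one metabolite; negative exchange
flux is uptake, positive is secretion, and user-facing "uptake" values
are magnitudes. Growth-associated maintenance (GAM, default 40 mmol
ATP·gDW⁻¹) is an ATP-hydrolysis term inside the biomass reaction;
non-growth maintenance (NGAM, default 5 mmol ATP·gDW⁻¹·h⁻¹) is a
separate reaction pinned to its rate in every culture condition. The
NGAM pin matters beyond realism: it anchors the flux scale, without
which the yield-per-flux objective below would be maximized by shrinking
all fluxes toward zero.

Culture conditions set substrate uptake bounds (fixed by default —
chemostat-style — or as upper magnitudes), may block product exchanges,
and may enable the acetate constraint (glycerol cultures only).

## Objectives

* `lp_biomass` — max *μ*. A linear program (HiGHS via
  `scipy.optimize.linprog`); the optimum is a vertex of the flux
  polytope. On networks able to vent electrons as H₂/formate this vertex
  uses the substrate almost purely as electron donor and makes no PDO.
* `yield_per_flux` — max *μ / Σ v²*. The denominator sums squared fluxes
  over all reactions by default (configurable set; whether exchanges
  belong in the sum is genuinely ambiguous, so the set is exposed as a
  parameter). Non-convex fractional program.
* `weighted` — max *μ / (w Σ v² + (1−w) v_ATP²)* with *w* strictly inside
  (0,1). *v_ATP* = Σ max(σ_j v_j, 0) over the model's designated
  ATP-producing reactions, σ_j orienting each toward ATP synthesis, so
  only thermodynamically productive direction counts. The *w* → 1 limit
  recovers `yield_per_flux`. The weight for glycerol-excess cultures is
  calibrated by grid search against experimental yields
  (`calibrate_weight`); ties in the error grid are broken toward the
  largest *w*, i.e. toward the least departure from optimal growth that
  the data cannot refute.

### Solving the fractional programs

Direct NLP (SLSQP) on the ratio, with the equality system row-reduced to
full rank first (stoichiometric matrices carry conserved-moiety
dependencies — NAD(H), adenylates, CoA — that make the raw system
rank-deficient and break the least-squares subproblems). The objective
is defined as 0 at *μ* = 0 and starts are nudged off the origin.
Multi-start is essential and has three ingredients:

1. the growth-rate LP vertex plus random convex mixtures of
   random-objective LP vertices (a cheap stand-in for hit-and-run);
2. LP vertices along the growth/ATP trade-off path (max *μ* under a cap
   on ATP production, 8 cap levels) — these reach the low-ATP basin that
   plain growth starts never find;
3. orthant enumeration: when the model has ≤ 3 reversible internal
   reactions, the solve is repeated under every sign restriction of
   them. The non-convexity of these ratios lives almost entirely in the
   directionality of reactions like the ferredoxin:NAD⁺ reductase, so
   enumerating those orthants turns a local method into a reliable
   global one at toy scale. Genome-scale models have more reversible
   reactions; there the multi-start is the only global device, matching
   the standing assumption that the best local optimum of this objective
   is the global one.

Tolerances: solver ftol 1e-8, steady-state residual ≤ 1e-5 accepted,
tol_zero = 1e-6 for "carries flux". All seeds are explicit arguments
with fixed defaults.

## Acetate secretion constraint

Acetate secretion in glycerol cultures is capped by a logistic function
of the uptake magnitude *u*: bound(u) = vmax / (1 + (vmax/v0 − 1)
e^(−rate·u)), v0 = 0.158, vmax = 11.5 mmol·gDW⁻¹·h⁻¹, rate = 0.0859
g·h·mmol⁻¹. Written in this overflow-safe form, the bound rises
monotonically from v0 at zero uptake toward vmax, matching the stated
initial and maximum values; the sign convention takes the uptake as a
magnitude with a positive rate. An alternative rate of 0.0879 circulates
in prose descriptions of the same fit; both are accepted via
`AcetateConstraintParams`, with 0.0859 the default. The constraint is
re-evaluated per grid point in robustness scans.

## FVA

After solving FBA, each target flux is min/maximized with the objective
constrained to ≥ 95% of its optimum (maximization case; relaxation
configurable). For the linear objective the subproblems are LPs; for the
fractional objectives the constraint *μ − 0.95 Z\*·denom(v) ≥ 0* is a
smooth quadratic handled by SLSQP directly, warm-started from the
incumbent flux, targets processed in sorted-id order. The incumbent is
always feasible, so returned intervals are tightened against it; ranges
widen monotonically with the relaxation. The relaxation is applied to
all objectives, linear included.

## ROOM

Mutant prediction minimizes Σ b_j (b binary; b_j = 1 iff reaction j
leaves the band v_wild ± (δ|v_wild| + ε), δ = 0.05, ε = 0.001) subject
to steady state and deletion bounds, as one MILP (HiGHS via
`scipy.optimize.milp`). Big-M constants come per reaction from the bound
differences, exactly the band-vs-bound gap. Enzyme deletions close a
reaction only when every annotated isozyme is deleted. Degenerate
optima (equal Σb) are resolved by the solver's incumbent; the count, not
the flux vector, is the invariant quantity. Mutant feasible ranges
(`mutant_fva`) hold the in-band reactions inside their (slightly
relaxed) wild bands and scan the targets — one defensible reading of
"mutant FVA", recorded as an interpretation since the band-constrained
mutant space admits others.

Screens default their candidate set to enzymes directionally coupled to
growth: deleting fully/partially coupled enzymes necessarily costs
growth, and blocked or uncoupled enzymes cannot change the phenotype.
Double deletions exclude single-essential enzymes. The wild-type FVA
maximum of the PDO yield bounds what any *growth-preserving* mutant can
reach; mutants that sacrifice growth (hydrogenase deletions) can exceed
it and are outside that bound's qualifier.

## Blocked detection and coupling

A metabolite is blocked when its maximal net production — tested with a
temporary sink, one LP per metabolite — is ≤ 1e-6 under declared bounds.
This producibility test deliberately equals the classical binary-MILP
result set while staying deterministic; note a consumer-less dead-end
metabolite is *producible* once the sink exists, and is exposed instead
by the reaction-level scan (FVA interval [0,0]). Conserved cofactor
pools without synthesis routes (NAD, CoA in the toy network) are
correctly reported blocked: they can cycle but never carry net
production.

Coupling ratios |v_j|/v_target are computed exactly by the
Charnes–Cooper substitution (y = t·v, t ≥ 0, y_target = 1; two LPs per
reaction). Classes: full (ratio a nonzero constant), partial (Rmin > 0;
this includes Rmax = ∞, since the enzyme is still active whenever the
target runs), directional (Rmin = 0 but the reaction cannot run while
the target is silent — the convention that nonzero v_j implies nonzero
v_target), uncoupled, blocked. Reversible reactions are classified on
|v_j| because expression prediction cares about activity, not direction.
Enzymes take the strongest class over their reactions and are blocked
only if all their reactions are.

## Omics consistency

Expressed-enzyme lists (EC numbers, de-duplicated; dashed ECs match by
prefix) are compared qualitatively with a solved flux state: an enzyme
is predicted iff any catalyzed reaction carries |v| > 1e-6. Enzymes
blocked at the network level are excluded — their silence is structure,
not condition. The prediction rate is predicted / (shared − blocked).
Fully/partially coupled enzymes are predicted whenever growth is
positive (a structural theorem the tests assert), so non-predicted
enzymes always fall in the directional/uncoupled classes.

## Perturbation and co-fermentation screens

Biomass-composition perturbation draws each precursor coefficient
multiplier from Normal(1, rsd) (default rsd = 0.30), *excluding* (not
redrawing) samples with any non-positive draw, so the retained count is
an observable checked against the closed-form normal-tail expectation
1 − Φ(1/rsd)^k. After perturbing, the whole precursor set is rescaled to
keep Σ coeff·M_w = 1 g/gDW — renormalization must span all precursors,
not only the perturbed ones, or a uniform perturbation would cancel
exactly and yields would be incomparable across samples. Pearson
correlations are computed between multipliers (dimensionless) and
yields; constant yields give NaN, and only correlations above ~3/√n are
sign-stable across seeds — weaker ones are sampling noise.

Co-fermentation maps the FVA maximum of PDO secretion ÷ glycerol uptake
over a glucose × glycerol uptake grid (`spec=None` scans the whole
feasible space without an optimality constraint). The minimal
glucose/glycerol uptake ratio achieving complete conversion
(Y_PDO ≥ 1 − tol) is found by bisection to 3 decimals. On a minimal
redox-courier network the ratio equals the hand-computed electron
balance (1/2 when glucose yields 2 NADH and each glycerol needs 1); on
the toy network ATP bookkeeping shifts it to ≈ 0.29.

## Loop detection

A flux state is certified loopless when no sign-compatible circulation
exists over its active internal reactions: one LP maximizes the total
circulation; if positive, its support is decomposed into simple cycles
on the directed metabolite graph, and each candidate cycle is certified
by a second LP before being reported. The circulation test is what
prevents false positives from cofactor couplings (NAD/NADH "cycles" that
are not closed in the full stoichiometry).

## The synthetic network

`toy_glycerol_model` is an ~18-internal-reaction anaerobic network with
textbook integer stoichiometry: a lumped oxidative trunk (glycerol →
pyruvate, 2 NADH + 1 ATP), pyruvate:ferredoxin oxidoreductase,
pyruvate-formate lyase, hydrogenase, a reversible ferredoxin:NAD⁺
reductase, acetate/butyrate/lactate/ethanol branches, the reductive
glycerol → 3-HPA → PDO route, three lumped biomass precursor pools
(carbon skeletons, nitrogen compounds via alanine-like chemistry,
lipids from acetyl-CoA) summing to 1 g/gDW, GAM/NGAM, and a closed
glucose route for co-fermentation. Every internal reaction is atom- and
charge-balanced with real formulas (cofactors carry their actual
elemental compositions). Branches toggle via `ToySpec`; the default
glycerol uptake of 10 mmol·gDW⁻¹·h⁻¹ stands in for limitation and 30
for excess, bracketing the range where anaerobic glycerol fermenters
are typically characterized.

What the toy reproduces: the three qualitative regimes (LP → no PDO;
yield-per-flux → PDO > 0; ATP-penalized → ferredoxin-reductase reversal
and lower α_H2/Fd), exact balance checking, coupling structure with all
five classes reachable, and screens at tractable size. What it does not:
genome-scale numerics (hundreds of reactions, alternate optima at
scale, realistic biomass with ~50 precursors), quantitative yields of
any real strain, or pH/thermodynamic effects. Tests passing on the toy
certify the algorithms and their oracles, not quantitative predictions
for real fermentations.

`random_model` generates connected 1:1-conversion networks (uniform
formula C, so balance is structural) with a guaranteed
exchange-to-exchange backbone, used for round-trip and oracle-
equivalence testing; `synthetic_expression` derives expression lists
from a flux state with configurable false-positive/negative rates.

## I/O

SBML Level 3 with FBC bounds (python-libsbml), tolerating legacy files
whose bounds live in kinetic-law parameters; package metadata (GAM/NGAM,
designated reactions, EC annotations) rides in SBML notes as JSON.
Real-valued formulas (biomass precursors) are carried in species notes
since FBC chemical formulas are integer-only. The tabular format is two
TSV blocks (reactions with equation strings, metabolites) under a JSON
header line — diff-able fixtures. Round trips are field-exact in both
formats. FluxState serializes to JSON.

## Problem sizes

Everything in the test suite and analysis scripts runs on the toy
network (31 reactions) or smaller: grid oracles on ≤ 3 free dimensions,
ROOM enumeration on ≤ 12 reactions, perturbation screens at n = 2,000
draws (sampling) and n ≈ 250 × 5 seeds (solving), chosen so the full
suite completes in a few minutes on one CPU while still exercising every
code path against an independent oracle.

## Known limitations

* The fractional solves certify only the best local optimum beyond toy
  scale (orthant enumeration caps at 3 reversible internal reactions).
* ROOM reports one optimal b-pattern among possibly many; only Σb is
  stable.
* Mutant FVA is an interpretation (see above).
* The blocked-metabolite producibility test and dead-end semantics
  differ deliberately (documented above).
* Coupling classification treats |v|; a reaction whose forward and
  backward directions couple differently is summarized by its activity,
  not per-direction.
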