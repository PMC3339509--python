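# Methods

## Model and constraint-based core

The package works on the standard constraint-based representation of
metabolism: a stoichiometric matrix `S` (m metabolites × n reactions), the
steady-state constraint `S·v = 0`, and box constraints `α ≤ v ≤ β` on the
flux vector. Only linear objectives are supported. Exchange reactions are
single-metabolite boundary reactions; with the canonical coefficient −1,
negative flux is uptake and positive flux is secretion. Reversible reactions
without explicit bounds default to ±1000 flux units, irreversible ones to
[0, 1000] — the conventional "effectively unbounded" magnitude; every
magnitude-dependent result in the package is property-checked rather than
value-matched, so this choice affects scale, not structure.

All LPs go through one internal wrapper around `scipy.optimize.linprog`
(HiGHS, primal feasibility tolerance 1e-9 requested). Optimal solutions are
re-verified in the wrapper: a steady-state residual above 1e-6 raises rather
than returning a silently wrong answer, and a solver status outside
{optimal, infeasible, unbounded} raises a `SolverError`. The wrapper exposes
a hook interface used by the test suite to assert `‖S·v‖∞ ≤ 1e-6` and bound
satisfaction (±1e-6) on every optimal solution produced anywhere.

FVA runs a zero-objective feasibility LP first so an empty polytope is
diagnosed once, with a clear message, before any per-reaction LP runs.

## Flux spans and their comparison

Per condition, a reaction's Flux Span is the width of its FVA interval
(tiny numerical negatives clipped to 0). Between two conditions the Flux
Span Ratio is computed reaction-wise, numerator = control-side condition,
denominator = patient-side condition; the orientation is recorded in the
result rather than inferred. Denominator spans at or below an epsilon are
not divided: such entries are flagged "undefined" (numerator nonzero) or
"both-zero" (both spans numerically zero).

Classification thresholds: ratios ≥ 1+δ_strong are "increased", ≤ 1/(1+δ_strong)
"decreased", within [1/(1+δ_weak), 1+δ_weak] "unchanged", otherwise
"intermediate"; defaults δ_weak = 0.1, δ_strong = 0.5, both configurable and
echoed in every report. No published cutoffs exist for the qualitative
increased/decreased/intermediate distinction, so the defaults are simply
reproducible choices that the report makes explicit. "Both-zero" pairs
classify as "unchanged": two equal (zero) spans are no change; only a
zero-span denominator with a nonzero numerator is "undefined". This keeps
the self-comparison identity exact — comparing any condition against itself
yields ratio 1 or both-zero everywhere, hence "unchanged" everywhere.

Epsilon defaults: 1e-9 (below LP tolerance) for direct span-ratio use, but
1e-4 inside the full pipeline. The pipeline fixes each optimized
pseudo-objective with an absolute slack of 1e-6 (an exact equality fix is
numerically brittle), and that slack leaks residual spans of order
slack × coefficient ≈ 1e-5 into structurally pinned reactions; 1e-4 sits
above the leakage and orders of magnitude below any real span.

## From profiles to conditions

**Envelope separation.** With two measurements in one group and a handful in
the other, distributional tests are meaningless; the rule used is purely
order-based: a metabolite belongs to the patient-elevated set when the
patient group's minimum strictly exceeds the reference group's maximum, and
conversely for the depressed set. Ties break toward exclusion (strict
inequalities), and which group is "patient-side" is an explicit argument.
A caveat the package's own simulations quantify: with ~30 metabolites and
(10 vs 2) draws, exchangeability alone produces a false separation with
probability 2/C(12,2) ≈ 0.03 per metabolite — about one spurious metabolite
per study and roughly a 50% chance of at least one. Envelope sets from small
cohorts should be read as hypotheses, not detections.

**Clustering and PCA.** Two-way hierarchical clustering uses unweighted
average linkage (UPGMA) on raw concentrations; the default distance is the
infinity norm, with 1- and 2-norms available (group separations should be —
and in the synthetic studies are — largely norm-insensitive). No
normalization is applied by default; a z-scored matrix is available
explicitly (`ProfileTable.zscored`). Merge order is deterministic for a
fixed input ordering. PCA uses mean-centering only (matching the
no-normalization default) with a deterministic sign convention (each
component's largest-magnitude loading is positive).

**Media and the open set.** A media specification lists limited uptakes
(lower bound −magnitude, default 10 flux units each) and freely exchanged
species (±default bound); all other exchanges are closed to uptake with
secretion left open. The packaged rich-media preset permits uptake of the
20 proteinogenic amino acids, glucose, palmitate and oxygen, with protons
and water free. Under that state, every reaction's bounds are replaced by
its FVA interval — the "open set" bounding box, which is idempotent by
construction and knocks out unreachable reactions.

**Pseudo-objectives.** Each condition is represented by a single drain
pseudo-reaction consuming `scale × wᵢ` of each profile metabolite per unit
flux, where `wᵢ` is the metabolite's secretion (exchange) maximum under the
open set — measured through a temporary drain when a metabolite lacks an
exchange. This mirrors a non-growth-associated biomass objective: the
profile dictates relative demands, the network decides feasibility. When
the maxima cannot be met simultaneously the scale is lowered: the
patient-side default is 0.5 and the control-side 1.0, and an "auto" policy
finds the largest feasible scale by bisection on the feasibility LP (the
supply/demand toy in the tests — 20 units demanded per unit flux against a
10-unit inlet — has the closed-form answer 1/2 and the bisection returns it
to within 1e-6). Raw (unnormalized) maxima are used as coefficients.

**Comparison.** Both condition models derive from the same open-set base;
the two drains never coexist, so no cross-condition leakage is possible.
Each condition is optimized for its drain, the drain is fixed at
`fraction × optimum` (fraction 1.0 by default) ± the fixing slack, FVA runs
over the shared base reactions, and spans, ratios and classes are bundled
with full provenance (scales, optima, config echo). The procedure is
deterministic given the configuration.

## The synthetic cohort generator

`simulate_profiles` emulates the structure of a small fasting plasma NMR
study: 5 control subjects × 2 fasting draws, one patient with 2
pre-treatment draws, optionally one control-like post-treatment draw and one
non-fasting draw. The panel is the standard 30-metabolite plasma set; the
baseline concentration and CV tables are synthetic — round, plausible
fasting-adult magnitudes (glucose 5 mM with 5% CV, ketone bodies small but
highly variable, amino acids 0.03–0.6 mM at 10–15% CV), not measurements.

Noise is lognormal multiplicative per cell, mean-preserving
(`μ·exp(N(−σ²/2, σ))`, σ² = ln(1+CV²)), with draws independent across
samples and metabolites. The patient effect (default 5 baseline SDs, added
after the noise so it does not inflate the patient's own draw-to-draw
variance) raises the elevated set and lowers the depressed set; values are
floored at 1% of baseline to stay positive. The non-fasting draw deviates by
3 SDs against the fasting trend on the whole panel (ketone-like metabolites
down, everything else up) — a caricature of the fed state sufficient for
clustering behavior, not a model of feeding physiology.

What the generator deliberately does *not* model, and the consequences:

* **Within-individual correlation.** Real replicate draws from one person
  correlate strongly; here all draws are independent. Under the infinity
  norm on raw concentrations this matters: between any two independent
  draws the largest coordinate difference is usually glucose or lactate
  noise (~0.3 mM), which competes with the planted patient shift (~0.9 mM
  on 3-hydroxybutyrate). The planted clustering topology (patient pair
  coheres first, non-fasting draw joins last) therefore holds in most but
  not all seeds (~80–90% measured); with correlated within-person draws it
  would be near-certain, but correlation would also raise the envelope
  rule's false-separation rate well above its iid floor — one generator
  cannot have both, and the iid choice matches the stated noise model and
  keeps the false-positive floor honest.
* **Multiplicity of the envelope rule.** Exact recovery of the planted
  high/low sets requires zero false separations across the 21 non-planted
  metabolites; under exchangeability that caps the exact-recovery rate near
  (1 − 2/66)²¹ ≈ 52% regardless of effect size or noise scale. The planted
  sets themselves are recovered essentially always; the in-practice failure
  mode is one extra chance metabolite. Tests on real data should expect the
  same.

`make_toy_network` produces chain / branch / diamond networks with
hand-solvable FVA and seeded random networks built around a guaranteed
inlet-to-drain chain (feasibility is verified by LP, with rejection
sampling). `make_condition_pair` builds the planted differential network
described in the README; its ground truth is verifiable by direct FVA
without the pipeline, and the planted classes are recovered in 100% of
tested seeds.

## Problem sizes and numerical choices

Everything ships as generated, seed-reproducible data: random-network oracle
checks use 50 networks of ≤ 8 reactions; cohort statistics use 100 simulated
studies; pipeline recovery uses 20 condition pairs — sizes at which every
quantity is recomputed from scratch in seconds. Oracle agreement is asserted
at 1e-6 against a differently formulated LP (null-space parameterization
with pure inequality rows), deliberately sharing no code path with the
production FVA; a second cross-check against an established COBRA
implementation runs on the toy networks. Bisection tolerances default to
1e-7 for the feasible-scale search. Degenerate inputs fail loudly: empty
coefficient maps, non-exchange media ids, overlapping sample groups,
all-zero matrix columns and malformed formulas all raise typed errors, and
unparseable metabolite formulas downgrade a balance verdict to "unknown"
rather than crashing.

## Known limitations

* No loopless FVA or thermodynamic constraints; span ratios inherit FVA's
  known tolerance of thermodynamically infeasible cycles.
* Media magnitudes are qualitative knobs; absolute plasma concentrations are
  never mapped onto flux bounds.
* The increased/decreased/intermediate cutoffs are conventions, not
  estimates; reports echo them so downstream users can re-threshold.
* The envelope rule's false-positive behavior at small n (above) is a
  property of the method, not of this implementation.
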