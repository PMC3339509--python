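# fluxspan

Differential flux analysis of constraint-based metabolic models driven by
plasma metabolomic profiles.

## The problem

When a patient's plasma metabolite panel differs qualitatively from healthy
controls but there are too few replicates for conventional statistics, the
differences can still be interpreted mechanistically: the blood exchanges
metabolites with every organ, so a shift in the plasma profile reflects a
shift in whole-body net uptake and secretion. `fluxspan` turns such a shift
into two condition-specific constraint sets on a genome-scale metabolic
network and asks which reactions gain or lose flux capability between the two
conditions. It is written for systems-biology and clinical-research users who
have (1) a stoichiometric model (SBML or a plain matrix file) and (2) a small
sample-by-metabolite concentration table with group labels.

## The method

A metabolic steady state is a flux vector `v` satisfying

```
S · v = 0,     α ≤ v ≤ β
```

with `S` the m×n stoichiometric matrix and `α`, `β` the flux bounds. Flux
Balance Analysis (FBA) optimizes a linear objective `max/min cᵀ·v` over that
polytope; Flux Variability Analysis (FVA) maximizes and minimizes *every*
reaction, giving a bounding box on the feasible states. From FVA the package
computes, per reaction and condition,

* **Flux Span** = `max_flux − min_flux`, and between two conditions
* **Flux Span Ratio** = `span(condition A) / span(condition B)`,

the comparison statistic: reactions are classified increased / decreased /
intermediate / unchanged by how far the ratio departs from 1.

The two conditions come from the metabolomics side:

1. **Envelope separation** — a metabolite separates patient from controls
   when one group's maximum concentration lies strictly below the other
   group's minimum; this yields a patient-elevated ("ketone-like") set and a
   patient-depressed ("amino-acid-like") set. Two-way UPGMA clustering
   (infinity-norm distance) and PCA provide the supporting sample-structure
   views.
2. **Pseudo-objectives** — under a rich-media uptake set, bounds are replaced
   by their FVA box (the "open set"); each separating metabolite's secretion
   maximum becomes the stoichiometric coefficient of a condition-specific
   drain pseudo-reaction (analogous to a non-growth-associated biomass
   objective). An over-demanding drain is rescued by down-scaling its
   coefficients — one half by default for the patient-side objective, or the
   largest feasible scale found by bisection.
3. **Optimize–fix–FVA** — each condition model is optimized for its drain,
   the drain flux is fixed at the optimum, FVA is rerun, and span ratios are
   reported with the control condition in the numerator: a "decreased" ratio
   means a larger flux span in the patient condition.

All linear programs are solved with HiGHS via `scipy.optimize.linprog`.

## Worked example

`examples/03_condition_comparison.py` runs the whole chain on a small network
with a planted differential branch: one limited inlet feeding a ketone-like
product `K` (two parallel routes RK1/RK2) and an amino-acid-like product `M`
(routes RM1/RM2), each secreted by an exchange:

```
network: 9 reactions, inlet capacity 14
patient-side coefficients (ketone-like): {'K': 14.0}
control-side coefficients (amino-like):  {'M': 14.0}

scales used: {'patient': 0.5, 'non_patient': 1.0}  optima: {'patient': 2.0, 'non_patient': 1.0}
reaction      ratio        class
EX_A      both-zero    unchanged
RK1           0.000    decreased
RK2           0.000    decreased
EX_K      both-zero    unchanged
RM1       undefined    undefined
RM2       undefined    undefined
EX_M      both-zero    unchanged
RW        both-zero    unchanged
EX_W      both-zero    unchanged
```

Reading the numbers: the patient drain consumes `0.5 × 14` units of K per
unit flux, so its optimum is 2.0 and fixing it commits the whole inlet to the
ketone branch — but only the *sum* RK1+RK2 is pinned, so each route keeps a
span of 14 in the patient condition while being pinned to ~0 in the control
condition. Their span ratio (control/patient) is ≈ 0, hence "decreased" —
exactly the planted truth. The amino routes are pinned only in the control
condition (zero-span denominator → "undefined"), and everything pinned in
both conditions is "unchanged".

The other examples cover hand-solvable FVA (`01`), envelope separation and
clustering on the synthetic cohort (`02`), and balance checking plus
TSV/SBML round trips (`04`). A thin CLI wraps the same entry points:
`fluxspan simulate | cluster | separate | compare | balance`.

## Layout

```
src/fluxspan/
  model.py      stoichiometric containers, TSV/SBML I/O, balance checking
  flux.py       FBA, FVA, flux spans, span ratios, classification
  profiles.py   concentration tables, envelope separation, UPGMA, PCA
  pipeline.py   media, open-set bounds, pseudo-objectives, comparison
  synthetic.py  toy networks, synthetic cohort, planted condition pairs
  panels.py     the 30-metabolite plasma panel and group presets
  cli.py        thin command-line wrappers
```
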