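# Methods

## Model and assumptions

`nadflux` operates on ordinary constraint-based models: a stoichiometric
matrix `S`, flux bounds, gene–protein–reaction (GPR) rules, pathway
(subsystem) labels, and a linear objective (typically ATP demand), read and
written as SBML Level 3 + FBC through cobrapy. Two assumptions are load-
bearing:

1. **Steady state with a conserved cofactor moiety.** NAD⁺/NADH (and
   NADP⁺/NADPH) appear in reactions only as interconversions; the total
   pool size never enters `S·v = 0`. Concentration effects therefore cannot
   emerge from stoichiometry and must be imposed on the bounds.
2. **Michaelis–Menten occupancy limits attainable flux.** A reaction's
   maximal rate scales with `C/(Km + C)` in the free cofactor concentration
   `C`. We do not model full enzyme kinetics — only this saturating factor,
   normalized so the reference state is untouched.

## Bound scaling

For each cofactor-dependent reaction with a curated `Km`, FVA at
`fva_fraction` of the optimum yields `[v_, v̄]`, and both ends are
multiplied by

```
f = s · C/(Km + C),   s = (Km + C0)/C0
```

`f = 1` exactly at `C = C0` (the identity is algebraic, not numeric, and is
tested to 1e-12). `f` is strictly increasing in `C`; under depletion a
smaller `Km` gives a larger `f`, i.e. a weaker constraint, which is why
`Km` selection takes the *minimum* within the best-available organism
(priority human > pig > cow > rat > mouse) — conservatism with respect to
the predicted effect. Zero ranges stay zero: blocked reactions cannot be
revived by cofactor arithmetic.

Decisions taken where the design was genuinely open:

- **Scope of bound replacement.** Only cofactor reactions with a selected
  `Km` receive scaled-FVA bounds; everything else keeps its prior bounds.
  Tightening all reactions to FVA ranges would silently alter non-cofactor
  pathways; it remains available as `tighten_all=True`.
- **Multiple cofactor species / compartments in one reaction.** The
  effective factor is the minimum over all participating species with a
  `Km` (most-limiting-substrate rule); transporters spanning compartments
  inherit the more depleted compartment's factor.
- **NADP(H).** Treated identically to NAD(H) — one concentration table
  drives all four species, overridable by passing explicit cofactor id
  sets.
- **Extrapolation `C > C0`.** Gives `f > 1` (bounds relaxed beyond the FVA
  range); allowed and logged, with `cap_at_fva=True` to clamp at the FVA
  ceiling. Both behaviors are defensible; relaxation is the literal
  formula.
- **Unmapped cofactor reactions** keep their original bounds: absence of a
  `Km` is absence of evidence for a constraint.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `fva_fraction` | 0.5 | — | objective fraction during the FVA that defines scalable ranges. Low enough that FVA lower bounds rarely force flux by themselves, high enough that the ceilings reflect the objective. Exposed everywhere; results should be reported with the value used. |
| `pfba_fraction` | 1.0 | — | objective fraction fixed during parsimonious FBA of each scenario |
| `gimme_objective_fraction` | 0.8 | — | minimum objective retained by the context extraction |
| `activity_threshold` | median of the two cell lines' median reaction scores | score | below it, reactions are penalized in the GIMME LP |
| `C`, `C0`, `Km` | shipped example: reference c 0.11, m 0.23 mM; depleted c 0.066, m 0.023 mM | mM | all concentration-like quantities share units; the loader performs no unit conversion |
| `sigma_min` | 0.01 | flux | pathway filter is strict (`σ > 0.01`), the reaction table inclusive (`σ ≥ 0.01`) |
| `percent_change_cap` | 1000 | % | upper clamp; handles reference fluxes of zero. Decreases are never clamped (bounded at −100 %) |
| σ definition | population std | — | four scenarios make sample-vs-population material; configurable by post-processing the summary frame |

## Context extraction (GIMME)

Replicate abundance ratios are averaged per protein (missing replicates
skipped), optionally translated to model gene ids via a two-column map
(unmapped proteins dropped with a logged count), and aggregated through the
GPR tree with AND → min, OR → max; genes without data drop out of OR nodes
and are ignored in AND nodes that have a scored sibling. Reactions with no
GPR or no scored gene are *unscored* — a distinct state from a zero score.
The extraction LP minimizes `Σ (threshold − score)·|v|` over scored
below-threshold reactions (absolute values via auxiliary variables),
subject to the objective constraint; a below-threshold reaction survives if
it carries `|v| > 1e-6` in the penalty optimum, so round-off cannot
resurrect removed reactions. Unscored reactions are retained
unconditionally by default (`keep_unscored=False` switches to flux-based
pruning of them too). Ties are broken by model order and the GLPK backend
is deterministic, so identical inputs give identical submodels.

## LP layer

FBA, FVA, and pFBA are cobrapy/optlang calls behind small dataclass
contracts (`FluxResult`, `FluxRange`). Solver feasibility tolerance is
1e-9; test assertions compare at 1e-6. Infeasibility is a reported status,
not an exception, so scenario drivers can branch. pFBA at fraction 1.0
pins the objective at its optimum before minimizing total absolute flux.
The test suite cross-checks all three operations against independent
brute-force oracles (vertex enumeration over the flux polytope; a
scipy/HiGHS LP with explicit flux splitting for pFBA) on 100+ random
networks of ≤ 6 reactions.

## Synthetic fixtures: what they emulate, and what they do not

`make_toy_model` builds a 14-reaction, two-compartment network carrying the
redox architecture the method addresses: an NAD⁺-consuming glycolysis
proxy, a lactate branch and a malate–aspartate-style shuttle competing to
reoxidize cytosolic NADH, an NAD-coupled TCA proxy, an ETC proxy paying out
2.5 ATP per mitochondrial NADH, an ATP-demand objective, and two
low-expressed futile oxidases that the context extraction is supposed to
prune. NAD species are strictly interconverted, so steady state holds and
depletion acts only through the bound scaling. Fluxes are dimensionless;
the toy's concentration defaults are the shipped reference values, and the
generated Km table sets each canonical `Km` equal to the compartment's
reference concentration so the worked factors (0.75 cytosolic, ≈0.1818
mitochondrial) apply exactly. Decoy Km records (larger human duplicates,
smaller lower-priority-organism values) exercise the selection rules
without changing the selected value.

The proteomics generator emits triplicate lognormal abundance ratios. Gene
means are structured, not flat: overflow-route genes (lactate branch,
shuttle) at 3.0, core machinery at 2.0, futile decoys at 0.2, background
genes at 1.0. This matters because the median-of-medians threshold lands
inside the score distribution by construction; a flat proteome would put
every reaction on the knife edge and let replicate noise decide which core
reactions survive extraction. The "compensated" condition doubles the
overflow genes and halves the ETC gene, emulating the expression adaptation
of a chronically NAD-depleted line.

What the toy does **not** emulate: realistic proteome coverage (hundreds of
mapped proteins over thousands measured), genome-scale degeneracy of
alternate optima, real pathway annotations, or literature-spread Km values.
Passing the directional tests shows the machinery propagates concentration
changes with the right signs — not that predictions on a published model
are quantitatively correct; those require the user's own model, proteomics,
and curated Km inputs, for which the file formats are exercised end to end
in the tests.

## Problem sizes and numerical choices

Tests and the acceptance script run on the toy network (14 reactions), the
5-reaction diamond network with known exact LP values (optimum 10, branch
FVA ranges [2, 8], parsimonious total flux 32, context submodel of 4), 100
random ≤ 6-reaction networks for oracle equivalence, and 50 random branched
models for extraction properties — sizes chosen so every expected value is
hand- or oracle-checkable while still covering each code path. Degenerate
inputs are handled explicitly: empty GPRs are a no-GPR marker, absent Km or
concentration data are modeled states (never silent zeros), `[0,0]` FVA
ranges are preserved exactly, and bound pairs are re-ordered after negative
scaling factors cannot occur (factors are nonnegative by construction).

## Known limitations

- Occupancy scaling bounds *capacity*; it says nothing about thermodynamic
  driving force, which a depleted NADH/NAD⁺ ratio would also shift.
- FVA-derived bounds inherit the arbitrariness of `fva_fraction`; scaled
  lower bounds can force flux and, in extreme depletion, infeasibility —
  surfaced as an explicit scenario failure, not papered over.
- GIMME is the only extraction method offered; the scores it consumes are
  abundance ratios, not absolute abundances.
- Percent changes against a near-zero reference saturate at the cap and
  should be read qualitatively.
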