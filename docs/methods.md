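# Methods

## Scope and model of the problem

oncoflux treats oncometabolite emergence as two separable mechanisms on a
genome-scale metabolic network with gene–protein–reaction (GPR) rules:

1. **Loss of function.** An enzyme inactivated by truncating mutations
   closes its reactions; under steady-state mass balance the network must
   reroute flux around the lesion, and the metabolites at the junction are
   the candidate oncometabolites. Because a single flux vector is
   underdetermined, the unit of comparison is the *distribution* of
   feasible fluxes in the sub-optimal space (objective ≥ 90% of optimum),
   estimated by Markov-chain sampling of the cancer (enzyme-deficient)
   and matched normal models.
2. **Gain of function.** A missense-mutated enzyme may catalyse a
   reaction similar to its native one on a similar substrate. This is
   modelled chemically, not through flux: generic reaction operators
   applied to structural analogs of the native participants enumerate the
   plausible neomorphic activities, and reaction-fingerprint similarity
   to the native reaction ranks them.

Both arms assume steady state, a growth-like objective, and that binary
presence/absence of enzymes (not expression magnitude) determines network
context.

## Key parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| recurrence threshold | 0.05 | fraction of samples | screen for recurrently mutated genes; computed per arm on distinct samples |
| FIS cut | 1.9 | score | "medium impact" convention of conservation-based functional-impact scorers; aggregate = max over a gene's mutations |
| detection threshold | 10 | expression units | read-count-like detection floor for P/A calls |
| consensus fraction | 0.99 | fraction of samples | a gene is present only when detected in *more than* 99% of samples (strict inequality) |
| GIMME required fraction | 0.9 | of optimum | matches the sampling optimality bound |
| GIMME penalty | 1.0 per absent reaction | – | binary P/A calls carry no magnitude to weight by |
| objective weights a, b | 1, 1 | – | equal biomass and ATP-demand contribution in normal models, each term scaled by its maximum flux |
| sampling bound | 0.9 | of FBA optimum | sub-optimal but growth-relevant flux space |
| recorded points / thinning | 5000 / 100 | – | chain length giving a mixed fraction of ≈0.5 on the packaged network |
| flux-shift calling | p < 1e-3, fold ≥ 2 | – | calling rule for significant shifts; BH q ≤ 0.01 also reported |
| currency metabolites | ATP, ADP, NAD(H), H, H2O, CO2, O2, Pi, CoA | – | excluded from metabolite calls and neighbourhood construction |
| fingerprint | 1024 bits, ≤6 bonds, 2 bits/pattern | – | linear-path hashed fingerprint parameters |
| substrate candidate cutoff | TCdiss ≤ 0.6 | – | wide enough to admit close analogs (2-HG vs isocitrate ≈ 0.47) while rejecting unrelated chemotypes (≥ 0.79) |
| reaction cutoff | calibration + 0.05 | TCdiss | calibrated on the packaged isocitrate→α-KG vs α-KG→2-HG pair (≈ 0.64) |
| activity cap | 30,000 | reactions per native reaction | very large/complex substrates are excluded rather than enumerated |
| deletion categories | <0.90 essential; [0.90, 0.99) reduced; ≥0.99 no change | growth ratio | strictly-more-than-10% reading; a ratio of exactly 0.90 is *not* essential |

## The flux-shift statistic

For each retained reaction, with normalised samples $A$ and $B$:
$p_{XY} = \mathbb{E}_{x \in X} P_Y(|y - \mathrm{med}(Y)| \ge |x - \mathrm{med}(Y)|)$,
and $p = \min(1, p_{AB} + p_{BA})$, floored at $1/(n_A n_B)$. Properties
relied on by the pipeline, and enforced by tests: swap symmetry, $p = 1$
for identical samples, the floor for disjoint supports, and exact
agreement with a brute-force double-loop evaluation. The fold change is
the ratio of mean $|v|$ with a $10^{-9}$ pseudo-floor; direction is the
sign of that ratio relative to 1.

The estimator measures *location shift relative to spread*: a knockout is
only detected when the normal-model distribution is bounded away from the
deficient point mass. This is why the synthetic network gives its TCA
dehydrogenases finite Vmax-like capacities (upper bound 1.5) and carries a
substantial ATP maintenance demand — the energy balance then pins those
fluxes into a window well away from zero at 90% optimality, so closing one
enzyme produces a disjoint-support shift, which is the geometry the method
is designed to detect in real networks.

## Sampling and its diagnostics

ACHR (via cobrapy's sampler) uses warmup corner points from randomised
objectives, directions toward the running centre, and uniform steps on the
feasible chord; a single chain is recorded every `thinning` steps. The
**mixed fraction** splits the recorded chain in half, takes the
per-reaction median of the final half, and reports the fraction of
(point, reaction) pairs whose side of that median differs between the
paired halves; constant columns are excluded. Independent snapshots give
0.5, a frozen chain 0. The exact chain variant is recorded in the sample
set's JSON sidecar.

Reversible reactions are represented by split forward/reverse solver
variables; sampling is uniform over that lifted polytope. Marginals of
reactions with slack in both split variables are therefore not exactly
uniform over the net flux; the box-uniformity tests use irreversible
networks where the representation is one-to-one.

Loop reactions are found by flux variability with every exchange closed
and forced fluxes relaxed to include zero: any reaction with a nonzero
feasible range belongs to a thermodynamically infeasible internal cycle.
Filtering (zero-flux in both conditions, loops) precedes normalisation so
removed fluxes do not distort the denominators.

## Enzyme-deficient models

A deficient model is the context cancer model with the gene knocked out
through its GPRs. The verdict is *infeasible* when the deficient optimum
falls below the sampling fraction of the wild-type optimum — an essential
enzyme cannot be analysed at a 90% bound and is excluded with a report.
Feasible deficient models are sampled at the fraction of their own
optimum. Candidate metabolites come from the gene's reactions plus
reactions sharing a non-currency metabolite with them (one step by
default, configurable); predictions are compartment-tagged, and
planted-truth evaluation collapses to base metabolite species, since the
ground truth is a chemical species rather than a compartment instance.

## The GoF arm

Native participants are mapped to library structures; candidates are
library compounds within the substrate TCdiss cutoff of any non-currency
participant, excluding the query structure itself and configured
cofactors. The shipped operator library contains 12 curated irreversible
transformations (alcohol oxidation / carbonyl reduction, de/carboxylation,
de/hydration, reductive amination, phosphorylation, O-methylation, enoate
reduction/desaturation, alcohol amination) written as SMIRKS with level-3
EC tags and cofactor pairs; user libraries in the same TSV format are
accepted. Mass balance is checked on heavy atoms plus hydrogens after
explicit-H normalisation, using fixed cofactor compositions chosen so the
oxidised/reduced pair differs by exactly H2 (charge balance is not
checked). Products that fail valence sanitisation are discarded;
single-heavy-atom molecules are fingerprinted with their explicit-H bonds
so no real structure has an empty fingerprint.

Reaction fingerprints assign up to four compounds per side, each side
sorted by canonical SMILES — the 4+4 slot convention is this package's
choice. Dominant substructures use RDKit's maximum-common-substructure
search with a support threshold (the most common substructure present in
at least that fraction of compounds, exact bond-order matching), verified
afterwards by explicit substructure matching; "dominant" requires support
≥ 0.5 and ≥ 3 atoms.

## What the synthetic generators emulate — and what they do not

The toy network (29 reactions, 3 compartments) mirrors the canonical
lesions: glucose uptake, lumped glycolysis with an isoenzyme pair,
pyruvate branching (lactate overflow vs mitochondria), a TCA-like cycle
with anaplerosis, oxidative phosphorylation, ATP maintenance, a biomass
drain, a succinate overflow route, and a deliberate 3-reaction futile
cycle for the loop filter. Expression matrices have clean P/A separation
(absent genes at 1% of the detection threshold), mutation tables have
exact planted recurrence and class structure, and the compound library
has one close analog and clearly dissimilar decoys.

Real data differ in ways the generators deliberately do not model:
expression is noisy around the detection threshold rather than bimodal;
mutation recurrence is confounded by gene length and mutational
signatures; genome-scale networks have thousands of reactions, many
near-redundant routes, and much weaker knockout signatures; metabolite
libraries contain near-duplicates of every query. Passing the planted
recovery suite therefore demonstrates that the machinery is correct and
discriminating under its own assumptions, not that real-data hit lists
will be this clean.

Problem sizes used by the validation suite are the package's own
choices: recovery runs sample 1000 points at thinning 25 per model over
20 scenario seeds; the convergence diagnostic uses the full 5000 × 100
chain.

## Numerical choices

* LP feasibility tolerance 1e-9 (GLPK), reporting/audit tolerance 1e-6;
  "infinite" bounds encoded as ±1000.
* GPR grammar: case-insensitive and/or with parentheses for mixed
  operators; empty GPRs count as satisfied (spontaneous/exchange).
* GIMME's |v| is linearised with auxiliary variables t ≥ ±v; a penalised
  reaction is removed when its penalty-optimal flux is below 1e-6.
* Mixed-fraction sides use strict "greater than the median"; ties fall on
  the same side in both halves and do not count as mixing.
* Zero-flux reaction filter: |v| < 1e-9 in ≥ 99% of points in both
  conditions.
* The structure–expression correlation treats constant correlation rows
  (e.g. identical conditions) as a degenerate case reported with
  correlation 1 and a flag; significance permutes each condition's
  reaction-presence entries independently.
* Seeds: every generator and sampler stream is derived from the scenario
  seed with fixed offsets, kept below 2^31.

## Known limitations

* The sampler inherits cobrapy's ACHR: no loopless variant, and
  convergence is only assessed by the mixed fraction.
* The overlap p-value is insensitive to pure variance changes with equal
  medians, and its resolution is bounded by the floor 1/(n_A n_B).
* Mass balance ignores charge and protonation state.
* Hashed path fingerprints are not bit-compatible with other toolkits'
  fingerprints; only the metric properties (identity, symmetry,
  sim + diss = 1) are contractual.
* The transporter heuristic (same base species moved across compartments)
  misses transporters annotated with distinct species ids per
  compartment, and the base-id convention assumes `met_compartment`
  identifiers.
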