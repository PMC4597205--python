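# Methods

## Model class

`booldyn` operates on Boolean networks: each node *i* holds a binary state
(ON/OFF), updated by a logical transfer function *f_i* of its *k_i* distinct
regulators, written with AND/OR/NOT.  The ON state is read as activation of a
gene/protein or presence of a molecule or cell population.  Time is discrete
("steps").  Three propagation schemes are implemented:

- **synchronous** — all nodes apply *f_i* to the current state simultaneously;
- **general asynchronous (GA)** — one node, drawn uniformly at random from the
  non-clamped nodes, is updated per step.  This is the primary scheme: it makes
  no assumption about relative reaction timescales, and ensemble statistics
  over random update orders are biologically interpretable;
- **random-order asynchronous (ROA)** — each step applies every free node once
  in a fresh random permutation, each update seeing the partially updated
  state.

A *scenario* separates two kinds of interventions: **fixed** nodes are clamped
for the whole run (constitutive activation, knockout, drug inhibition) by
replacing their rules with constants, while **initial** nodes merely start in
a given state.  Remaining nodes start uniformly at random (each ON with
probability 0.5) or all-OFF, per the scenario's policy.

## Activation frequencies and stabilization

For an ensemble of *R* replicate GA trajectories, the activation frequency of
a node at step *t* is the exact fraction of replicates in which it is ON — a
qualitative proxy for the probability that the component is active in a cell
population.  Defaults mirror common practice for networks of this size:
R = 5,000 replicates, 2,000 steps, with stabilization judged on the final
500-step window at a band of epsilon = 0.01 (stable-ON when the window mean is
at least 1 − epsilon, stable-OFF when at most epsilon, oscillating otherwise;
a node whose two window halves differ by more than epsilon is flagged as not
yet converged).  These are configuration values, not constants; the packaged
61-node model relaxes in roughly 2,000–3,000 GA steps from random initial
conditions, so pipeline reports use 4,000 steps for scenario frequencies.

**Randomness.**  One master seed; replicate *r* draws its initial state and
its entire update-order sequence from its own child stream
(`SeedSequence.spawn`), so ensembles are reproducible bit-for-bit and
independent of replicate evaluation order.  Noise flips (below) and ROA
permutations are drawn from a separate spawned stream step-major; this keeps
memory bounded for long runs while preserving full reproducibility under
(seed, configuration).

**Noise.**  The robustness check flips every non-clamped node independently
with probability *p* after each update step and compares steady frequencies
with the noiseless run.  A lone self-maintaining node under flip noise is a
symmetric two-state Markov chain, giving the analytic check that its long-run
frequency is 1/2 regardless of the start.

## Network reduction

Exhaustive attractor analysis scales as 2^n, so models are reduced by three
dynamics-preserving operations iterated to a global fixed point:

1. **constant propagation** — rules are simplified under the standard Boolean
   identities (identity/annihilator absorption, double negation, idempotence,
   complement cancellation on identical literals); a rule that collapses to a
   constant stabilizes its node, the constant is substituted everywhere, and
   the process repeats.  Simplification is deliberately syntactic so the
   eliminated set is transparent; an optional exhaustive mode also evaluates
   each simplified rule on all 2^k_i regulator assignments, catching
   tautologies/contradictions the identities miss (cheap because k_i is
   small).
2. **mediator removal** — a node with exactly one regulator and one target
   (signed distinct pairs; self-loops disqualify) is spliced out by
   substituting its rule into its target, which preserves the target's truth
   table over the surviving variables and carries negation parity through the
   chain.  The scan runs in declaration order and restarts after each removal
   with degrees recomputed on the current model.
3. **dangling removal** — nodes with zero out-degree are deleted iteratively.

Output/readout nodes and scenario-clamped nodes are protected from phases 2–3
by default so reduced models keep their biological readouts.

**What is guaranteed.**  Under GA updating the reduced model's attractors
equal the full model's attractors projected onto the retained nodes; the
property suite verifies this exactly against a brute-force oracle on random
networks.  Under synchronous updating only fixed points are guaranteed:
synchronous cycles encode transmission delays, and splicing a mediator that
sits on a feedback loop (e.g. a two-node positive loop collapsing to a
self-loop) shortens the delay and can destroy an anti-phase cycle.  Property
testing surfaced exactly this counterexample, so the synchronous half of the
preservation suite asserts fixed-point preservation only.  The same effect is
visible in the packaged model, where the three-node JAK → STAT3 → SOCS
negative feedback ring is spliced down to a self-negating STAT3 node: GA
attractors project correctly, but synchronous cycle lengths change.

## Attractors, basins, phenotypes

The state space is enumerated as integers 0..2^n−1 (bit *b* = node *b*); each
node's rule is evaluated bit-vectorized over the whole space, and successor
arrays are materialized as flat edge lists (null updates omitted).  Attractors
are the terminal strongly connected components of this graph — SCCs with no
outgoing edge — computed with sparse SCC condensation, so state-space graphs
with millions of states never recurse or allocate per-state objects.  Because
null updates are omitted, a singleton terminal SCC is exactly a fixed point; a
terminal SCC in which every state has one outgoing transition is a simple
(limited) cycle; anything else is a complex attractor.  The enumeration cap is
2^24 states; larger models must be reduced first.

Basins are computed by exact backward reachability on the reversed graph.
Under GA, basins may overlap (a state can commit to different attractors
depending on update order), so both the total basin and the exclusive basin
(states that can reach only that attractor) are reported, as exact fractions
of the enumerated space; under synchronous updating basins partition the
space and the two coincide.  Basin fractions for a clamped/reduced model are
computed over the reduced state space — the free nodes — which is the
meaningful denominator once clamped and logically determined nodes are folded
away.

Each attractor carries a per-node **activation pattern**: the ON-fraction
across its states — full (1), inactive (0) or partial (oscillating).  Nodes
eliminated by reduction re-enter the pattern as full/inactive constants, so
readouts survive reduction.  The default **phenotype** decision table reads
the readouts of the packaged model: Apoptosis fully active ⇒ *apoptosis*;
otherwise Proliferation full/partial/inactive ⇒ *proliferation* / *limited
proliferation* / *resting*, with CYCLIND1/P21 as proxies when the
Proliferation node was reduced away (its reduced rule is `CYCLIND1 and not
P21`).  The table is an explicit function so other models can define their
own readouts.

The **node-fixing scan** clamps each candidate node to ON and OFF in turn,
recomputes the landscape (constant-folding first, so most clamps shrink the
space further), and reports surviving phenotypes and whether the landscape
collapsed to a single attractor — the operational definition of a core
regulatory node.

## Perturbation screens

A single-node screen derives its candidates from the baseline stabilization
structure: stabilized nodes are clamped once, to the opposite of their
attracting state; oscillating nodes are clamped twice (ON and OFF);
scenario-fixed nodes and the output nodes are never candidates.  Each clamp
is simulated with the same seeded configuration and scored against the
baseline output frequencies:

- *no effect*: both outputs move less than 0.1 (checked first, so clamping a
  node to its baseline value is inert even when the baseline is already
  proliferative);
- *pro-proliferative*: Proliferation at or above 0.9;
- *pro-apoptotic*: Apoptosis rises by at least 0.25;
- *anti-proliferative*: Proliferation falls by at least 0.25;
- *weak effect* otherwise.

All cut-offs are configurable (`ScreenThresholds`); only the 0.9
pro-proliferative bound is canonical, the others are documented defaults.
Double screens simulate pairs of clamps and mark a pair *not applicable* when
both of its outputs are within 0.02 of the more effective constituent single
perturbation — the combination adds nothing over the single hit.

## The synthetic flagship model

The packaged `cac_synthetic` network (61 nodes, 102 signed interactions) is a
**synthetic** colitis-associated colon cancer (CAC) style model: a stand-in
demonstration network assembled from textbook pathway logic, not a
transcription of any published curated model.  It couples an immune
microenvironment (DC, MAC, TREG, CTL, TH1, TH2 as clampable inputs; cytokines
IL6, TNFA, IL12, IL10, TGFB, IFNG, IL4) to an intestinal-epithelial-cell
interior: IL6/GP130/JAK/STAT3 with the SOCS negative feedback ring, TNF/IKK/
IKB/NF-kB, COX2/PGE2, the ERK MAPK cascade, PI3K/AKT/PTEN/GSK3B/mTOR, an
oxidative-stress-driven P53/MDM2 axis with P21 and CYCLIND1, the SPHK1/S1P
versus ceramide rheostat, and the mitochondrial apoptosis machinery
(PP2A, BCL2, BAX, tBID, MOMP, cytochrome c, IAP, caspases 8/9/3), with
`Proliferation* = CYCLIND1 and not P21` and `Apoptosis* = CASP3` as readouts.
P53 carries the standard self-stabilization idiom
(`(ATM or P53) and not MDM2`), making P53-committed states genuine attractors
rather than slaves of the upstream oscillation.

Design intent, in order: (i) every pipeline stage has non-trivial work on it
(the pro-tumour scenario stabilizes 24 nodes, leaves a 17-node/31-edge core
after mediator and dangling removal, and yields overlapping-basin GA
multistability); (ii) the canonical combination-therapy mechanism is
reproduced logically — ceramide alone is buffered because AKT, via mTOR,
keeps PP2A off and BCL2 on, whereas ceramide plus AKT blockade opens MOMP and
commits the cell to apoptosis; (iii) P53 loss converts the bistable
pro-tumour landscape into a single full-basin proliferation attractor, the
logical signature of malignant transformation.

What it does **not** emulate: transcriptional dose-response, real kinetic
timescales, stochastic molecular noise, cell-cell heterogeneity or any fitted
correspondence to measured activation frequencies.  Quantities computed on it
(e.g. Apoptosis stabilizing near 0.61 under the non-inflammatory scenario, or
the 93.75%/6.25% shared/exclusive basins under the pro-tumour scenario) are
properties of this synthetic network, and the regression tests freeze them as
such; passing them demonstrates the correctness of the machinery, not
agreement with any experimental system.

## Verification strategy and problem sizes

Every analytical path is cross-checked against an independent brute-force
oracle that shares no code with it: synchronous orbits are followed state by
state, GA transition graphs are materialized edge by edge with dictionary
evaluation and condensed with a general-purpose graph library, and basins are
re-derived by explicit reverse reachability.  The acceptance suite runs this
comparison over 200 random networks (4–10 nodes, both schemes, exact equality
of attractor sets, kinds, lengths and basin fractions), checks GA reduction
preservation on networks up to 12 nodes, parse/export round-trips, the GA
single-flip and clamp-conservation invariants, and the binomial behaviour of
a frozen node at 10,000 replicates.  Ensemble sizes in tests (hundreds of
replicates, 1,000–1,500 steps) and in `scripts/acceptance.py` (2,000
replicates, 4,000 steps for scenario frequencies) were chosen as the smallest
sizes at which the measured quantities' sampling error is well inside the
asserted tolerances.

## Known limitations

- Synchronous complex attractors are not invariant under mediator removal
  (see above); reduce with an empty protected set only if GA semantics are
  intended, or verify synchronous results on the unreduced model.
- The exhaustive attractor machinery is capped at 2^24 states and offers no
  symbolic (BDD) or sampling fallback; models that stay large after reduction
  are out of scope.
- Basin fractions of reduced models are relative to the reduced state space;
  they are not comparable across scenarios that stabilize different node
  sets.
- Perturbation screens equate a clamp with an idealized, complete and
  permanent intervention; partial inhibition has no representation.
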