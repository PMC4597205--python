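# booldyn

Boolean network dynamics for cell-signalling models: rule-file parsing,
multi-scheme simulation with ensemble activation frequencies,
dynamics-preserving network reduction, exhaustive attractor and
basin-of-attraction analysis, and systematic in-silico perturbation screens.

## Who this is for

Systems biologists who model signalling as logical networks — each node
(gene, protein, metabolite, or cell population) is ON or OFF and updates via
a Boolean transfer function *f_i* of its *k_i* regulators, e.g.

```
Proliferation* = CYCLIND1 and not P21
```

Such models answer qualitative questions kinetic models cannot reach without
parameters: which stable cell fates (attractors) a wiring diagram supports,
how large their basins are, and which node clamps — knockouts, constitutive
activations, drug inhibitions — reshape the fate landscape.

## What it computes

- **Simulation** (`booldyn.dynamics`): synchronous, general asynchronous
  (GA: one random node per step) and random-order asynchronous updating.
  Over an ensemble of replicate GA runs, the *activation frequency* of a node
  at step *t* — the fraction of runs with the node ON — approximates the
  probability that the component is active; stabilization is classified per
  node (stable-ON / stable-OFF / oscillating) over a trailing window, and a
  flip-noise mode checks robustness.
- **Reduction** (`booldyn.reduction`): constant propagation over the Boolean
  identities, splicing of single-in/single-out mediator nodes, and deletion
  of zero-out-degree nodes, iterated to a fixed point.  Under GA updating the
  reduced model's attractors provably project from the full model's (the test
  suite verifies this exactly against a brute-force oracle); under
  synchronous updating fixed points are preserved.
- **Attractors** (`booldyn.attractors`): the state space 0..2^n−1 is
  enumerated bit-vectorized; attractors are terminal strongly connected
  components of the state transition graph (fixed points, limited cycles,
  complex attractors), with exact total and exclusive basin fractions —
  under asynchronous updating basins overlap, so both matter.  Activation
  patterns (full / partial / inactive per node) map attractors to phenotype
  labels.
- **Perturbation screens** (`booldyn.perturbation`): single clamps derived
  from the baseline stabilization structure (opposite value for stabilized
  nodes, both values for oscillating ones) and double clamps, scored
  against baseline output frequencies as pro-proliferative /
  anti-proliferative / pro-apoptotic / no-effect.

A packaged **synthetic** colitis-associated colon cancer (CAC) style model
(61 nodes, 102 interactions; immune microenvironment driving IL6/STAT3,
NF-kB, COX2, ERK, PI3K/AKT, P53/MDM2, ceramide and mitochondrial-apoptosis
modules toward Proliferation/Apoptosis readouts) exercises every stage; see
`docs/methods.md` for its design and its limits.

## Worked example

Reduce the synthetic model under its pro-tumour scenario (dendritic cells
clamped ON, other immune cells OFF, APC ON) and enumerate the attractors of
the reduced core:

```
$ booldyn reduce --model cac_synthetic --scenario pro_tumor_dc \
      --out reduced.bool --trace rtrace.json
reduced to 17 nodes (31 stabilized, 11 mediators, 2 dangling)

$ booldyn report attractors
id  kind     length  basin_pct  exclusive_basin_pct  phenotype
1   complex  32      93.75      6.25                 proliferation
2   complex  4       93.75      6.25                 apoptosis
```

Reading: 31 of 61 nodes logically stabilize under the clamps (the ERK
cascade locks ON, the death machinery locks OFF), 11 mediators and 2 sinks
are spliced away, and the remaining 17-node core is bistable under GA
updating — a proliferative attractor and an apoptotic one, whose basins
overlap on 87.5% of the reduced state space (only 6.25% of states are
committed to each fate regardless of update order).

Clamping P53 OFF on top (`--scenario p53_off`) collapses the landscape to a
single full-basin proliferation attractor — the logical signature of
transformation — visible equally in simulation:

```
$ booldyn simulate --model cac_synthetic --scenario p53_off \
      --steps 2000 --replicates 1000 --seed 1 --out trace.tsv
step  Proliferation  Apoptosis  STAT3  NFKB
0     0.512          0.530      0.498  0.485
500   0.816          0.113      0.515  0.474
2000  1.000          0.000      0.511  0.471
```

Proliferation reaches activation frequency 1.0 while Apoptosis dies out;
STAT3 and NFKB hover near 0.5 because they oscillate inside the attractor.
The library API mirrors the CLI:

```python
import booldyn as bd
model = bd.load_model("cac_synthetic")
trace, atts = bd.attractor_landscape(model, bd.load_scenario("pro_tumor_dc"))
[(a.kind, a.length, a.phenotype) for a in atts]
# [('complex', 32, 'proliferation'), ('complex', 4, 'apoptosis')]
```

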