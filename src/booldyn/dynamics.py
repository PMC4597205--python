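"""State propagation and ensemble simulation.

Three update schemes are supported:

``synchronous``
    every node applies its transfer function to the current state at once;
``general_asynchronous`` (GA)
    one node, drawn uniformly at random from the non-clamped nodes, is
    updated per step — the stochastic scheme used for activation-frequency
    ensembles;
``random_order``  (ROA)
    each step applies every free node once in a fresh uniform random
    permutation, each update seeing the partially updated state.

The *activation frequency* of a node at step t over an ensemble of replicate
runs is the number of replicates in which the node is ON at t divided by the
replicate count — a qualitative proxy for the probability that the
corresponding biological component is active.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Callable

import numpy as np

from . import expr as E
from .model import BooleanModel, Scenario, apply_scenario

SCHEMES = ("synchronous", "general_asynchronous", "random_order")

#: ensemble defaults: 5,000 replicate runs of 2,000 single-node updates, with
#: stabilization judged on the final 500 steps at a 0.01 band
DEFAULT_REPLICATES = 5000
DEFAULT_STEPS = 2000
DEFAULT_WINDOW = 500
DEFAULT_EPSILON = 0.01


@dataclass(frozen=True)
class SimulationConfig:
    scheme: str = "general_asynchronous"
    steps: int = DEFAULT_STEPS
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    noise_flip_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.steps < 1 or self.replicates < 1:
            raise ValueError("steps and replicates must be >= 1")
        if not 0.0 <= self.noise_flip_probability < 1.0:
            raise ValueError("noise flip probability must be in [0, 1)")


@dataclass(frozen=True)
class EnsembleTrace:
    """Per-step per-node activation frequencies over an ensemble of runs.

    ``frequencies[t, j]`` is the exact fraction of replicates with node j ON
    at step t; row 0 records the initial states.
    """

    nodes: tuple[str, ...]
    frequencies: np.ndarray  # (steps + 1, n) float
    replicates: int
    config: SimulationConfig

    def node_trace(self, name: str) -> np.ndarray:
        return self.frequencies[:, self.nodes.index(name)]


@dataclass(frozen=True)
class StabilizationReport:
    """Classification of each node's long-run behaviour.

    ``status[n]`` is ``stable_on`` / ``stable_off`` / ``oscillating``;
    ``steady[n]`` is the mean activation frequency over the assessment
    window; ``drifting`` lists nodes whose window mean had not converged
    (first and second half of the window differ by more than epsilon).
    """

    status: dict[str, str]
    steady: dict[str, float]
    drifting: frozenset[str] = frozenset()

    def nodes_with(self, status: str) -> list[str]:
        return [n for n, s in self.status.items() if s == status]


# ---------------------------------------------------------------------------
# rule compilation

def compile_rule(rule: E.Expr, index: dict[str, int]) -> Callable[[np.ndarray], np.ndarray]:
    """Compile a rule into a vectorized function over a (replicates, n) bool
    state array, returning the next-state column."""
    if isinstance(rule, E.Var):
        i = index[rule.name]
        return lambda S: S[:, i]
    if isinstance(rule, E.Const):
        v = rule.value
        return lambda S: np.full(S.shape[0], v, dtype=bool)
    if isinstance(rule, E.Not):
        f = compile_rule(rule.child, index)
        return lambda S: ~f(S)
    if isinstance(rule, E.And):
        fs = [compile_rule(c, index) for c in rule.children]
        return lambda S: reduce(np.logical_and, (f(S) for f in fs))
    if isinstance(rule, E.Or):
        fs = [compile_rule(c, index) for c in rule.children]
        return lambda S: reduce(np.logical_or, (f(S) for f in fs))
    raise TypeError(type(rule))


def compiled_rules(model: BooleanModel) -> list[Callable[[np.ndarray], np.ndarray]]:
    index = {n: i for i, n in enumerate(model.nodes)}
    return [compile_rule(model.rules[n], index) for n in model.nodes]


def free_node_indices(model: BooleanModel) -> np.ndarray:
    """Indices of nodes not clamped by a scenario (the GA selection pool)."""
    return np.array([i for i, n in enumerate(model.nodes) if n not in model.clamped],
                    dtype=np.int64)


# ---------------------------------------------------------------------------
# single-trajectory stepping

def step(model: BooleanModel, state: np.ndarray, scheme: str,
         rng: np.random.Generator) -> np.ndarray:
    """Advance one state vector (length-n 0/1 array) by one step."""
    S = np.asarray(state, dtype=bool)[None, :].copy()
    fs = compiled_rules(model)
    free = free_node_indices(model)
    if scheme == "synchronous":
        nxt = np.stack([f(S)[0] for f in fs])
        return nxt.astype(np.int8)
    if scheme == "general_asynchronous":
        j = int(rng.choice(free))
        S[0, j] = fs[j](S)[0]
        return S[0].astype(np.int8)
    if scheme == "random_order":
        for j in rng.permutation(free):
            S[0, j] = fs[j](S)[0]
        return S[0].astype(np.int8)
    raise ValueError(f"unknown scheme {scheme!r}")


def state_to_index(state: np.ndarray) -> int:
    """Pack a 0/1 state vector into its integer index (bit b = node b)."""
    return int(sum(int(v) << b for b, v in enumerate(state)))


def index_to_state(idx: int, n: int) -> np.ndarray:
    return np.array([(idx >> b) & 1 for b in range(n)], dtype=np.int8)


# ---------------------------------------------------------------------------
# ensembles

def _initial_states(model: BooleanModel, scenario: Scenario,
                    child_rngs: list[np.random.Generator]) -> np.ndarray:
    """Per-replicate initial states honouring clamps, initial directives and
    the scenario's default-initial policy."""
    n, R = model.n, len(child_rngs)
    if scenario.default_initial == "all_off":
        S = np.zeros((R, n), dtype=bool)
    else:
        S = np.empty((R, n), dtype=bool)
        for r, rng in enumerate(child_rngs):
            S[r] = rng.random(n) < 0.5
    for name, value in scenario.initial.items():
        S[:, model.index(name)] = value
    for name, value in model.clamped.items():
        S[:, model.index(name)] = value
    # scenario.fixed covers models the caller has not clamped yet
    for name, value in scenario.fixed.items():
        S[:, model.index(name)] = value
    return S


def simulate_ensemble(model: BooleanModel, scenario: Scenario,
                      config: SimulationConfig) -> EnsembleTrace:
    """Run ``config.replicates`` independent trajectories and record exact
    activation frequencies at every step (step 0 = initial states).

    Each replicate draws its initial state and its GA update order from its
    own child stream spawned from the master seed, so the ensemble is
    reproducible bit-for-bit and independent of replicate evaluation order.
    Optional noise flips every non-clamped node with the configured
    probability after each update step.
    """
    m = apply_scenario(model, scenario)
    fs = compiled_rules(m)
    free = free_node_indices(m)
    if free.size == 0:
        raise ValueError("all nodes are clamped; nothing to simulate")
    n, R, T = m.n, config.replicates, config.steps

    root = np.random.SeedSequence(config.seed)
    replicate_seeds, aux_seed = root.spawn(2)
    child_rngs = [np.random.Generator(np.random.PCG64(s))
                  for s in replicate_seeds.spawn(R)]
    aux_rng = np.random.Generator(np.random.PCG64(aux_seed))

    S = _initial_states(m, scenario, child_rngs)
    freq = np.empty((T + 1, n), dtype=np.float64)
    freq[0] = S.mean(axis=0)

    if config.scheme == "general_asynchronous":
        sel = np.empty((R, T), dtype=np.int64)
        for r, rng in enumerate(child_rngs):
            sel[r] = free[rng.integers(0, free.size, size=T)]
    p = config.noise_flip_probability
    rows = np.arange(R)

    for t in range(1, T + 1):
        if config.scheme == "synchronous":
            S = np.stack([f(S) for f in fs], axis=1)
        elif config.scheme == "general_asynchronous":
            chosen = sel[:, t - 1]
            for j in np.unique(chosen):
                rr = rows[chosen == j]
                S[rr, j] = fs[j](S[rr])
        else:  # random_order: one fresh permutation per replicate per step
            keys = aux_rng.random((R, free.size))
            order = np.argsort(keys, axis=1)
            for k in range(free.size):
                jcol = free[order[:, k]]
                for j in np.unique(jcol):
                    rr = rows[jcol == j]
                    S[rr, j] = fs[j](S[rr])
        if p > 0.0:
            flips = aux_rng.random((R, free.size)) < p
            S[:, free] ^= flips
        freq[t] = S.mean(axis=0)

    return EnsembleTrace(nodes=m.nodes, frequencies=freq, replicates=R,
                         config=config)


def detect_stabilization(trace: EnsembleTrace, window: int = DEFAULT_WINDOW,
                         epsilon: float = DEFAULT_EPSILON) -> StabilizationReport:
    """Classify nodes from the mean frequency over the final ``window`` steps.

    A node is ``stable_on`` when that mean is >= 1 - epsilon, ``stable_off``
    when <= epsilon, and ``oscillating`` otherwise.  Nodes whose first- and
    second-half window means differ by more than epsilon are additionally
    reported as drifting (the ensemble had not settled)."""
    T = trace.frequencies.shape[0]
    if window > T:
        raise ValueError(f"window {window} exceeds trace length {T}")
    tail = trace.frequencies[T - window:]
    means = tail.mean(axis=0)
    half = window // 2
    drift = np.abs(tail[:half].mean(axis=0) - tail[half:].mean(axis=0))
    status, steady = {}, {}
    drifting = set()
    for j, name in enumerate(trace.nodes):
        mu = float(means[j])
        steady[name] = mu
        if mu >= 1.0 - epsilon:
            status[name] = "stable_on"
        elif mu <= epsilon:
            status[name] = "stable_off"
        else:
            status[name] = "oscillating"
        if drift[j] > epsilon:
            drifting.add(name)
    return StabilizationReport(status=status, steady=steady,
                               drifting=frozenset(drifting))


@dataclass(frozen=True)
class NoiseComparison:
    noiseless: StabilizationReport
    noisy: StabilizationReport
    delta: dict[str, float]  # per-node |change in steady frequency|


def noise_robustness(model: BooleanModel, scenario: Scenario,
                     config: SimulationConfig, flip_probability: float,
                     window: int = DEFAULT_WINDOW,
                     epsilon: float = DEFAULT_EPSILON) -> NoiseComparison:
    """Compare steady activation frequencies with and without update noise.

    Noise flips every non-clamped node independently with the given
    probability after each update step; a robust network shows small
    per-node changes in steady frequency."""
    if not 0.0 < flip_probability <= 0.1:
        raise ValueError("flip probability must be in (0, 0.1]")
    base_cfg = SimulationConfig(scheme=config.scheme, steps=config.steps,
                                replicates=config.replicates, seed=config.seed,
                                noise_flip_probability=0.0)
    noisy_cfg = SimulationConfig(scheme=config.scheme, steps=config.steps,
                                 replicates=config.replicates, seed=config.seed,
                                 noise_flip_probability=flip_probability)
    base = detect_stabilization(simulate_ensemble(model, scenario, base_cfg),
                                window, epsilon)
    noisy = detect_stabilization(simulate_ensemble(model, scenario, noisy_cfg),
                                 window, epsilon)
    delta = {n: abs(noisy.steady[n] - base.steady[n]) for n in base.steady}
    return NoiseComparison(noiseless=base, noisy=noisy, delta=delta)
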