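"""Exhaustive state-transition-graph and attractor analysis.

The state space of an n-node model is the 2^n integer indices whose bit b
holds node b's state.  Under synchronous updating every state has exactly one
successor; under general asynchronous (GA) updating it has one successor per
free node (null updates dropped).  An attractor is a terminal strongly
connected component (SCC) of this graph — an SCC with empty out-component: a
fixed point (single state, all updates null), a limited cycle (every member
has exactly one outgoing transition) or a complex attractor.

A state belongs to an attractor's *basin* when the attractor is reachable
from it; under GA updating basins may overlap, so both the total and the
exclusive (reachable-and-nothing-else) basin are computed, exactly, as
fractions of the 2^n state space.

Successor generation is bit-vectorized over the whole state space and the
SCC condensation runs through sparse matrices, so graphs with a few million
states are handled without per-state Python objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import reduce
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import expr as E
from .model import BooleanModel, ModelError, Scenario, apply_scenario
from .reduction import propagate_constants

DEFAULT_STATE_CAP = 24  # refuse exhaustive enumeration beyond 2^24 states


def _compile_bitwise(rule: E.Expr, index: dict[str, int],
                     states: np.ndarray) -> np.ndarray:
    """Evaluate a rule on every state index at once (bit b of a state is
    node b)."""
    if isinstance(rule, E.Var):
        return ((states >> index[rule.name]) & 1).astype(bool)
    if isinstance(rule, E.Const):
        return np.full(states.shape, rule.value, dtype=bool)
    if isinstance(rule, E.Not):
        return ~_compile_bitwise(rule.child, index, states)
    if isinstance(rule, E.And):
        return reduce(np.logical_and,
                      (_compile_bitwise(c, index, states) for c in rule.children))
    if isinstance(rule, E.Or):
        return reduce(np.logical_or,
                      (_compile_bitwise(c, index, states) for c in rule.children))
    raise TypeError(type(rule))


@dataclass(frozen=True)
class StateTransitionGraph:
    """Exhaustive transition structure, stored as flat edge arrays.

    Null transitions (updates that do not change the state) are omitted, so a
    state with no outgoing edges under GA is a fixed point."""

    nodes: tuple[str, ...]
    scheme: str
    src: np.ndarray
    dst: np.ndarray

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_states(self) -> int:
        return 1 << self.n

    def successors(self, state: int) -> set[int]:
        return set(self.dst[self.src == state].tolist())

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.src, minlength=self.n_states)


def build_stg(model: BooleanModel, scheme: str = "general_asynchronous",
              cap: int = DEFAULT_STATE_CAP) -> StateTransitionGraph:
    """Enumerate all one-step transitions of the model.

    ``scheme`` is ``synchronous`` or ``general_asynchronous``; clamped nodes
    are excluded from the GA update pool (their constant rules would only
    ever produce null updates once satisfied).
    """
    if scheme not in ("synchronous", "general_asynchronous"):
        raise ValueError(f"unsupported STG scheme {scheme!r}")
    if model.n > cap:
        raise ModelError(
            f"{model.n}-node model exceeds the 2^{cap}-state cap; "
            "reduce the network first")
    n = model.n
    index = {name: i for i, name in enumerate(model.nodes)}
    dtype = np.int32 if n < 31 else np.int64
    states = np.arange(1 << n, dtype=dtype)
    next_bits = [_compile_bitwise(model.rules[name], index, states)
                 for name in model.nodes]
    if scheme == "synchronous":
        nxt = np.zeros_like(states)
        for j, bits in enumerate(next_bits):
            nxt |= bits.astype(dtype) << j
        moved = nxt != states
        return StateTransitionGraph(nodes=model.nodes, scheme=scheme,
                                    src=states[moved], dst=nxt[moved])
    free = [j for j, name in enumerate(model.nodes) if name not in model.clamped]
    srcs, dsts = [], []
    for j in free:
        cur = ((states >> j) & 1).astype(bool)
        flips = cur != next_bits[j]
        srcs.append(states[flips])
        dsts.append(states[flips] ^ (np.asarray(1, dtype) << j))
    src = np.concatenate(srcs) if srcs else np.empty(0, dtype)
    dst = np.concatenate(dsts) if dsts else np.empty(0, dtype)
    return StateTransitionGraph(nodes=model.nodes, scheme=scheme, src=src, dst=dst)


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC with its basin sizes and per-node activation pattern."""

    states: np.ndarray
    kind: str  # fixed_point | cyclic | complex
    basin_fraction: float = float("nan")
    exclusive_basin_fraction: float = float("nan")
    pattern: dict[str, tuple[str, float]] = field(default_factory=dict)
    phenotype: str = ""

    @property
    def length(self) -> int:
        return len(self.states)


def find_attractors(stg: StateTransitionGraph) -> list[Attractor]:
    """Terminal SCCs of the state transition graph, ordered by smallest
    contained state index.

    A fixed point is a singleton SCC with no outgoing transitions; a terminal
    SCC in which every state has exactly one outgoing transition is a simple
    (limited) cycle; anything larger is a complex attractor.
    """
    N = stg.n_states
    graph = sp.csr_matrix(
        (np.ones(len(stg.src), dtype=np.int8), (stg.src, stg.dst)), shape=(N, N))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    has_out = np.zeros(n_comp, dtype=bool)
    cross = labels[stg.src] != labels[stg.dst]
    has_out[labels[stg.src[cross]]] = True
    # null updates are omitted from the edge set, so a terminal singleton is
    # a genuine fixed point (all of its updates leave the state unchanged)
    att_states = np.flatnonzero(~has_out[labels])
    if att_states.size == 0:
        return []
    att_labels = labels[att_states]
    order = np.argsort(att_labels, kind="stable")
    att_states, att_labels = att_states[order], att_labels[order]
    bounds = np.flatnonzero(np.diff(att_labels)) + 1
    groups = np.split(att_states, bounds)
    outdeg = stg.out_degrees()
    attractors = []
    for states in groups:
        states = np.sort(states)
        if len(states) == 1:
            kind = "fixed_point"
        elif np.all(outdeg[states] == 1):
            kind = "cyclic"
        else:
            kind = "complex"
        attractors.append(Attractor(states=states, kind=kind))
    attractors.sort(key=lambda a: int(a.states[0]))
    return attractors


def compute_basins(stg: StateTransitionGraph,
                   attractors: Sequence[Attractor]) -> list[Attractor]:
    """Fill total and exclusive basin fractions by exact backward
    reachability over the reversed transition graph."""
    N = stg.n_states
    reverse = sp.csr_matrix(
        (np.ones(len(stg.src), dtype=np.int8), (stg.dst, stg.src)), shape=(N, N))
    basins = []
    for att in attractors:
        visited = np.zeros(N, dtype=bool)
        visited[att.states] = True
        frontier = att.states
        while frontier.size:
            preds = reverse[frontier].indices
            preds = np.unique(preds)
            preds = preds[~visited[preds]]
            visited[preds] = True
            frontier = preds
        basins.append(visited)
    counts = np.zeros(N, dtype=np.int32)
    for visited in basins:
        counts += visited
    out = []
    for att, visited in zip(attractors, basins):
        total = float(visited.sum()) / N
        exclusive = float((visited & (counts == 1)).sum()) / N
        out.append(replace(att, basin_fraction=total,
                           exclusive_basin_fraction=exclusive))
    return out


def activation_pattern(states: np.ndarray, nodes: Sequence[str]
                       ) -> dict[str, tuple[str, float]]:
    """Per-node ON-fraction across an attractor's states.

    Fraction 1 is *full* activation, 0 is *inactive*, anything in between is
    *partial* (oscillating within the attractor)."""
    if len(states) == 0:
        raise ValueError("empty attractor")
    pattern = {}
    arr = np.asarray(states)
    for j, name in enumerate(nodes):
        frac = float(((arr >> j) & 1).mean())
        label = "full" if frac == 1.0 else "inactive" if frac == 0.0 else "partial"
        pattern[name] = (label, frac)
    return pattern


#: default readout decision table: Apoptosis dominates, then Proliferation's
#: activation grade; CYCLIND1/P21 serve as proxies when the Proliferation
#: readout was removed by reduction (reduced rule: CYCLIND1 and not P21)
def classify_phenotype(pattern: dict[str, tuple[str, float]]) -> str:
    """Map an activation pattern to a phenotype label.

    ``apoptosis`` when Apoptosis is fully active; otherwise ``proliferation``
    / ``limited proliferation`` / ``resting`` according to the Proliferation
    node (full / partial / inactive), falling back to the CYCLIND1-P21 proxy
    when Proliferation is absent."""
    if "Apoptosis" in pattern and pattern["Apoptosis"][0] == "full":
        return "apoptosis"
    if "Proliferation" in pattern:
        grade = pattern["Proliferation"][0]
        return {"full": "proliferation", "partial": "limited proliferation",
                "inactive": "resting"}[grade]
    missing = [n for n in ("CYCLIND1", "P21") if n not in pattern]
    if missing:
        raise ModelError("phenotype classification requires Proliferation or "
                         "the CYCLIND1/P21 proxies; missing: " + ", ".join(missing))
    cyclin, p21 = pattern["CYCLIND1"][0], pattern["P21"][0]
    if cyclin == "inactive":
        return "resting"
    if cyclin == "full" and p21 == "inactive":
        return "proliferation"
    return "limited proliferation"


def annotate(stg: StateTransitionGraph, attractors: Sequence[Attractor],
             extra_pattern: dict[str, tuple[str, float]] | None = None,
             ) -> list[Attractor]:
    """Attach basins, activation patterns and phenotype labels.

    ``extra_pattern`` supplies full/inactive entries for nodes eliminated
    before the STG was built (e.g. stabilized readouts), so phenotype
    classification still sees them."""
    out = []
    for att in compute_basins(stg, attractors):
        pattern = activation_pattern(att.states, stg.nodes)
        if extra_pattern:
            pattern = {**extra_pattern, **pattern}
        try:
            phenotype = classify_phenotype(pattern)
        except ModelError:
            phenotype = ""  # model has no recognised readout nodes
        out.append(replace(att, pattern=pattern, phenotype=phenotype))
    return out


def analyse(model: BooleanModel, scheme: str = "general_asynchronous",
            cap: int = DEFAULT_STATE_CAP,
            stabilized: dict[str, bool] | None = None) -> list[Attractor]:
    """Constant-fold any clamped/stabilized nodes, enumerate the remaining
    state space and return fully annotated attractors.

    Stabilized nodes — both those folded here and any recorded by an earlier
    reduction and passed via ``stabilized`` — re-enter each attractor's
    activation pattern as full/inactive entries so readout phenotypes
    survive reduction."""
    folded, newly_stabilized = propagate_constants(model)
    constants = dict(stabilized or {})
    constants.update(newly_stabilized)
    extra = {n: ("full" if v else "inactive", 1.0 if v else 0.0)
             for n, v in constants.items()}
    if folded.n == 0:
        # everything stabilized: a single fixed point with full basin
        try:
            phenotype = classify_phenotype(extra)
        except ModelError:
            phenotype = ""
        return [Attractor(states=np.array([0]), kind="fixed_point",
                          basin_fraction=1.0, exclusive_basin_fraction=1.0,
                          pattern=extra, phenotype=phenotype)]
    stg = build_stg(folded, scheme, cap=cap)
    return annotate(stg, find_attractors(stg), extra_pattern=extra)


def attractor_landscape(model: BooleanModel, scenario: Scenario | None = None,
                        scheme: str = "general_asynchronous",
                        protected: Sequence[str] = ("Proliferation", "Apoptosis"),
                        cap: int = DEFAULT_STATE_CAP):
    """End-to-end pipeline: apply a scenario, reduce the network as far as
    needed, and enumerate the annotated attractors.

    Constant propagation always runs; mediator and dangling removal are
    applied only when the constant-folded model still exceeds the
    enumeration cap, so small models are analysed on their own state space
    (basin fractions of a reduced model are relative to the reduced space).
    Returns ``(reduction_trace, attractors)``; stabilized nodes (including
    stabilized readouts) are folded back into the activation patterns.
    """
    from .reduction import ReductionTrace, reduce_network
    m = apply_scenario(model, scenario) if scenario is not None else model
    folded, stabilized = propagate_constants(m)
    if folded.n <= cap:
        trace = ReductionTrace(stabilized=stabilized, reduced=folded,
                               protected=frozenset(protected))
        atts = analyse(folded, scheme, cap=cap, stabilized=stabilized)
        return trace, atts
    trace = reduce_network(m, protected={p for p in protected if p in m.nodes})
    atts = analyse(trace.reduced, scheme, cap=cap, stabilized=trace.stabilized)
    return trace, atts


@dataclass(frozen=True)
class FixScanEntry:
    node: str
    value: bool
    phenotypes: tuple[str, ...]
    single_attractor: bool
    n_attractors: int


def node_fixing_scan(model: BooleanModel, candidates: Sequence[str] | None = None,
                     scheme: str = "general_asynchronous",
                     cap: int = DEFAULT_STATE_CAP) -> list[FixScanEntry]:
    """Clamp each candidate node to ON and to OFF in turn and summarise the
    resulting attractor landscape.

    Used to expose the core regulatory circuit: a clamp that funnels every
    trajectory into one attractor marks a decisive control point."""
    if candidates is None:
        candidates = [n for n in model.nodes if n not in model.clamped]
    entries = []
    for name in candidates:
        for value in (True, False):
            scenario = Scenario(fixed={name: value}, default_initial="uniform_random")
            clamped = apply_scenario(model, scenario)
            atts = analyse(clamped, scheme, cap=cap)
            phenos = tuple(sorted({a.phenotype for a in atts}))
            entries.append(FixScanEntry(node=name, value=value, phenotypes=phenos,
                                        single_attractor=len(atts) == 1,
                                        n_attractors=len(atts)))
    return entries
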