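"""Packaged models, toy networks, random network generation and the
brute-force attractor oracle.

The flagship fixture ``cac_synthetic`` is a synthetic colitis-associated
colon cancer (CAC) style signalling network: a stand-in demonstration model
assembled from textbook pathway logic (IL6/JAK/STAT3 with SOCS feedback,
TNF/NF-kB, COX2/PGE2, ERK MAPK, PI3K/AKT, P53/MDM2, the sphingolipid
rheostat and mitochondrial apoptosis), not a transcription of any published
curated model.  Four scenarios accompany it: ``non_inflammatory``,
``transient_dc``, ``pro_tumor_dc`` and ``p53_off``.

The toys and random networks drive the property-test suite, and
:func:`oracle_attractors` is a deliberately naive, independent re-derivation
of attractors and basins used to cross-check the production implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import networkx as nx
import numpy as np

from . import expr as E
from . import io
from .model import BooleanModel, Scenario

MICROENVIRONMENT = ("DC", "MAC", "TREG", "CTL", "TH1", "TH2")
SCENARIO_NAMES = ("non_inflammatory", "transient_dc", "pro_tumor_dc", "p53_off")

_TOYS = {
    # two mutually repressing genes: GA attractors are the two fixed points;
    # synchronous updating adds the out-of-phase 2-cycle
    "toggle": "A* = not B\nB* = not A\n",
    # three-node negation ring: no fixed point, oscillates under any scheme
    "tristate_cycle": "A* = not C\nB* = not A\nC* = not B\n",
    # input-driven chain: two fixed points, all-OFF and all-ON
    "cascade": "A* = A\nB* = A\nC* = B\n",
    # negative feedback pair: a single 4-state cycle under synchronous update
    "feedback_loop": "A* = not B\nB* = A\n",
}


def make_toy(name: str) -> BooleanModel:
    """Return one of the canonical small models (``toggle``,
    ``tristate_cycle``, ``cascade``, ``feedback_loop``)."""
    try:
        return io.parse_model(_TOYS[name])
    except KeyError:
        raise ValueError(f"unknown toy {name!r}; choices: {sorted(_TOYS)}") from None


def _read_data(filename: str) -> str:
    return (resources.files("booldyn") / "data" / filename).read_text()


def load_model(name: str = "cac_synthetic") -> BooleanModel:
    """Load a packaged rule file (``cac_synthetic`` or
    ``cac_synthetic_reduced``)."""
    model = io.parse_model(_read_data(f"{name}.bool"))
    roles = {n: "microenvironment" for n in MICROENVIRONMENT if n in model.nodes}
    roles.update({n: "output" for n in ("Proliferation", "Apoptosis")
                  if n in model.nodes})
    return BooleanModel(nodes=model.nodes, rules=model.rules, roles=roles)


def load_scenario(name: str) -> Scenario:
    """Load a packaged scenario (one of ``SCENARIO_NAMES``)."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choices: {SCENARIO_NAMES}")
    return io.parse_scenario(_read_data(f"{name}.scn"))


def list_fixtures() -> dict[str, list[str]]:
    return {"toys": sorted(_TOYS), "models": ["cac_synthetic", "cac_synthetic_reduced"],
            "scenarios": list(SCENARIO_NAMES)}


# ---------------------------------------------------------------------------
# random networks

@dataclass(frozen=True)
class RandomNetworkSpec:
    """Recipe for a random Boolean network: ``n`` nodes, each with
    ``in_degree`` distinct regulators and a random truth table whose rows are
    ON with probability ``bias``."""

    n: int
    in_degree: int = 2
    bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.in_degree <= self.n:
            raise ValueError("in_degree must be in [1, n]")
        if not 0.0 < self.bias < 1.0:
            raise ValueError("bias must be in (0, 1)")


def _table_to_dnf(regulators: list[str], table: np.ndarray) -> E.Expr:
    """Materialize a truth table as a disjunctive normal form expression.

    Row r of the table is the output for the assignment whose bit b is
    regulator b's state."""
    if not table.any():
        return E.FALSE
    if table.all():
        return E.TRUE
    minterms = []
    for r in np.flatnonzero(table):
        literals: list[E.Expr] = []
        for b, reg in enumerate(regulators):
            v: E.Expr = E.Var(reg)
            literals.append(v if (int(r) >> b) & 1 else E.Not(v))
        minterms.append(E.conj(literals))
    return E.disj(minterms)


def random_model(spec: RandomNetworkSpec) -> BooleanModel:
    """Generate a reproducible random Boolean network from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    names = [f"N{i}" for i in range(spec.n)]
    rules = {}
    for name in names:
        regulators = [names[j] for j in
                      rng.choice(spec.n, size=spec.in_degree, replace=False)]
        table = rng.random(1 << spec.in_degree) < spec.bias
        rules[name] = _table_to_dnf(regulators, table)
    return BooleanModel(nodes=tuple(names), rules=rules)


# ---------------------------------------------------------------------------
# brute-force oracle

ORACLE_CAP = 12


@dataclass(frozen=True)
class OracleAttractor:
    states: frozenset[int]
    kind: str
    basin_fraction: float
    exclusive_basin_fraction: float


def _oracle_sync_next(model: BooleanModel, state: int) -> int:
    assignment = {name: (state >> b) & 1 for b, name in enumerate(model.nodes)}
    nxt = 0
    for b, name in enumerate(model.nodes):
        if model.rules[name].evaluate(assignment):
            nxt |= 1 << b
    return nxt


def _classify(states: frozenset[int], graph: nx.DiGraph) -> str:
    if len(states) == 1:
        return "fixed_point"
    if all(graph.out_degree(s) == 1 for s in states):
        return "cyclic"
    return "complex"


def oracle_attractors(model: BooleanModel, scheme: str) -> list[OracleAttractor]:
    """Naive reference computation of attractors and basins (n <= 12).

    Synchronous: follow the deterministic orbit from every state until it
    repeats, collecting the cycles.  General asynchronous: materialize the
    full labelled transition graph, take strongly connected components with
    no outgoing edge, and compute basins by explicit reverse reachability.
    Shares no code with the production state-transition-graph pipeline.
    """
    if model.n > ORACLE_CAP:
        raise ValueError(f"oracle limited to {ORACLE_CAP} nodes")
    n_states = 1 << model.n

    graph = nx.DiGraph()
    graph.add_nodes_from(range(n_states))
    if scheme == "synchronous":
        for s in range(n_states):
            t = _oracle_sync_next(model, s)
            if t != s:
                graph.add_edge(s, t)
    elif scheme == "general_asynchronous":
        free = [b for b, name in enumerate(model.nodes)
                if name not in model.clamped]
        for s in range(n_states):
            assignment = {name: (s >> b) & 1 for b, name in enumerate(model.nodes)}
            for b in free:
                value = model.rules[model.nodes[b]].evaluate(assignment)
                t = (s | (1 << b)) if value else (s & ~(1 << b))
                if t != s:
                    graph.add_edge(s, t)
    else:
        raise ValueError(f"unsupported scheme {scheme!r}")

    attractors = []
    for scc in nx.strongly_connected_components(graph):
        if any(t not in scc for s in scc for t in graph.successors(s)):
            continue
        attractors.append(frozenset(scc))

    reverse = graph.reverse(copy=False)
    basins = []
    for states in attractors:
        basin = set(states)
        for s in states:
            basin |= nx.descendants(reverse, s)
        basins.append(basin)
    counts: dict[int, int] = {}
    for basin in basins:
        for s in basin:
            counts[s] = counts.get(s, 0) + 1
    out = []
    for states, basin in zip(attractors, basins):
        exclusive = sum(1 for s in basin if counts[s] == 1)
        out.append(OracleAttractor(
            states=states, kind=_classify(states, graph),
            basin_fraction=len(basin) / n_states,
            exclusive_basin_fraction=exclusive / n_states))
    out.sort(key=lambda a: min(a.states))
    return out


def oracle_projected_attractors(model: BooleanModel, scheme: str,
                                keep: list[str]) -> set[frozenset[int]]:
    """Attractor state-sets projected onto the ``keep`` nodes (bit b of a
    projected state is ``keep[b]``) — the comparison object for reduction
    soundness checks."""
    bits = [model.index(name) for name in keep]
    projected = set()
    for att in oracle_attractors(model, scheme):
        proj = frozenset(
            sum(((s >> b) & 1) << i for i, b in enumerate(bits))
            for s in att.states)
        projected.add(proj)
    return projected


def enumerate_truth_table(model: BooleanModel, name: str) -> list[bool]:
    """Exhaustive evaluation of one node's rule over its regulators, in
    sorted regulator order (independent check for generated DNF rules)."""
    regs = sorted(model.regulators(name))
    rows = []
    for values in product((0, 1), repeat=len(regs)):
        rows.append(model.rules[name].evaluate(dict(zip(regs, values))))
    return rows
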