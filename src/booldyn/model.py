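"""Boolean network models and simulation scenarios.

A :class:`BooleanModel` is an ordered collection of named nodes, each carrying
one Boolean transfer function f_i over the states of its regulators (k_i =
number of distinct regulators).  A :class:`Scenario` declares which nodes are
clamped (held at ON/OFF for a whole simulation, modelling constitutive
activation or knockout) and which merely start in a given state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import expr as E

#: optional functional classes for nodes, mirroring the colour classes used in
#: signalling-network diagrams
NODE_ROLES = ("microenvironment", "inflammatory-signalling", "proliferation",
              "survival", "output")


class ModelError(ValueError):
    """Raised on invalid models or scenarios."""


@dataclass(frozen=True)
class BooleanModel:
    """An ordered, validated set of Boolean update rules.

    Parameters
    ----------
    nodes
        Node names, order significant (bit b of a packed state integer is
        node ``nodes[b]``).
    rules
        One expression per node, keyed by name.
    roles
        Optional functional tag per node.
    clamped
        Nodes whose rule is a scenario-imposed constant.
    """

    nodes: tuple[str, ...]
    rules: dict[str, E.Expr]
    roles: dict[str, str] = field(default_factory=dict)
    clamped: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ModelError("duplicate node names")
        if any(not n for n in self.nodes):
            raise ModelError("empty node name")
        if set(self.rules) != set(self.nodes):
            raise ModelError("rules must cover exactly the declared nodes")
        declared = set(self.nodes)
        for name, rule in self.rules.items():
            dangling = rule.variables() - declared
            if dangling:
                raise ModelError(
                    f"rule for {name} references undeclared node(s): "
                    + ", ".join(sorted(dangling)))
        for role in self.roles.values():
            if role not in NODE_ROLES:
                raise ModelError(f"unknown role {role!r}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def inputs(self) -> frozenset[str]:
        """Self-maintaining nodes (rule ``X* = X``): environmental switches
        whose state is set only by initial conditions or scenario clamps."""
        return frozenset(n for n in self.nodes if self.rules[n] == E.Var(n))

    def index(self, name: str) -> int:
        return self.nodes.index(name)

    def in_degree(self, name: str) -> int:
        """Number of distinct regulators of ``name`` (k_i), self included."""
        return len(self.rules[name].variables())

    def regulators(self, name: str) -> set[str]:
        return self.rules[name].variables()

    def targets(self, name: str) -> set[str]:
        return {t for t in self.nodes if name in self.rules[t].variables()}

    def with_rules(self, new_rules: dict[str, E.Expr], **kw) -> "BooleanModel":
        rules = dict(self.rules)
        rules.update(new_rules)
        return replace(self, rules=rules, **kw)

    def drop_nodes(self, names: set[str]) -> "BooleanModel":
        keep = tuple(n for n in self.nodes if n not in names)
        return BooleanModel(
            nodes=keep,
            rules={n: self.rules[n] for n in keep},
            roles={n: r for n, r in self.roles.items() if n in keep},
            clamped={n: v for n, v in self.clamped.items() if n in keep},
        )


def model_edges(model: BooleanModel) -> set[tuple[str, str, str]]:
    """Signed regulator->target interactions.

    One triple per distinct regulator appearing in a target's rule.  The sign
    is '+' when every occurrence sits under an even number of negations, '-'
    under odd, and '+/-' (dual) when both parities occur.
    """
    edges = set()
    for target in model.nodes:
        for reg, parities in E.signed_regulators(model.rules[target]).items():
            sign = "+/-" if len(parities) == 2 else next(iter(parities))
            edges.add((reg, target, sign))
    return edges


def edge_count(model: BooleanModel) -> int:
    """Number of distinct (regulator, target) pairs."""
    return len(model_edges(model))


@dataclass(frozen=True)
class Scenario:
    """Fixed-state and initial-state directives for a simulation.

    ``fixed`` nodes are clamped for the whole run; ``initial`` nodes start in
    the given state but evolve freely.  Remaining nodes start according to
    ``default_initial``: each independently ON with probability 0.5
    (``uniform_random``) or OFF (``all_off``).
    """

    fixed: dict[str, bool] = field(default_factory=dict)
    initial: dict[str, bool] = field(default_factory=dict)
    default_initial: str = "uniform_random"

    def __post_init__(self) -> None:
        if self.default_initial not in ("uniform_random", "all_off"):
            raise ModelError(
                f"unknown default initial policy {self.default_initial!r}")
        overlap = set(self.fixed) & set(self.initial)
        if overlap:
            raise ModelError(
                "node(s) in both [fixed] and [initial]: " + ", ".join(sorted(overlap)))

    def validate(self, model: BooleanModel) -> None:
        unknown = (set(self.fixed) | set(self.initial)) - set(model.nodes)
        if unknown:
            raise ModelError("scenario references unknown node(s): "
                             + ", ".join(sorted(unknown)))


def apply_scenario(model: BooleanModel, scenario: Scenario) -> BooleanModel:
    """Clamp the scenario's fixed nodes by replacing their rules with constants.

    Initial-state directives do not alter rules; they only bias the starting
    state and are handled by the simulator.
    """
    scenario.validate(model)
    new_rules = {n: (E.TRUE if v else E.FALSE) for n, v in scenario.fixed.items()}
    clamped = dict(model.clamped)
    clamped.update(scenario.fixed)
    return model.with_rules(new_rules, clamped=clamped)
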