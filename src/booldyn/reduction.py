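"""Logical network reduction.

Exhaustive attractor analysis scales as 2^n, so large models are first shrunk
by a reduction that provably preserves long-term dynamics on the retained
nodes:

1. *constant propagation* — any rule that simplifies to TRUE/FALSE under the
   Boolean identities stabilizes its node; the constant is substituted into
   all other rules and the process repeats to a fixed point;
2. *mediator removal* — a node with in-degree 1 and out-degree 1 (no
   self-loop) is spliced out by substituting its rule into its single target;
3. *dangling removal* — nodes nobody reads (out-degree 0) are deleted.

Output/readout nodes and scenario-clamped nodes are protected from removal by
default so the reduced model keeps its biological readouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import expr as E
from .model import BooleanModel, model_edges


@dataclass
class ReductionTrace:
    """Record of a reduction run: which nodes went where, and the result."""

    stabilized: dict[str, bool] = field(default_factory=dict)
    removed_mediators: list[tuple[str, str]] = field(default_factory=list)
    removed_dangling: list[str] = field(default_factory=list)
    protected: frozenset[str] = frozenset()
    reduced: BooleanModel | None = None

    @property
    def removed(self) -> set[str]:
        return (set(self.stabilized) | {m for m, _ in self.removed_mediators}
                | set(self.removed_dangling))


def _constant_value(rule: E.Expr, exhaustive: bool) -> bool | None:
    simplified = E.simplify(rule)
    if isinstance(simplified, E.Const):
        return simplified.value
    if exhaustive:
        # small k_i makes an exhaustive truth-table constancy check cheap
        table = E.truth_table(simplified, sorted(simplified.variables()))
        if all(table):
            return True
        if not any(table):
            return False
    return None


def propagate_constants(model: BooleanModel, exhaustive: bool = False
                        ) -> tuple[BooleanModel, dict[str, bool]]:
    """Iteratively eliminate nodes whose rules reduce to constants.

    Rules are simplified under the standard identities; a rule that becomes
    TRUE/FALSE stabilizes its node, the constant is substituted everywhere
    and simplification repeats until no further rule collapses.  With
    ``exhaustive=True`` constancy is additionally decided by evaluating the
    simplified rule on all 2^k_i regulator assignments.

    Self-referencing rules never stabilize this way (``X* = X`` has two
    attracting states), which is exactly why input nodes survive unless a
    scenario clamps them.
    """
    rules = {n: E.simplify(r) for n, r in model.rules.items()}
    stabilized: dict[str, bool] = {}
    changed = True
    while changed:
        changed = False
        newly: dict[str, E.Expr] = {}
        for name, rule in rules.items():
            if name in stabilized:
                continue
            value = _constant_value(rule, exhaustive)
            if value is not None:
                stabilized[name] = value
                newly[name] = E.Const(value)
                changed = True
        if newly:
            for name in list(rules):
                if name in stabilized:
                    continue
                rules[name] = E.simplify(E.substitute(rules[name], newly))
    keep = tuple(n for n in model.nodes if n not in stabilized)
    reduced = BooleanModel(
        nodes=keep,
        rules={n: rules[n] for n in keep},
        roles={n: r for n, r in model.roles.items() if n in keep},
        clamped={n: v for n, v in model.clamped.items() if n in keep},
    )
    return reduced, stabilized


def _degrees(model: BooleanModel) -> tuple[dict[str, int], dict[str, int]]:
    indeg = {n: 0 for n in model.nodes}
    outdeg = {n: 0 for n in model.nodes}
    for reg, tgt, _sign in model_edges(model):
        indeg[tgt] += 1
        outdeg[reg] += 1
    return indeg, outdeg


def remove_mediators(model: BooleanModel, protected: set[str] = frozenset()
                     ) -> tuple[BooleanModel, list[tuple[str, str]]]:
    """Iteratively splice out simple mediator nodes.

    A mediator has exactly one regulator and one target, is not its own
    regulator or target, and is not protected.  Its rule expression is
    substituted into the downstream rule, directly connecting its input to
    its output (negation parity is carried by the expression itself).  The
    scan runs in declaration order and restarts after every removal, with
    degrees recomputed on the current model.
    """
    m = model
    records: list[tuple[str, str]] = []
    while True:
        indeg, outdeg = _degrees(m)
        candidate = None
        for name in m.nodes:
            if name in protected or name in m.clamped:
                continue
            if indeg[name] != 1 or outdeg[name] != 1:
                continue
            if name in m.rules[name].variables():  # self-loop disqualifies
                continue
            targets = m.targets(name)
            if targets == {name}:
                continue
            candidate = (name, next(iter(targets)))
            break
        if candidate is None:
            return m, records
        med, tgt = candidate
        new_rule = E.simplify(E.substitute(m.rules[tgt], {med: m.rules[med]}))
        m = m.with_rules({tgt: new_rule}).drop_nodes({med})
        records.append((med, tgt))


def remove_dangling(model: BooleanModel, protected: set[str] = frozenset()
                    ) -> tuple[BooleanModel, list[str]]:
    """Iteratively delete unprotected nodes with out-degree zero."""
    m = model
    removed: list[str] = []
    while True:
        _indeg, outdeg = _degrees(m)
        doomed = [n for n in m.nodes
                  if outdeg[n] == 0 and n not in protected and n not in m.clamped]
        if not doomed:
            return m, removed
        m = m.drop_nodes(set(doomed))
        removed.extend(doomed)


def reduce_network(model: BooleanModel, protected: set[str] = frozenset(),
                   exhaustive: bool = False) -> ReductionTrace:
    """Full reduction pipeline, iterated to a global fixed point.

    The model should already have scenario clamps applied (clamped rules are
    constants, so constant propagation folds the scenario in).  ``protected``
    nodes survive mediator and dangling removal; clamped nodes are never
    removed structurally (they stabilize in phase 1 instead).
    """
    trace = ReductionTrace(protected=frozenset(protected))
    m = model
    while True:
        m, stab = propagate_constants(m, exhaustive=exhaustive)
        trace.stabilized.update(stab)
        m, meds = remove_mediators(m, protected)
        trace.removed_mediators.extend(meds)
        m, dang = remove_dangling(m, protected)
        trace.removed_dangling.extend(dang)
        if not (stab or meds or dang):
            break
    trace.reduced = m
    return trace
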