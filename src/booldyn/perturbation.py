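"""Systematic in-silico perturbation screens.

A perturbation clamps one node (single screen) or two nodes (double screen)
to ON or OFF on top of a background scenario — the computational analogue of
constitutive activation, knockdown or pharmacological inhibition — and reads
out the stabilized activation frequencies of the output nodes Proliferation
and Apoptosis.

Candidate construction follows the stabilization structure of the baseline:
a node that stabilizes ON or OFF is perturbed once, to the opposite state;
an oscillating node is perturbed twice, to ON and to OFF.  Output nodes and
scenario-clamped nodes are never candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .dynamics import (SimulationConfig, StabilizationReport,
                       detect_stabilization, simulate_ensemble)
from .model import BooleanModel, ModelError, Scenario

OUTPUT_NODES = ("Proliferation", "Apoptosis")


@dataclass(frozen=True)
class ScreenThresholds:
    """Effect-classification cut-offs (all on activation frequencies).

    ``pro_proliferative``: absolute Proliferation frequency at or above this
    is scored pro-proliferative.  ``proliferation_delta`` /
    ``apoptosis_delta``: drop in Proliferation / rise in Apoptosis relative
    to baseline needed for the anti-proliferative / pro-apoptotic calls.
    ``affect``: both outputs moving less than this is "no effect".
    """

    pro_proliferative: float = 0.9
    proliferation_delta: float = 0.25
    apoptosis_delta: float = 0.25
    affect: float = 0.1
    na_tolerance: float = 0.02  # double-screen "no additional effect" band


@dataclass(frozen=True)
class PerturbationRecord:
    clamps: tuple[tuple[str, bool], ...]
    proliferation: float
    apoptosis: float
    effect: str = ""
    delta_proliferation: float = 0.0
    delta_apoptosis: float = 0.0

    def label(self) -> str:
        return "+".join(f"{n}({'+' if v else '-'})" for n, v in self.clamps)


def _merged_scenario(scenario: Scenario, clamps: tuple[tuple[str, bool], ...]
                     ) -> Scenario:
    fixed = dict(scenario.fixed)
    for name, value in clamps:
        if name in fixed and fixed[name] != value:
            raise ModelError(f"conflicting clamp on {name}")
        fixed[name] = value
    initial = {n: v for n, v in scenario.initial.items() if n not in fixed}
    return Scenario(fixed=fixed, initial=initial,
                    default_initial=scenario.default_initial)


def enumerate_single_perturbations(model: BooleanModel, scenario: Scenario,
                                   baseline: StabilizationReport,
                                   outputs: tuple[str, ...] = OUTPUT_NODES
                                   ) -> list[tuple[str, bool]]:
    """Candidate clamps derived from the baseline stabilization report.

    Stabilized nodes contribute one clamp (the opposite of their attracting
    state); oscillating nodes contribute both clamps.  Scenario-fixed nodes
    and output nodes are excluded.  Order follows model declaration order.
    """
    scenario.validate(model)
    excluded = set(scenario.fixed) | set(model.clamped) | set(outputs)
    clamps: list[tuple[str, bool]] = []
    for name in model.nodes:
        if name in excluded or name not in baseline.status:
            continue
        status = baseline.status[name]
        if status == "stable_on":
            clamps.append((name, False))
        elif status == "stable_off":
            clamps.append((name, True))
        else:
            clamps.append((name, True))
            clamps.append((name, False))
    return clamps


def classify_effect(record: PerturbationRecord, baseline: tuple[float, float],
                    thresholds: ScreenThresholds = ScreenThresholds()) -> str:
    """Score a perturbation against the baseline output frequencies."""
    base_prolif, base_apop = baseline
    d_prolif = record.proliferation - base_prolif
    d_apop = record.apoptosis - base_apop
    # a clamp that moves neither output is inert even when the baseline
    # itself sits in the pro-proliferative range
    if abs(d_prolif) < thresholds.affect and abs(d_apop) < thresholds.affect:
        return "no_effect"
    if record.proliferation >= thresholds.pro_proliferative:
        return "pro_proliferative"
    if d_apop >= thresholds.apoptosis_delta:
        return "pro_apoptotic"
    if -d_prolif >= thresholds.proliferation_delta:
        return "anti_proliferative"
    return "weak_effect"


def _measure(model: BooleanModel, scenario: Scenario,
             clamps: tuple[tuple[str, bool], ...], config: SimulationConfig,
             window: int, outputs: tuple[str, ...]) -> PerturbationRecord:
    merged = _merged_scenario(scenario, clamps)
    trace = simulate_ensemble(model, merged, config)
    report = detect_stabilization(trace, window=min(window, config.steps))
    prolif = report.steady.get(outputs[0], float("nan"))
    apop = report.steady.get(outputs[1], float("nan"))
    return PerturbationRecord(clamps=clamps, proliferation=prolif, apoptosis=apop)


def run_screen(model: BooleanModel, scenario: Scenario,
               clamp_list: list[tuple[str, bool]], config: SimulationConfig,
               baseline: tuple[float, float],
               thresholds: ScreenThresholds = ScreenThresholds(),
               window: int = 500,
               outputs: tuple[str, ...] = OUTPUT_NODES
               ) -> list[PerturbationRecord]:
    """Simulate every single-node clamp and classify its effect.

    Each record is measured with the same configuration (seeded, so the
    screen is reproducible and independent of clamp order) and scored
    against the supplied baseline (Proliferation, Apoptosis) frequencies.
    """
    records = []
    for clamp in clamp_list:
        rec = _measure(model, scenario, (clamp,), config, window, outputs)
        rec = replace(rec,
                      effect=classify_effect(rec, baseline, thresholds),
                      delta_proliferation=rec.proliferation - baseline[0],
                      delta_apoptosis=rec.apoptosis - baseline[1])
        records.append(rec)
    return records


def run_double_screen(model: BooleanModel, scenario: Scenario,
                      pairs: list[tuple[tuple[str, bool], tuple[str, bool]]],
                      config: SimulationConfig,
                      baseline: tuple[float, float],
                      thresholds: ScreenThresholds = ScreenThresholds(),
                      window: int = 500,
                      outputs: tuple[str, ...] = OUTPUT_NODES
                      ) -> list[PerturbationRecord]:
    """Simulate pairs of simultaneous clamps.

    A pair whose two outputs both sit within the NA tolerance of the more
    effective of its constituent single perturbations adds nothing over the
    single clamp and is marked ``not_applicable``.
    """
    singles: dict[tuple[str, bool], PerturbationRecord] = {}
    records = []
    for a, b in pairs:
        if a[0] == b[0]:
            if a[1] != b[1]:
                raise ModelError(f"conflicting clamp on {a[0]}")
            raise ModelError(f"pair clamps the same node twice: {a[0]}")
        for single in (a, b):
            if single not in singles:
                singles[single] = _measure(model, scenario, (single,), config,
                                           window, outputs)
        rec = _measure(model, scenario, (a, b), config, window, outputs)
        effect = classify_effect(rec, baseline, thresholds)
        tol = thresholds.na_tolerance
        for single in (a, b):
            s = singles[single]
            if (abs(rec.proliferation - s.proliferation) <= tol
                    and abs(rec.apoptosis - s.apoptosis) <= tol):
                effect = "not_applicable"
                break
        rec = replace(rec, effect=effect,
                      delta_proliferation=rec.proliferation - baseline[0],
                      delta_apoptosis=rec.apoptosis - baseline[1])
        records.append(rec)
    return records
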