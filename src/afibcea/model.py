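"""End-to-end deterministic model runs: tree, Markov phase and comparison."""

from __future__ import annotations

from dataclasses import dataclass

from . import economics
from .economics import ArmSummary, CEResult, EventMetrics, compute_event_metrics, summarize_arm
from .markov import Trace, run_markov
from .params import ParameterSet
from .tree import InitialAllocation, run_decision_tree

INTERVENTION = "cryoablation"
COMPARATOR = "aad"


@dataclass
class ArmRun:
    arm: str
    allocation: InitialAllocation
    trace: Trace
    summary: ArmSummary


@dataclass
class DeterministicResult:
    intervention: ArmRun
    comparator: ArmRun
    ce: CEResult
    stroke_metrics: EventMetrics
    hf_metrics: EventMetrics


def run_arm(params: ParameterSet, arm: str) -> ArmRun:
    """Decision tree followed by the Markov phase for one arm."""
    allocation = run_decision_tree(params, arm)
    trace = run_markov(params, allocation, arm)
    return ArmRun(arm=arm, allocation=allocation, trace=trace, summary=summarize_arm(allocation, trace))


def run_deterministic(params: ParameterSet) -> DeterministicResult:
    """Run both arms and assemble the incremental comparison."""
    params.validate()
    a = run_arm(params, INTERVENTION)
    b = run_arm(params, COMPARATOR)
    ce = CEResult(intervention=a.summary, comparator=b.summary, wtp=params.settings.wtp)
    stroke = compute_event_metrics(
        "stroke", a.summary.strokes, b.summary.strokes, ce.delta_cost
    )
    hf = compute_event_metrics(
        "heart_failure", a.summary.hf_onsets, b.summary.hf_onsets, ce.delta_cost
    )
    return DeterministicResult(
        intervention=a, comparator=b, ce=ce, stroke_metrics=stroke, hf_metrics=hf
    )
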