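"""Discounting, per-cycle accrual and cost-effectiveness summary metrics.

Costs fall into five reporting categories mirroring the deterministic
results breakdown: the initial procedure, re-ablations, healthcare contact
costs, pharmaceutical costs and AF-related adverse events. Health benefit is
quality-adjusted life years (QALYs): per-cycle utility equals the
age-dependent population norm minus the rhythm-state decrement minus
prevalence-weighted adverse-event decrements, floored at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import states
from .params import NYHA, SEVERITIES, ParameterSet

COST_CATEGORIES = (
    "initial_procedure",
    "reablation",
    "healthcare_contacts",
    "pharmaceutical",
    "adverse_events",
)

CONTACT_RATE_CATEGORIES = ("hospitalization", "ed_visit", "outpatient")


def discount_factor(cycle_index: int, rate: float, cycle_length: float = 0.25) -> float:
    """Discount weight for a quarterly cycle on the model-wide clock.

    ``(1 + rate) ** (-cycle_index * cycle_length)``; cycle 0 is undiscounted.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-cycle_index * cycle_length)


@dataclass
class CycleAccrual:
    cost_undisc: dict
    cost_disc: dict
    qaly_undisc: float
    qaly_disc: float
    ly_undisc: float
    ly_disc: float


def _contact_cost_per_person(group: str, arm: str, params: ParameterSet) -> float:
    """Expected healthcare-contact cost for one person-cycle in a rhythm group."""
    c = params.costs
    util = params.risks.utilization
    unit = {
        "hospitalization": c.cv_hospitalization_per_cycle,
        "ed_visit": c.ed_visit_per_cycle,
        "outpatient": c.outpatient_per_cycle,
        "pharm_cardioversion": c.pharm_cardioversion,
        "elec_cardioversion": c.elec_cardioversion,
    }
    return sum(util[cat][arm][group] * unit[cat] for cat in unit)


def accrue_cycle(
    occupancy: np.ndarray,
    strokes: np.ndarray,
    ablations: float,
    blanked: float,
    stroke_prev: np.ndarray,
    hf_prev: np.ndarray,
    age: float,
    arm: str,
    global_cycle: int,
    params: ParameterSet,
) -> CycleAccrual:
    """Cost and QALY accrual for one cycle.

    ``strokes`` is the by-severity event mass this cycle; ``stroke_prev`` and
    ``hf_prev`` are prevalence masses carried into the cycle. ``blanked`` is
    the ablation-failure mass reclassified to NSR under the blanking period:
    it is charged ST-level minus NSR-level contact costs so the blanked
    episode's healthcare utilization still accrues.
    """
    s = params.settings
    c = params.costs
    u = params.utilities
    cl = s.cycle_length

    cost = {cat: 0.0 for cat in COST_CATEGORIES}
    alive = 0.0
    contacts = 0.0
    for st in states.LIVING:
        o = float(occupancy[st])
        if o <= 0.0:
            continue
        g = states.group_of(st)
        alive += o
        contacts += o * _contact_cost_per_person(g, arm, params)
    if blanked > 0.0:
        contacts += blanked * (
            _contact_cost_per_person("ST", arm, params)
            - _contact_cost_per_person("NSR", arm, params)
        )
    cost["healthcare_contacts"] = contacts
    cost["pharmaceutical"] = alive * c.pharma_per_cycle[arm]
    cost["reablation"] = ablations * c.ablation_procedure
    ae = float(sum(strokes[j] * c.stroke_acute[sev] for j, sev in enumerate(SEVERITIES)))
    ae += float(stroke_prev.sum()) * c.stroke_longterm_per_cycle
    ae += float(sum(hf_prev[j] * c.hf_per_cycle[cls] for j, cls in enumerate(NYHA)))
    cost["adverse_events"] = ae

    # QALYs: norm minus rhythm-state decrement minus prevalence-weighted
    # long-term AE decrements (uniform among the living), floored at 0 per
    # state; new strokes take their short-term decrement in the event cycle.
    norm = u.baseline_utility(age)
    prev_dec_mass = float(
        sum(stroke_prev[j] * u.stroke_long_decrement[sev] for j, sev in enumerate(SEVERITIES))
    ) + float(sum(hf_prev[j] * u.hf_decrement[cls] for j, cls in enumerate(NYHA)))
    per_alive_dec = prev_dec_mass / alive if alive > 1e-15 else 0.0
    qol_mass = 0.0
    for st in states.LIVING:
        o = float(occupancy[st])
        if o <= 0.0:
            continue
        g = states.group_of(st)
        qol_mass += o * max(0.0, norm - u.state_decrement(g) - per_alive_dec)
    qol_mass -= float(
        sum(strokes[j] * u.stroke_short_decrement[sev] for j, sev in enumerate(SEVERITIES))
    )
    qaly = cl * max(0.0, qol_mass)
    ly = cl * alive

    df_c = discount_factor(global_cycle, s.discount_rate_costs, cl)
    df_e = discount_factor(global_cycle, s.discount_rate_effects, cl)
    return CycleAccrual(
        cost_undisc=cost,
        cost_disc={cat: v * df_c for cat, v in cost.items()},
        qaly_undisc=qaly,
        qaly_disc=qaly * df_e,
        ly_undisc=ly,
        ly_disc=ly * df_e,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class ArmSummary:
    """Per-arm lifetime totals with the five-category cost breakdown."""

    arm: str
    cost_by_category: dict  # discounted
    cost_by_category_undisc: dict
    qalys: float
    qalys_undisc: float
    life_years: float
    life_years_undisc: float
    strokes: float
    hf_onsets: float
    reablations_12m: float
    reablations_horizon: float
    time_in_states: dict

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_by_category.values()))

    @property
    def total_cost_undisc(self) -> float:
        return float(sum(self.cost_by_category_undisc.values()))


def summarize_arm(allocation, trace) -> ArmSummary:
    """Combine year-one tree accruals with the Markov phase into arm totals.

    The grand total equals the sum of the category totals exactly.
    """
    from .markov import lifetime_ablations, time_in_states

    cost_d = {}
    cost_u = {}
    for cat in COST_CATEGORIES:
        cost_d[cat] = float(allocation.year1_cost_disc[cat] + trace.cost_disc[cat].sum())
        cost_u[cat] = float(allocation.year1_cost_undisc[cat] + trace.cost_undisc[cat].sum())
    abls = lifetime_ablations(trace, allocation)
    tis_markov = time_in_states(trace)
    tis = {
        g: allocation.year1_time_in_states.get(g, 0.0) + tis_markov[g]
        for g in tis_markov
    }
    return ArmSummary(
        arm=trace.arm,
        cost_by_category=cost_d,
        cost_by_category_undisc=cost_u,
        qalys=float(allocation.year1_qalys_disc + trace.qaly_disc.sum()),
        qalys_undisc=float(allocation.year1_qalys_undisc + trace.qaly_undisc.sum()),
        life_years=float(allocation.year1_ly_disc + trace.ly_disc.sum()),
        life_years_undisc=float(allocation.year1_ly_undisc + trace.ly_undisc.sum()),
        strokes=float(allocation.year1_strokes + trace.strokes.sum()),
        hf_onsets=float(allocation.year1_hf_onsets + trace.hf_onsets.sum()),
        reablations_12m=abls["twelve_months"],
        reablations_horizon=abls["horizon"],
        time_in_states=tis,
    )


DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def compute_icer(delta_cost: float, delta_effect: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance flag.

    'dominant' when the intervention saves money and gains health,
    'dominated' when it costs more and loses health, 'undefined' at zero
    incremental effect.
    """
    if delta_effect == 0.0:
        return UNDEFINED
    if delta_cost <= 0.0 and delta_effect > 0.0:
        return DOMINANT
    if delta_cost > 0.0 and delta_effect < 0.0:
        return DOMINATED
    return delta_cost / delta_effect


def compute_nmb(delta_cost: float, delta_effect: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_effect - delta_cost


@dataclass
class CEResult:
    """Deterministic incremental cost-effectiveness comparison of two arms."""

    intervention: ArmSummary
    comparator: ArmSummary
    wtp: float
    delta_cost: float = field(init=False)
    delta_qalys: float = field(init=False)
    delta_life_years: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_cost = self.intervention.total_cost - self.comparator.total_cost
        self.delta_qalys = self.intervention.qalys - self.comparator.qalys
        self.delta_life_years = self.intervention.life_years - self.comparator.life_years

    @property
    def icer(self) -> float | str:
        return compute_icer(self.delta_cost, self.delta_qalys)

    @property
    def nmb(self) -> float:
        return compute_nmb(self.delta_cost, self.delta_qalys, self.wtp)


@dataclass
class EventMetrics:
    """Lifetime event-rate comparison for one adverse-event type."""

    event: str
    rate_intervention: float
    rate_comparator: float
    absolute_difference: float
    relative_difference: float | None
    nnt: int | None
    cost_per_event_avoided: float | None


def compute_event_metrics(
    event: str,
    rate_intervention: float,
    rate_comparator: float,
    delta_cost: float,
) -> EventMetrics:
    """NNT, relative reduction and cost per event avoided from lifetime rates.

    NNT uses the ceiling of the reciprocal absolute risk difference; both
    NNT and cost per event avoided are undefined (None) at zero difference.
    """
    diff = rate_intervention - rate_comparator
    rel = diff / rate_comparator if rate_comparator != 0.0 else None
    if diff == 0.0:
        return EventMetrics(event, rate_intervention, rate_comparator, 0.0, rel, None, None)
    # ceiling convention, guarded against float noise in the reciprocal
    nnt = math.ceil(1.0 / abs(diff) - 1e-9)
    # negative sign marks money spent per event avoided when events fall
    cpea = delta_cost / diff
    return EventMetrics(event, rate_intervention, rate_comparator, diff, rel, nnt, cpea)
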