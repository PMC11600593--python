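"""Stroke, heart-failure and mortality probability machinery.

All clinical event inputs are annual; the cohort model runs on three-month
cycles, so every annual probability passes through the complement-power
conversion ``1 - (1 - p)**(1/4)``. Background mortality comes from a
cause-deleted life table, sex-weighted to the cohort; stroke case fatality
and heart-failure excess mortality are added on the hazard scale so the
life table is conserved in the no-event limit.
"""

from __future__ import annotations

import math

from .params import ParameterSet

CYCLES_PER_YEAR = 4


class EventRateError(ValueError):
    pass


def annual_to_cycle_prob(p_annual: float, cycles_per_year: int = CYCLES_PER_YEAR) -> float:
    """Convert an annual probability to an equivalent per-cycle probability.

    Uses the constant-hazard identity ``p_cycle = 1 - (1 - p_annual)**(1/m)``
    so that compounding m cycles recovers the annual probability exactly.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise EventRateError(f"annual probability {p_annual} outside [0, 1]")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def cycle_prob_to_annual(p_cycle: float, cycles_per_year: int = CYCLES_PER_YEAR) -> float:
    """Inverse of :func:`annual_to_cycle_prob`."""
    if not 0.0 <= p_cycle <= 1.0:
        raise EventRateError(f"cycle probability {p_cycle} outside [0, 1]")
    return 1.0 - (1.0 - p_cycle) ** cycles_per_year


def prob_to_hazard(p: float, period_years: float = 1.0) -> float:
    """Continuous hazard equivalent to a probability over a period."""
    if not 0.0 <= p <= 1.0:
        raise EventRateError(f"probability {p} outside [0, 1]")
    if p == 1.0:
        return math.inf
    return -math.log(1.0 - p) / period_years


def hazard_to_prob(h: float, period_years: float = 1.0) -> float:
    """Probability of at least one event over a period at constant hazard."""
    if h < 0:
        raise EventRateError(f"hazard {h} must be >= 0")
    return 1.0 - math.exp(-h * period_years)


def cha2ds2vasc_at_age(baseline_score: int, age: float) -> int:
    """Cohort CHA2DS2-VASc score at a given age.

    The age components of the score add one point at 65 and a second at 75;
    all other components are frozen at their baseline contribution.
    """
    score = baseline_score
    if age >= 65:
        score += 1
    if age >= 75:
        score += 1
    return score


def stroke_annual_probability(group: str, age: float, params: ParameterSet) -> float:
    """Annual stroke probability for a rhythm state at the cohort's age."""
    score = cha2ds2vasc_at_age(params.demographics.baseline_cha2ds2vasc, age)
    table = params.risks.stroke_annual_by_score
    key = str(min(score, max(int(k) for k in table)))
    base = table[key]
    rr = params.risks.stroke_state_rr[group]
    return min(1.0, base * rr)


def stroke_cycle_probability(group: str, age: float, params: ParameterSet) -> float:
    """Per-cycle stroke probability, health-state and age dependent."""
    if group == "DEAD":
        raise EventRateError("stroke probability undefined for the dead state")
    return annual_to_cycle_prob(stroke_annual_probability(group, age, params))


def split_stroke_severity(stroke_mass: float, split: dict) -> dict:
    """Partition a stroke event mass over severity tiers; conserves mass."""
    total = sum(split.values())
    if abs(total - 1.0) > 1e-9:
        raise EventRateError(f"severity split sums to {total}, not 1")
    if any(v < 0 for v in split.values()):
        raise EventRateError("severity split has negative entries")
    return {sev: stroke_mass * frac for sev, frac in split.items()}


def hf_annual_incidence(age: float, params: ParameterSet) -> float:
    """General-population annual heart-failure incidence at an age."""
    for lo, hi, q in params.risks.hf_annual_by_age:
        if lo <= age < hi:
            return q
    raise EventRateError(f"no heart-failure age band covers age {age}")


def hf_cycle_probability(group: str, age: float, params: ParameterSet) -> float:
    """Per-cycle heart-failure onset probability for a rhythm state."""
    if group == "DEAD":
        raise EventRateError("heart-failure probability undefined for the dead state")
    rr = params.risks.hf_rr_permanent if group == "PERM" else 1.0
    annual = min(1.0, hf_annual_incidence(age, params) * rr)
    return annual_to_cycle_prob(annual)


def background_annual_mortality(age: float, params: ParameterSet) -> float:
    """Sex-weighted cause-deleted annual all-cause mortality from the life table."""
    return params.life_table.sex_weighted(age, params.demographics.male_fraction)


def combine_mortality(
    group: str,
    age: float,
    params: ParameterSet,
    hf_prevalence: float = 0.0,
) -> float:
    """Per-cycle death probability for one rhythm state.

    Adds, on the annual hazard scale: the cause-deleted background hazard
    (sex-weighted), the stroke-attributable hazard (state/age-specific stroke
    incidence times 30-day case fatality) and the heart-failure excess hazard
    scaled by the prevalent-HF fraction in the state. The summed hazard is
    converted to a three-month probability.
    """
    if not 0.0 <= hf_prevalence <= 1.0:
        raise EventRateError(f"hf_prevalence {hf_prevalence} outside [0, 1]")
    h = prob_to_hazard(background_annual_mortality(age, params))
    stroke_annual = stroke_annual_probability(group, age, params)
    h += prob_to_hazard(min(1.0, stroke_annual)) * params.risks.stroke_case_fatality
    h += hf_prevalence * prob_to_hazard(params.risks.hf_excess_mortality_annual)
    return hazard_to_prob(h, period_years=1.0 / CYCLES_PER_YEAR)
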