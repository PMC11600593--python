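"""Cohort state-transition engine.

Builds the per-cycle 14-state transition matrix (rhythm transitions, repeat
ablations with a three-procedure lifetime cap, competing-risk mortality) and
propagates the cohort over quarterly cycles, tallying clinical events and
cost/QALY accruals. The decision tree covering the first model year reuses
the same cycle runner (see :mod:`afibcea.tree`) so that tree and Markov
transition logic cannot drift apart.

Conventions
-----------
* Death is evaluated first as a competing risk; rhythm and ablation
  transitions apply to survivors.
* Stroke and heart-failure sequelae are carried as cohort-level prevalence
  masses (fractions of the initial cohort, uniform across living states);
  deaths remove prevalence proportionally.
* No half-cycle correction by default (configurable in Settings).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import clinical, states
from .params import ARMS, NYHA, SEVERITIES, ParameterSet

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-10


class EngineError(ValueError):
    pass


@dataclass
class TransitionAux:
    """Per-state event probabilities that accompany a transition matrix."""

    p_death: np.ndarray  # (14,)
    p_reablation: np.ndarray  # (14,) unconditional on start-of-cycle occupancy
    p_blanked: np.ndarray  # (14,) ablation failures reclassified under blanking


def _clip_prob(p: float, what: str) -> float:
    if p < 0.0:
        raise EngineError(f"negative probability for {what}: {p}")
    if p > 1.0:
        logger.debug("probability cap applied for %s: %.6f -> 1.0", what, p)
        return 1.0
    return p


def build_transition_matrix(
    params: ParameterSet,
    arm: str,
    age: float,
    hf_prevalence: float = 0.0,
    tree_mode: bool = False,
) -> tuple[np.ndarray, TransitionAux]:
    """One-cycle transition matrix for an arm at a cohort age.

    ``hf_prevalence`` is the prevalent-heart-failure fraction among the
    living, feeding the excess-mortality hazard. ``tree_mode`` disables
    progression beyond the ST-episodic state, restricting outcomes to the
    decision tree's three health states (NSR, ST-episodic, death).

    The index procedure in the cryoablation arm counts toward the lifetime
    cap of three ablations but not toward the substate index k.
    """
    if arm not in ARMS:
        raise EngineError(f"unknown arm {arm!r} (valid: {ARMS})")
    risks = params.risks
    blanking = params.settings.blanking_period_active
    arm_offset = 1 if arm == "cryoablation" else 0
    max_total = params.settings.max_total_ablations

    n = states.N_STATES
    M = np.zeros((n, n))
    p_death = np.zeros(n)
    p_reabl = np.zeros(n)
    p_blank = np.zeros(n)

    success = _clip_prob(risks.ablation_success, "ablation_success")

    for s in range(n):
        g = states.group_of(s)
        if g == "DEAD":
            M[s, states.DEAD] = 1.0
            continue
        k = states.substate_of(s)
        pd = clinical.combine_mortality(g, age, params, hf_prevalence=hf_prevalence)
        p_death[s] = pd
        M[s, states.DEAD] = pd
        surv = 1.0 - pd

        cond = np.zeros(n)  # transition row conditional on surviving the cycle
        if g == "NSR":
            p_rec = _clip_prob(
                risks.recurrence[arm] * risks.rr_recurrence_by_count[k],
                f"recurrence NSR_{k}",
            )
            cond[states.ST[k]] += p_rec
            cond[s] += 1.0 - p_rec
        elif g in ("ST", "LT"):
            can_ablate = (k + arm_offset) < max_total
            p_abl = risks.reablation[g][arm] if can_ablate else 0.0
            p_abl = _clip_prob(p_abl, f"reablation {g}_{k}")
            if p_abl > 0.0:
                k1 = k + 1
                cond[states.NSR[k1]] += p_abl * success
                fail = p_abl * (1.0 - success)
                if blanking:
                    # recurrence in the first post-ablation quarter is not a
                    # treatment failure: the mass is booked back to NSR
                    cond[states.NSR[k1]] += fail
                    p_blank[s] = surv * fail
                else:
                    cond[states.ST[k1]] += fail
                p_reabl[s] = surv * p_abl
            rest = 1.0 - p_abl
            if g == "ST":
                p_res = _clip_prob(
                    risks.resolution[arm] * risks.rr_resolution_by_count[k],
                    f"resolution ST_{k}",
                )
                p_prog = 0.0 if tree_mode else risks.progression_st_to_lt
                if p_res + p_prog > 1.0:
                    scale = 1.0 / (p_res + p_prog)
                    logger.debug("joint cap on ST_%d resolution+progression", k)
                    p_res *= scale
                    p_prog *= scale
                cond[states.NSR[k]] += rest * p_res
                if p_prog:
                    cond[states.LT[k]] += rest * p_prog
                cond[s] += rest * (1.0 - p_res - p_prog)
            else:  # LT
                p_perm = 0.0 if tree_mode else risks.progression_lt_to_perm
                p_rem = risks.remission_lt_to_st
                if p_perm + p_rem > 1.0:
                    scale = 1.0 / (p_perm + p_rem)
                    p_perm *= scale
                    p_rem *= scale
                if p_perm:
                    cond[states.PERM] += rest * p_perm
                if p_rem:
                    cond[states.ST[k]] += rest * p_rem
                cond[s] += rest * (1.0 - p_perm - p_rem)
        elif g == "PERM":
            cond[s] = 1.0
        M[s, : states.DEAD] += surv * cond[: states.DEAD]
        M[s, states.DEAD] += surv * cond[states.DEAD]

    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > ROW_SUM_TOL):
        worst = int(np.argmax(np.abs(rowsum - 1.0)))
        raise EngineError(
            f"transition row for {states.STATES[worst]} sums to {rowsum[worst]!r}"
        )
    return M, TransitionAux(p_death=p_death, p_reablation=p_reabl, p_blanked=p_blank)


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """Per-cycle occupancy, events, prevalence paths and accruals.

    ``occupancy`` has ``n_cycles + 1`` rows (cycle 0 is the initial
    allocation); events and accruals have one entry per transition cycle.
    Costs are keyed by reporting category. ``global_offset`` is the quarterly
    index of the first cycle on the model-wide discounting clock (4 for the
    Markov phase, 0 for the decision tree).
    """

    arm: str
    occupancy: np.ndarray  # (n+1, 14)
    ages: np.ndarray  # (n,) cohort age at the start of each cycle
    global_offset: int
    deaths: np.ndarray
    strokes: np.ndarray  # (n, 3) by severity, fatal and non-fatal
    hf_onsets: np.ndarray
    ablations: np.ndarray
    pharm_cv: np.ndarray
    elec_cv: np.ndarray
    blanked: np.ndarray
    stroke_prev: np.ndarray  # (n+1, 3) prevalence masses by severity
    hf_prev: np.ndarray  # (n+1, 4) prevalence masses by NYHA class
    cost_undisc: dict  # category -> (n,)
    cost_disc: dict
    qaly_undisc: np.ndarray
    qaly_disc: np.ndarray
    ly_undisc: np.ndarray
    ly_disc: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    def check_invariants(self, tol: float = 1e-9) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > tol):
            raise EngineError("occupancy rows do not sum to 1")
        dead = self.occupancy[:, states.DEAD]
        if np.any(np.diff(dead) < -tol):
            raise EngineError("dead occupancy is not monotone non-decreasing")

    def to_frame(self):
        """Cycle-by-cycle export (one row per transition cycle)."""
        import pandas as pd

        n = self.n_cycles
        data = {"cycle": np.arange(n), "age": self.ages}
        for i, s in enumerate(states.STATES):
            data[f"occ_{s}"] = self.occupancy[:n, i]
        data["deaths"] = self.deaths
        for j, sev in enumerate(SEVERITIES):
            data[f"strokes_{sev}"] = self.strokes[:, j]
        data["hf_onsets"] = self.hf_onsets
        data["ablations"] = self.ablations
        data["pharm_cv"] = self.pharm_cv
        data["elec_cv"] = self.elec_cv
        data["blanked_recurrences"] = self.blanked
        for cat, arr in self.cost_undisc.items():
            data[f"cost_{cat}"] = arr
        for cat, arr in self.cost_disc.items():
            data[f"cost_disc_{cat}"] = arr
        data["qaly"] = self.qaly_undisc
        data["qaly_disc"] = self.qaly_disc
        data["life_years"] = self.ly_undisc
        return pd.DataFrame(data)


def run_cycles(
    params: ParameterSet,
    arm: str,
    occupancy0: np.ndarray,
    n_cycles: int,
    start_age: float,
    global_offset: int,
    tree_mode: bool = False,
    stroke_prev0: np.ndarray | None = None,
    hf_prev0: np.ndarray | None = None,
) -> Trace:
    """Propagate the cohort for ``n_cycles`` quarterly cycles.

    The shared engine behind both the decision tree and the Markov phase.
    """
    from . import economics  # deferred to avoid an import cycle

    occ0 = np.asarray(occupancy0, dtype=float)
    if occ0.shape != (states.N_STATES,):
        raise EngineError(f"occupancy must have shape ({states.N_STATES},)")
    if abs(occ0.sum() - 1.0) > 1e-9 or np.any(occ0 < -1e-12):
        raise EngineError("initial occupancy must be a distribution")

    cl = params.settings.cycle_length
    occ = np.zeros((n_cycles + 1, states.N_STATES))
    occ[0] = occ0
    ages = start_age + cl * np.arange(n_cycles)
    stroke_prev = np.zeros((n_cycles + 1, len(SEVERITIES)))
    hf_prev = np.zeros((n_cycles + 1, len(NYHA)))
    if stroke_prev0 is not None:
        stroke_prev[0] = stroke_prev0
    if hf_prev0 is not None:
        hf_prev[0] = hf_prev0

    deaths = np.zeros(n_cycles)
    strokes = np.zeros((n_cycles, len(SEVERITIES)))
    hf_onsets = np.zeros(n_cycles)
    ablations = np.zeros(n_cycles)
    pharm_cv = np.zeros(n_cycles)
    elec_cv = np.zeros(n_cycles)
    blanked = np.zeros(n_cycles)
    cats = economics.COST_CATEGORIES
    cost_u = {c: np.zeros(n_cycles) for c in cats}
    cost_d = {c: np.zeros(n_cycles) for c in cats}
    qaly_u = np.zeros(n_cycles)
    qaly_d = np.zeros(n_cycles)
    ly_u = np.zeros(n_cycles)
    ly_d = np.zeros(n_cycles)

    sev_split = np.array([params.risks.stroke_severity_split[s] for s in SEVERITIES])
    nyha_split = np.array([params.risks.hf_nyha_split[c] for c in NYHA])
    case_fatality = params.risks.stroke_case_fatality

    for t in range(n_cycles):
        o = occ[t]
        age = float(ages[t])
        alive = float(o[list(states.LIVING)].sum())
        hf_frac = float(hf_prev[t].sum() / alive) if alive > 1e-15 else 0.0
        hf_frac = min(1.0, hf_frac)
        M, aux = build_transition_matrix(
            params, arm, age, hf_prevalence=hf_frac, tree_mode=tree_mode
        )

        # event tallies on start-of-cycle occupancy
        deaths[t] = float(o @ aux.p_death)
        ablations[t] = float(o @ aux.p_reablation)
        blanked[t] = float(o @ aux.p_blanked)
        stroke_mass = 0.0
        hf_mass = 0.0
        for s in states.LIVING:
            if o[s] <= 0.0:
                continue
            g = states.group_of(s)
            stroke_mass += o[s] * clinical.stroke_cycle_probability(g, age, params)
            hf_mass += o[s] * clinical.hf_cycle_probability(g, age, params)
            util = params.risks.utilization
            pharm_cv[t] += o[s] * util["pharm_cardioversion"][arm][g]
            elec_cv[t] += o[s] * util["elec_cardioversion"][arm][g]
        strokes[t] = stroke_mass * sev_split
        hf_onsets[t] = hf_mass * (1.0 - hf_frac)

        acc = economics.accrue_cycle(
            occupancy=o,
            strokes=strokes[t],
            ablations=ablations[t],
            blanked=blanked[t],
            stroke_prev=stroke_prev[t],
            hf_prev=hf_prev[t],
            age=age,
            arm=arm,
            global_cycle=global_offset + t,
            params=params,
        )
        for c in cats:
            cost_u[c][t] = acc.cost_undisc[c]
            cost_d[c][t] = acc.cost_disc[c]
        qaly_u[t] = acc.qaly_undisc
        qaly_d[t] = acc.qaly_disc
        ly_u[t] = acc.ly_undisc
        ly_d[t] = acc.ly_disc

        # advance occupancy and prevalence
        occ[t + 1] = o @ M
        death_frac = deaths[t] / alive if alive > 1e-15 else 0.0
        keep = max(0.0, 1.0 - death_frac)
        stroke_prev[t + 1] = stroke_prev[t] * keep + strokes[t] * (1.0 - case_fatality)
        hf_prev[t + 1] = hf_prev[t] * keep + hf_onsets[t] * nyha_split

    trace = Trace(
        arm=arm,
        occupancy=occ,
        ages=ages,
        global_offset=global_offset,
        deaths=deaths,
        strokes=strokes,
        hf_onsets=hf_onsets,
        ablations=ablations,
        pharm_cv=pharm_cv,
        elec_cv=elec_cv,
        blanked=blanked,
        stroke_prev=stroke_prev,
        hf_prev=hf_prev,
        cost_undisc=cost_u,
        cost_disc=cost_d,
        qaly_undisc=qaly_u,
        qaly_disc=qaly_d,
        ly_undisc=ly_u,
        ly_disc=ly_d,
    )
    trace.check_invariants()
    return trace


def run_markov(params: ParameterSet, allocation, arm: str) -> Trace:
    """Run the lifetime Markov phase from a decision-tree allocation.

    Covers ``settings.horizon`` years (160 quarterly cycles in the base
    case) starting one tree-horizon after model entry; discounting continues
    on the model-wide quarterly clock.
    """
    s = params.settings
    return run_cycles(
        params,
        arm,
        occupancy0=allocation.occupancy,
        n_cycles=s.n_cycles,
        start_age=params.demographics.baseline_age + s.tree_horizon,
        global_offset=s.n_tree_cycles,
        tree_mode=False,
        stroke_prev0=allocation.stroke_prev,
        hf_prev0=allocation.hf_prev,
    )


def time_in_states(trace: Trace, cycle_length: float = 0.25) -> dict:
    """Undiscounted years spent in each rhythm-state group (substates pooled).

    Sums start-of-cycle occupancy over the transition cycles; together with
    years dead this partitions the trace horizon exactly.
    """
    n = trace.n_cycles
    out = {}
    for g, members in states.GROUP_MEMBERS.items():
        out[g] = float(trace.occupancy[:n, list(members)].sum() * cycle_length)
    return out


def lifetime_ablations(trace: Trace, allocation) -> dict:
    """Mean ablations per person, excluding the cryoablation index procedure.

    Reported at twelve months (decision-tree phase) and at the full horizon.
    """
    at_12m = float(allocation.year1_reablations)
    return {
        "twelve_months": at_12m,
        "horizon": at_12m + float(trace.ablations.sum()),
    }
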