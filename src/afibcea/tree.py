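"""Decision tree for the first model year.

The first twelve months are evaluated as four sequential quarterly periods
using the same transition logic as the Markov engine, restricted to the
tree's three outcomes (NSR, ST-episodic, death). The cryoablation arm pays
the index procedure at entry; its outcome (return to NSR for the first
90-day cycle, with probability ``risks.ablation_success``) sets the starting
state. The antiarrhythmic-drug arm starts on drug therapy in the ST-episodic
state; any ablation it receives is a crossover counted — and costed — as a
re-ablation. The end-of-year occupancy, with its re-ablation substate
counts, becomes the initial Markov allocation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import economics, states
from .markov import EngineError, Trace, run_cycles
from .params import ParameterSet


@dataclass
class InitialAllocation:
    """End-of-tree state allocation plus the year-one books.

    ``occupancy`` spans the full 14-state space (LT/PERM entries are zero by
    construction of the three-state tree). Costs are keyed by reporting
    category; ``year1_reablations`` excludes the cryoablation index
    procedure.
    """

    arm: str
    occupancy: np.ndarray
    year1_cost_undisc: dict
    year1_cost_disc: dict
    year1_qalys_undisc: float
    year1_qalys_disc: float
    year1_ly_undisc: float
    year1_ly_disc: float
    year1_reablations: float
    year1_strokes: float
    year1_hf_onsets: float
    year1_time_in_states: dict
    stroke_prev: np.ndarray
    hf_prev: np.ndarray
    trace: Trace

    def check_invariants(self, tol: float = 1e-12) -> None:
        if abs(self.occupancy.sum() - 1.0) > tol:
            raise EngineError("tree allocation does not sum to 1")
        if np.any(self.occupancy < -tol):
            raise EngineError("tree allocation has negative occupancy")


def run_decision_tree(params: ParameterSet, arm: str) -> InitialAllocation:
    """Evaluate the one-year decision tree for one treatment arm."""
    if arm not in ("cryoablation", "aad"):
        raise EngineError(f"unknown arm {arm!r}")
    s = params.settings
    c = params.costs

    occ0 = np.zeros(states.N_STATES)
    entry_cost = 0.0
    blanked_entry = 0.0
    if arm == "cryoablation":
        # index procedure at entry; outcome decides the first-cycle state
        entry_cost = c.ablation_procedure
        success = params.risks.ablation_success
        if s.blanking_period_active:
            # early recurrence after the index ablation is not a failure
            occ0[states.INDEX["NSR_0"]] = 1.0
            blanked_entry = 1.0 - success
        else:
            occ0[states.INDEX["NSR_0"]] = success
            occ0[states.INDEX["ST_0"]] = 1.0 - success
    else:
        occ0[states.INDEX["ST_0"]] = 1.0

    trace = run_cycles(
        params,
        arm,
        occupancy0=occ0,
        n_cycles=s.n_tree_cycles,
        start_age=params.demographics.baseline_age,
        global_offset=0,
        tree_mode=True,
    )

    cost_u = {cat: float(trace.cost_undisc[cat].sum()) for cat in economics.COST_CATEGORIES}
    cost_d = {cat: float(trace.cost_disc[cat].sum()) for cat in economics.COST_CATEGORIES}
    # entry procedure cost at t=0 is undiscounted by construction
    cost_u["initial_procedure"] += entry_cost
    cost_d["initial_procedure"] += entry_cost
    if blanked_entry > 0.0:
        extra = blanked_entry * (
            economics._contact_cost_per_person("ST", arm, params)
            - economics._contact_cost_per_person("NSR", arm, params)
        )
        cost_u["healthcare_contacts"] += extra
        cost_d["healthcare_contacts"] += extra  # cycle 0: discount factor 1

    from .markov import time_in_states

    alloc = InitialAllocation(
        arm=arm,
        occupancy=trace.occupancy[-1].copy(),
        year1_cost_undisc=cost_u,
        year1_cost_disc=cost_d,
        year1_qalys_undisc=float(trace.qaly_undisc.sum()),
        year1_qalys_disc=float(trace.qaly_disc.sum()),
        year1_ly_undisc=float(trace.ly_undisc.sum()),
        year1_ly_disc=float(trace.ly_disc.sum()),
        year1_reablations=float(trace.ablations.sum()),
        year1_strokes=float(trace.strokes.sum()),
        year1_hf_onsets=float(trace.hf_onsets.sum()),
        year1_time_in_states=time_in_states(trace),
        stroke_prev=trace.stroke_prev[-1].copy(),
        hf_prev=trace.hf_prev[-1].copy(),
        trace=trace,
    )
    alloc.check_invariants()
    return alloc
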