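"""Individual-level microsimulation cross-check of the cohort engine.

Walks a large number of simulated individuals through the same per-cycle
transition probabilities the cohort engine uses, sampling each transition
and clinical event, and reports empirical occupancy and cumulative event
counts with Monte-Carlo standard errors. The cohort trace's deterministic
linear-algebra propagation should agree with the microsimulation within a
few standard errors; any systematic discrepancy flags an engine defect.

The heart-failure mortality feedback uses the microsimulation's own
empirical prevalent-HF fraction each cycle, so the two engines share only
the transition-probability construction, not the propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import clinical, states
from .markov import build_transition_matrix
from .params import SEVERITIES, ParameterSet


@dataclass
class MicrosimResult:
    n_walkers: int
    occupancy: np.ndarray  # (n_cycles + 1, 14) empirical fractions
    deaths: np.ndarray  # per-cycle fractions
    strokes: np.ndarray  # (n_cycles, 3)
    hf_onsets: np.ndarray
    ablations: np.ndarray
    mean_ablation_count: float  # per person over the simulated span
    se_ablation_count: float  # Monte-Carlo SE of the per-person mean
    mean_stroke_count: float
    se_stroke_count: float

    def occupancy_se(self) -> np.ndarray:
        p = self.occupancy
        return np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / self.n_walkers)

    def cumulative_events(self) -> dict:
        return {
            "deaths": float(self.deaths.sum()),
            "strokes": float(self.strokes.sum()),
            "hf_onsets": float(self.hf_onsets.sum()),
            "ablations": float(self.ablations.sum()),
        }


def _ablation_indicator() -> np.ndarray:
    """Lookup A[from, to]: the transition implies an ablation procedure."""
    n = states.N_STATES
    A = np.zeros((n, n), dtype=bool)
    for s in range(n):
        g = states.group_of(s)
        if g not in ("ST", "LT"):
            continue
        k = states.substate_of(s)
        if k + 1 >= states.N_SUBSTATES:
            continue
        for t in (states.NSR[k + 1], states.ST[k + 1]):
            A[s, t] = True
    return A


def run_microsim(
    params: ParameterSet,
    arm: str,
    occupancy0: np.ndarray,
    n_cycles: int,
    start_age: float,
    n_walkers: int = 100_000,
    seed: int = 0,
    tree_mode: bool = False,
) -> MicrosimResult:
    """Simulate individual trajectories over quarterly cycles."""
    rng = np.random.default_rng(seed)
    occ0 = np.asarray(occupancy0, dtype=float)
    state = rng.choice(states.N_STATES, size=n_walkers, p=occ0 / occ0.sum())
    has_hf = np.zeros(n_walkers, dtype=bool)
    abl_count = np.zeros(n_walkers, dtype=np.int64)
    stroke_count = np.zeros(n_walkers, dtype=np.int64)
    A = _ablation_indicator()

    cl = params.settings.cycle_length
    occupancy = np.zeros((n_cycles + 1, states.N_STATES))
    occupancy[0] = np.bincount(state, minlength=states.N_STATES) / n_walkers
    deaths = np.zeros(n_cycles)
    strokes = np.zeros((n_cycles, len(SEVERITIES)))
    hf_onsets = np.zeros(n_cycles)
    ablations = np.zeros(n_cycles)
    sev_cum = np.cumsum([params.risks.stroke_severity_split[s] for s in SEVERITIES])

    for t in range(n_cycles):
        age = start_age + cl * t
        alive = state != states.DEAD
        n_alive = int(alive.sum())
        if n_alive == 0:
            occupancy[t + 1 :] = occupancy[t]
            break
        hf_frac = float(has_hf[alive].mean())
        M, _aux = build_transition_matrix(
            params, arm, age, hf_prevalence=hf_frac, tree_mode=tree_mode
        )

        # clinical event sampling on start-of-cycle states
        p_stroke = np.zeros(states.N_STATES)
        p_hf = np.zeros(states.N_STATES)
        for s in states.LIVING:
            g = states.group_of(s)
            p_stroke[s] = clinical.stroke_cycle_probability(g, age, params)
            p_hf[s] = clinical.hf_cycle_probability(g, age, params)
        u = rng.random(n_walkers)
        stroke_hit = alive & (u < p_stroke[state])
        stroke_count += stroke_hit
        n_strokes = int(stroke_hit.sum())
        if n_strokes:
            sev_idx = np.searchsorted(sev_cum, rng.random(n_strokes), side="right")
            sev_idx = np.clip(sev_idx, 0, len(SEVERITIES) - 1)
            strokes[t] = np.bincount(sev_idx, minlength=len(SEVERITIES)) / n_walkers
        hf_hit = alive & ~has_hf & (rng.random(n_walkers) < p_hf[state])
        hf_onsets[t] = hf_hit.sum() / n_walkers
        has_hf |= hf_hit

        # state transition sampling
        cum = np.cumsum(M, axis=1)
        draw = rng.random(n_walkers)
        rows = cum[state]
        new_state = (draw[:, None] > rows).sum(axis=1)
        new_state = np.minimum(new_state, states.N_STATES - 1)
        moved_abl = A[state, new_state]
        ablations[t] = moved_abl.sum() / n_walkers
        abl_count += moved_abl
        died = alive & (new_state == states.DEAD)
        deaths[t] = died.sum() / n_walkers
        has_hf &= ~died  # the dead carry no prevalence
        state = new_state
        occupancy[t + 1] = np.bincount(state, minlength=states.N_STATES) / n_walkers

    root_n = math.sqrt(n_walkers)
    return MicrosimResult(
        n_walkers=n_walkers,
        occupancy=occupancy,
        deaths=deaths,
        strokes=strokes,
        hf_onsets=hf_onsets,
        ablations=ablations,
        mean_ablation_count=float(abl_count.mean()),
        se_ablation_count=float(abl_count.std(ddof=1) / root_n),
        mean_stroke_count=float(stroke_count.mean()),
        se_stroke_count=float(stroke_count.std(ddof=1) / root_n),
    )
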