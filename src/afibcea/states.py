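"""Markov state space for the AF rhythm-control cohort model.

Five rhythm states — normal sinus rhythm (NSR), short-term episodic AF (ST),
long-term persistent AF (LT), permanent AF (PERM) — plus death. NSR, ST and LT
each carry a substate index k in {0,1,2,3} counting re-ablations received
(the index procedure in the cryoablation arm is excluded from k), giving
14 states in total with DEAD last.
"""

from __future__ import annotations

N_SUBSTATES = 4

GROUPS = ("NSR", "ST", "LT", "PERM", "DEAD")

STATES: tuple[str, ...] = tuple(
    f"{g}_{k}" for g in ("NSR", "ST", "LT") for k in range(N_SUBSTATES)
) + ("PERM", "DEAD")

N_STATES = len(STATES)  # 14

INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}

NSR = tuple(INDEX[f"NSR_{k}"] for k in range(N_SUBSTATES))
ST = tuple(INDEX[f"ST_{k}"] for k in range(N_SUBSTATES))
LT = tuple(INDEX[f"LT_{k}"] for k in range(N_SUBSTATES))
PERM = INDEX["PERM"]
DEAD = INDEX["DEAD"]

LIVING = tuple(i for i in range(N_STATES) if i != DEAD)


def group_of(state: str | int) -> str:
    """Rhythm group ('NSR', 'ST', 'LT', 'PERM' or 'DEAD') of a state."""
    name = STATES[state] if isinstance(state, int) else state
    return name.split("_")[0]


def substate_of(state: str | int) -> int:
    """Re-ablation count k of a state; PERM and DEAD report the cap (3)."""
    name = STATES[state] if isinstance(state, int) else state
    parts = name.split("_")
    return int(parts[1]) if len(parts) == 2 else N_SUBSTATES - 1


GROUP_MEMBERS: dict[str, tuple[int, ...]] = {
    "NSR": NSR,
    "ST": ST,
    "LT": LT,
    "PERM": (PERM,),
    "DEAD": (DEAD,),
}
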