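"""Shared fixtures: the synthetic base case and derived model runs.

Session-scoped fixtures are treated as read-only; tests that need to modify
parameters must copy them first (``params.copy()``).
"""

from __future__ import annotations

import numpy as np
import pytest

from afibcea import generate_parameter_set, run_deterministic
from afibcea.params import ParameterSet
from afibcea.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return generate_parameter_set(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def base_result(base_params):
    return run_deterministic(base_params)


@pytest.fixture()
def zero_risk_params(base_params) -> ParameterSet:
    """All clinical transitions and mortality off: forced-path setting."""
    p = base_params.copy()
    p.risks.recurrence = {"cryoablation": 0.0, "aad": 0.0}
    p.risks.resolution = {"cryoablation": 0.0, "aad": 0.0}
    p.risks.progression_st_to_lt = 0.0
    p.risks.progression_lt_to_perm = 0.0
    p.risks.reablation = {"ST": {"cryoablation": 0.0, "aad": 0.0},
                          "LT": {"cryoablation": 0.0, "aad": 0.0}}
    p.risks.ablation_success = 1.0
    p.risks.stroke_annual_by_score = {k: 0.0 for k in p.risks.stroke_annual_by_score}
    p.risks.stroke_case_fatality = 0.0
    p.risks.hf_annual_by_age = [[0, 121, 0.0]]
    p.risks.hf_excess_mortality_annual = 0.0
    p.life_table.q_male = np.zeros_like(p.life_table.q_male)
    p.life_table.q_female = np.zeros_like(p.life_table.q_female)
    return p
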