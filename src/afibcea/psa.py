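"""Probabilistic sensitivity analysis.

Each iteration draws a full parameter realization — gamma for costs, beta
for probabilities and utility decrements (moment-matched to mean and
standard error), a correlated multivariate-normal draw on the logit scale
for the trial-regression-derived per-cycle probabilities via a Cholesky
factor — and reruns the whole tree + Markov pipeline for both arms.
Summaries follow the standard conventions: empirical 2.5/97.5-percentile
credible intervals, mean ICER as ratio of mean increments, probability
cost-effective from net monetary benefit, and a cost-effectiveness
acceptability curve over a willingness-to-pay grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import economics
from .model import run_arm
from .params import (
    ARMS,
    NYHA,
    SEVERITIES,
    ParameterSet,
    get_path,
    set_path,
)

__all__ = [
    "fit_gamma",
    "fit_beta",
    "sample_coefficients",
    "run_psa",
    "ceac",
    "PSAResult",
    "sampled_scalar_paths",
    "draw_parameter_set",
]


class DistributionError(ValueError):
    pass


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale) for a cost parameter."""
    if mean <= 0 or se <= 0:
        raise DistributionError("gamma moment matching needs mean > 0 and se > 0")
    shape = mean * mean / (se * se)
    scale = se * se / mean
    return shape, scale


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Moment-matched beta (alpha, beta) for a probability or utility."""
    if not 0.0 < mean < 1.0:
        raise DistributionError("beta moment matching needs 0 < mean < 1")
    var = se * se
    bound = mean * (1.0 - mean)
    if var <= 0 or var >= bound:
        raise DistributionError(
            f"beta moment matching needs 0 < se^2 < mean(1-mean) = {bound:.6g}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_coefficients(
    mean_vector: np.ndarray, cholesky_factor: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Correlated normal draw: mean + L @ z with z ~ N(0, I)."""
    mean_vector = np.asarray(mean_vector, dtype=float)
    L = np.asarray(cholesky_factor, dtype=float)
    d = mean_vector.shape[0]
    if L.shape != (d, d):
        raise DistributionError(
            f"cholesky factor shape {L.shape} does not match mean dimension {d}"
        )
    if not np.allclose(L, np.tril(L)):
        raise DistributionError("cholesky factor must be lower-triangular")
    z = rng.standard_normal(d)
    return mean_vector + L @ z


# ---------------------------------------------------------------------------
# parameter sampling plan
# ---------------------------------------------------------------------------

# scalar cost parameters -> gamma
_COST_PATHS = (
    "costs.ablation_procedure",
    "costs.cv_hospitalization_per_cycle",
    "costs.ed_visit_per_cycle",
    "costs.outpatient_per_cycle",
    "costs.pharm_cardioversion",
    "costs.elec_cardioversion",
    "costs.stroke_longterm_per_cycle",
) + tuple(f"costs.stroke_acute.{sev}" for sev in SEVERITIES) + tuple(
    f"costs.hf_per_cycle.{cls}" for cls in NYHA
) + tuple(f"costs.pharma_per_cycle.{arm}" for arm in ARMS)

# probability / utility parameters -> beta
_BETA_PATHS = (
    "risks.ablation_success",
    "risks.stroke_case_fatality",
    "risks.hf_excess_mortality_annual",
    "utilities.decrement_st_episodic",
    "utilities.decrement_lt_persistent",
    "utilities.decrement_permanent",
) + tuple(f"risks.reablation.{g}.{arm}" for g in ("ST", "LT") for arm in ARMS)

# logit-scale coefficient block: trial-regression-derived transition inputs
COEFFICIENT_PATHS = (
    "risks.recurrence.cryoablation",
    "risks.recurrence.aad",
    "risks.resolution.cryoablation",
    "risks.resolution.aad",
    "risks.progression_st_to_lt",
    "risks.progression_lt_to_perm",
)


def sampled_scalar_paths() -> dict:
    """Dot-paths sampled each iteration, keyed by distribution family."""
    return {"gamma": _COST_PATHS, "beta": _BETA_PATHS}


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def default_coefficient_block(params: ParameterSet) -> dict:
    """Coefficient block centred on the current transition probabilities.

    Used when the config supplies none: logit-scale means with a diagonal
    factor scaled by the configured uncertainty fraction (zero uncertainty
    gives a zero factor, i.e. a degenerate block).
    """
    means = []
    diag = []
    for path in COEFFICIENT_PATHS:
        p = float(get_path(params, path))
        p = min(max(p, 1e-9), 1.0 - 1e-9)
        means.append(_logit(p))
        # se_fraction of the mean probability, propagated to the logit scale
        se_p = params.psa.se_fraction * p
        diag.append(se_p / (p * (1.0 - p)))
    d = len(means)
    factor = np.zeros((d, d))
    np.fill_diagonal(factor, diag)
    return {"names": list(COEFFICIENT_PATHS), "mean": means, "factor": factor.tolist()}


def draw_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA realization of the parameter set.

    Standard errors are ``psa.se_fraction`` of each mean (the 10% expert
    uncertainty rule in the base case); ``se_fraction = 0`` makes every
    distribution degenerate and returns the deterministic values.
    """
    frac = params.psa.se_fraction
    out = params.copy()
    if frac > 0.0:
        for path in _COST_PATHS:
            mean = float(get_path(params, path))
            if mean <= 0.0:
                continue
            shape, scale = fit_gamma(mean, frac * mean)
            set_path(out, path, float(rng.gamma(shape, scale)))
        for path in _BETA_PATHS:
            mean = float(get_path(params, path))
            if not 0.0 < mean < 1.0:
                continue
            a, b = fit_beta(mean, frac * mean)
            set_path(out, path, float(rng.beta(a, b)))
    block = params.psa.coefficient_block or default_coefficient_block(params)
    mean = np.asarray(block["mean"], dtype=float)
    factor = np.asarray(block["factor"], dtype=float)
    draw = sample_coefficients(mean, factor, rng)
    for name, x in zip(block["names"], draw):
        set_path(out, name, _expit(float(x)))
    return out


# ---------------------------------------------------------------------------
# PSA loop and summaries
# ---------------------------------------------------------------------------


@dataclass
class PSAResult:
    seed: int
    wtp: float
    cost_intervention: np.ndarray
    cost_comparator: np.ndarray
    qaly_intervention: np.ndarray
    qaly_comparator: np.ndarray
    wtp_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    ceac_values: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_iterations(self) -> int:
        return len(self.cost_intervention)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_intervention - self.cost_comparator

    @property
    def delta_qalys(self) -> np.ndarray:
        return self.qaly_intervention - self.qaly_comparator

    @property
    def mean_icer(self) -> float | str:
        return economics.compute_icer(
            float(self.delta_cost.mean()), float(self.delta_qalys.mean())
        )

    def credible_interval(self, values: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(values, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def prob_cost_effective(self) -> float:
        nmb = self.wtp * self.delta_qalys - self.delta_cost
        return float(np.mean(nmb > 0.0))

    @property
    def prob_cost_saving(self) -> float:
        return float(np.mean(self.delta_cost < 0.0))

    def summary(self) -> dict:
        dc, dq = self.delta_cost, self.delta_qalys
        icer = self.mean_icer
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "wtp": self.wtp,
            "mean_cost_intervention": float(self.cost_intervention.mean()),
            "mean_cost_comparator": float(self.cost_comparator.mean()),
            "mean_qaly_intervention": float(self.qaly_intervention.mean()),
            "mean_qaly_comparator": float(self.qaly_comparator.mean()),
            "cri_cost_intervention": self.credible_interval(self.cost_intervention),
            "cri_cost_comparator": self.credible_interval(self.cost_comparator),
            "cri_qaly_intervention": self.credible_interval(self.qaly_intervention),
            "cri_qaly_comparator": self.credible_interval(self.qaly_comparator),
            "mean_delta_cost": float(dc.mean()),
            "cri_delta_cost": self.credible_interval(dc),
            "mean_delta_qalys": float(dq.mean()),
            "cri_delta_qalys": self.credible_interval(dq),
            "mean_icer": icer if isinstance(icer, str) else float(icer),
            "prob_cost_effective": self.prob_cost_effective,
            "prob_cost_saving": self.prob_cost_saving,
        }


def run_psa(
    params: ParameterSet,
    n_iterations: int,
    seed: int,
    wtp_grid: np.ndarray | None = None,
) -> PSAResult:
    """Monte-Carlo uncertainty analysis over the full pipeline.

    One root seed spawns per-iteration substreams, so the result is
    bit-identical under a fixed seed regardless of execution order.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    params.validate()
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_iterations)
    ci = np.zeros(n_iterations)
    cc = np.zeros(n_iterations)
    qi = np.zeros(n_iterations)
    qc = np.zeros(n_iterations)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            drawn = draw_parameter_set(params, rng)
            drawn.validate()
            a = run_arm(drawn, "cryoablation")
            b = run_arm(drawn, "aad")
        except Exception as exc:
            raise RuntimeError(f"PSA iteration {i} (seed {seed}) failed: {exc}") from exc
        ci[i] = a.summary.total_cost
        cc[i] = b.summary.total_cost
        qi[i] = a.summary.qalys
        qc[i] = b.summary.qalys
    result = PSAResult(
        seed=seed,
        wtp=params.settings.wtp,
        cost_intervention=ci,
        cost_comparator=cc,
        qaly_intervention=qi,
        qaly_comparator=qc,
    )
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 100_000.0, 101)
    result.wtp_grid = np.asarray(wtp_grid, dtype=float)
    result.ceac_values = ceac(result, result.wtp_grid)
    return result


def ceac(psa_result: PSAResult, wtp_grid: np.ndarray) -> np.ndarray:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of iterations with
    positive net monetary benefit.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    dq = psa_result.delta_qalys[None, :]
    dc = psa_result.delta_cost[None, :]
    nmb = wtp_grid[:, None] * dq - dc
    return np.mean(nmb > 0.0, axis=1)
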