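"""Model parameter space: definition, validation, serialization and scenarios.

A :class:`ParameterSet` gathers everything one deterministic model run needs:
cohort demographics, run settings, German-payer unit costs, utility norms and
decrements, clinical event risks, and a sex-specific life table. Parameters
load from JSON or YAML; scenario analyses are expressed as small override
lists addressed by dot-notation paths.

Default values are the base case of the German first-line cryoablation
evaluation where published (unit costs, utility decrements, settings); the
per-cycle clinical probabilities derived from trial patient-level data are
not published, so their defaults here are synthetic stand-ins (see
:mod:`afibcea.synthetic`) and are flagged as such in the provenance log.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import yaml

from .lifetable import LifeTable

logger = logging.getLogger(__name__)

ARMS = ("cryoablation", "aad")
SEVERITIES = ("non_disabling", "moderate", "severe")
NYHA = ("I", "II", "III", "IV")
UTILIZATION_CATEGORIES = (
    "hospitalization",
    "ed_visit",
    "outpatient",
    "pharm_cardioversion",
    "elec_cardioversion",
)


class ValidationError(ValueError):
    """A parameter violated its invariant; the message names the field."""


class ScenarioError(ValueError):
    """A scenario override referenced an unknown parameter path."""


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass
class Demographics:
    baseline_age: float = 57.5
    cohort_size: float = 1000.0
    male_fraction: float = 0.65  # placeholder: pooled-trial sex split unpublished
    baseline_cha2ds2vasc: int = 1

    def validate(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValidationError("demographics.male_fraction must be in [0, 1]")
        if self.cohort_size <= 0:
            raise ValidationError("demographics.cohort_size must be > 0")
        if self.baseline_cha2ds2vasc < 0:
            raise ValidationError("demographics.baseline_cha2ds2vasc must be >= 0")


@dataclass
class Settings:
    cycle_length: float = 0.25  # years; three-month Markov cycle
    horizon: float = 40.0  # years in the Markov model
    tree_horizon: float = 1.0  # years in the decision tree
    discount_rate_costs: float = 0.03
    discount_rate_effects: float = 0.03
    wtp: float = 35_000.0  # € per QALY gained
    max_total_ablations: int = 3  # including the index procedure
    blanking_period_active: bool = False
    half_cycle_correction: bool = False  # sensitivity switch; off by default

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))

    @property
    def n_tree_cycles(self) -> int:
        return int(round(self.tree_horizon / self.cycle_length))

    def validate(self) -> None:
        if self.cycle_length <= 0:
            raise ValidationError("settings.cycle_length must be > 0")
        for name, span in (("horizon", self.horizon), ("tree_horizon", self.tree_horizon)):
            n = span / self.cycle_length
            if abs(n - round(n)) > 1e-9:
                raise ValidationError(f"settings.cycle_length must divide settings.{name} exactly")
        if self.discount_rate_costs < 0 or self.discount_rate_effects < 0:
            raise ValidationError("settings discount rates must be >= 0")
        if self.max_total_ablations != 3:
            raise ValidationError("settings.max_total_ablations must equal 3")


@dataclass
class CostInputs:
    """Unit costs in 2023 euros (German payer perspective)."""

    ablation_procedure: float = 8121.0
    cv_hospitalization_per_cycle: float = 1464.0
    ed_visit_per_cycle: float = 32.0
    outpatient_per_cycle: float = 107.0
    pharm_cardioversion: float = 1206.0
    elec_cardioversion: float = 166.0
    stroke_acute: dict = field(
        default_factory=lambda: {"non_disabling": 1204.0, "moderate": 2864.0, "severe": 5168.0}
    )
    stroke_longterm_per_cycle: float = 391.0
    hf_per_cycle: dict = field(
        default_factory=lambda: {"I": 166.0, "II": 213.0, "III": 244.0, "IV": 291.0}
    )
    pharma_per_cycle: dict = field(
        default_factory=lambda: {"cryoablation": 69.0, "aad": 89.0}
    )

    def validate(self) -> None:
        for path, value in _numeric_leaves("costs", dataclasses.asdict(self)):
            if value < 0:
                raise ValidationError(f"{path} must be >= 0")
        _require_keys("costs.stroke_acute", self.stroke_acute, SEVERITIES)
        _require_keys("costs.hf_per_cycle", self.hf_per_cycle, NYHA)
        _require_keys("costs.pharma_per_cycle", self.pharma_per_cycle, ARMS)


@dataclass
class UtilityInputs:
    # Age/sex utility norm source unpublished: synthetic linear-decline
    # placeholder anchored at 0.887 for the 57.5-year-old sex-weighted cohort.
    baseline_norm: dict = field(
        default_factory=lambda: {
            "anchor_age": 57.5,
            "anchor_utility": 0.887,
            "slope_per_year": -0.004,
            "floor": 0.40,
        }
    )
    decrement_st_episodic: float = 0.08
    decrement_lt_persistent: float = 0.08  # assumed equal to ST-episodic
    decrement_permanent: float = 0.11
    stroke_short_decrement: dict = field(
        default_factory=lambda: {"non_disabling": 0.0, "moderate": 0.23, "severe": 0.60}
    )
    stroke_long_decrement: dict = field(
        default_factory=lambda: {"non_disabling": 0.0, "moderate": 0.17, "severe": 0.35}
    )
    hf_decrement: dict = field(
        default_factory=lambda: {"I": 0.0, "II": 0.05, "III": 0.15, "IV": 0.33}
    )

    def baseline_utility(self, age: float) -> float:
        """Sex-weighted population utility norm at a given age."""
        bn = self.baseline_norm
        value = bn["anchor_utility"] + bn["slope_per_year"] * (age - bn["anchor_age"])
        return max(float(bn.get("floor", 0.0)), min(1.0, value))

    def state_decrement(self, group: str) -> float:
        return {
            "NSR": 0.0,
            "ST": self.decrement_st_episodic,
            "LT": self.decrement_lt_persistent,
            "PERM": self.decrement_permanent,
        }[group]

    def validate(self) -> None:
        decs = {
            "utilities.decrement_st_episodic": self.decrement_st_episodic,
            "utilities.decrement_lt_persistent": self.decrement_lt_persistent,
            "utilities.decrement_permanent": self.decrement_permanent,
        }
        for d in (self.stroke_short_decrement, self.stroke_long_decrement, self.hf_decrement):
            for k, v in d.items():
                decs[f"utilities.decrement[{k}]"] = v
        for path, v in decs.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{path} must be in [0, 1]")
        if not 0.0 < self.baseline_norm["anchor_utility"] <= 1.0:
            raise ValidationError("utilities.baseline_norm.anchor_utility must be in (0, 1]")
        _require_keys("utilities.stroke_short_decrement", self.stroke_short_decrement, SEVERITIES)
        _require_keys("utilities.stroke_long_decrement", self.stroke_long_decrement, SEVERITIES)
        _require_keys("utilities.hf_decrement", self.hf_decrement, NYHA)


def _default_utilization() -> dict:
    # per-cycle probabilities of one healthcare contact, by rhythm group;
    # identical across arms by default (arm differences enter via rhythm-state
    # occupancy); synthetic stand-ins for the trial-derived utilization rates
    per_group = {
        "hospitalization": {"NSR": 0.001, "ST": 0.040, "LT": 0.060, "PERM": 0.050},
        "ed_visit": {"NSR": 0.002, "ST": 0.050, "LT": 0.060, "PERM": 0.050},
        "outpatient": {"NSR": 0.010, "ST": 0.150, "LT": 0.200, "PERM": 0.150},
        "pharm_cardioversion": {"NSR": 0.0, "ST": 0.020, "LT": 0.015, "PERM": 0.0},
        "elec_cardioversion": {"NSR": 0.0, "ST": 0.030, "LT": 0.040, "PERM": 0.0},
    }
    return {
        cat: {arm: dict(groups) for arm in ARMS} for cat, groups in per_group.items()
    }


@dataclass
class RiskInputs:
    """Per-cycle clinical transition and event probabilities.

    Every probability refers to one three-month cycle unless the field name
    says annual. The trial-derived values are unpublished; defaults are
    synthetic.
    """

    recurrence: dict = field(  # NSR -> ST per cycle, by arm
        default_factory=lambda: {"cryoablation": 0.080, "aad": 0.200}
    )
    resolution: dict = field(  # ST -> NSR per cycle, by arm
        default_factory=lambda: {"cryoablation": 0.450, "aad": 0.450}
    )
    progression_st_to_lt: float = 0.015
    progression_lt_to_perm: float = 0.030
    remission_lt_to_st: float = 0.0  # disallowed by default; configurable
    reablation: dict = field(
        default_factory=lambda: {
            "ST": {"cryoablation": 0.020, "aad": 0.050},
            "LT": {"cryoablation": 0.020, "aad": 0.040},
        }
    )
    rr_recurrence_by_count: list = field(default_factory=lambda: [1.0, 0.80, 0.65, 0.55])
    rr_resolution_by_count: list = field(default_factory=lambda: [1.0, 1.10, 1.20, 1.25])
    ablation_success: float = 0.80  # P(NSR for the 90-day cycle after ablation)
    stroke_annual_by_score: dict = field(
        default_factory=lambda: {
            "0": 0.001, "1": 0.004, "2": 0.012, "3": 0.018, "4": 0.028,
            "5": 0.042, "6": 0.056, "7": 0.065, "8": 0.063, "9": 0.070,
        }
    )
    stroke_state_rr: dict = field(
        default_factory=lambda: {"NSR": 1.0, "ST": 1.10, "LT": 1.20, "PERM": 1.30}
    )
    stroke_state_rr_literature: dict = field(  # scenario input; source table unpublished
        default_factory=lambda: {"NSR": 0.80, "ST": 1.00, "LT": 1.20, "PERM": 1.46}
    )
    stroke_severity_split: dict = field(  # placeholder: split unpublished
        default_factory=lambda: {"non_disabling": 0.50, "moderate": 0.30, "severe": 0.20}
    )
    stroke_case_fatality: float = 0.18  # 30-day case fatality
    hf_annual_by_age: list = field(
        default_factory=lambda: [
            [0, 55, 0.0010], [55, 65, 0.0030], [65, 75, 0.0070],
            [75, 85, 0.0150], [85, 121, 0.0300],
        ]
    )
    hf_nyha_split: dict = field(
        default_factory=lambda: {"I": 0.40, "II": 0.35, "III": 0.18, "IV": 0.07}
    )
    hf_rr_permanent: float = 1.50
    hf_excess_mortality_annual: float = 0.10
    utilization: dict = field(default_factory=_default_utilization)

    def validate(self) -> None:
        probs: list[tuple[str, float]] = []
        for arm in ARMS:
            probs.append((f"risks.recurrence.{arm}", self.recurrence[arm]))
            probs.append((f"risks.resolution.{arm}", self.resolution[arm]))
        probs += [
            ("risks.progression_st_to_lt", self.progression_st_to_lt),
            ("risks.progression_lt_to_perm", self.progression_lt_to_perm),
            ("risks.remission_lt_to_st", self.remission_lt_to_st),
            ("risks.ablation_success", self.ablation_success),
            ("risks.stroke_case_fatality", self.stroke_case_fatality),
            ("risks.hf_excess_mortality_annual", self.hf_excess_mortality_annual),
        ]
        for grp, by_arm in self.reablation.items():
            for arm, p in by_arm.items():
                probs.append((f"risks.reablation.{grp}.{arm}", p))
        for score, q in self.stroke_annual_by_score.items():
            probs.append((f"risks.stroke_annual_by_score.{score}", q))
        for lo, hi, q in self.hf_annual_by_age:
            probs.append((f"risks.hf_annual_by_age[{lo},{hi})", q))
        for cat, by_arm in self.utilization.items():
            for arm, by_grp in by_arm.items():
                for grp, p in by_grp.items():
                    probs.append((f"risks.utilization.{cat}.{arm}.{grp}", p))
        for path, p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{path} must be a probability in [0, 1]")
        for name, rrs in (
            ("rr_recurrence_by_count", self.rr_recurrence_by_count),
            ("rr_resolution_by_count", self.rr_resolution_by_count),
        ):
            if len(rrs) != 4:
                raise ValidationError(f"risks.{name} must have 4 entries (counts 0-3)")
            if any(r <= 0 for r in rrs):
                raise ValidationError(f"risks.{name} entries must be > 0")
        for name, rr_map in (
            ("stroke_state_rr", self.stroke_state_rr),
            ("stroke_state_rr_literature", self.stroke_state_rr_literature),
        ):
            for grp, rr in rr_map.items():
                if rr < 0:
                    raise ValidationError(f"risks.{name}.{grp} must be >= 0")
        if self.hf_rr_permanent <= 0:
            raise ValidationError("risks.hf_rr_permanent must be > 0")
        for name, split, keys in (
            ("stroke_severity_split", self.stroke_severity_split, SEVERITIES),
            ("hf_nyha_split", self.hf_nyha_split, NYHA),
        ):
            _require_keys(f"risks.{name}", split, keys)
            total = sum(split.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"risks.{name} must sum to 1 (got {total})")
        _require_keys("risks.reablation", self.reablation, ("ST", "LT"))
        _require_keys("risks.utilization", self.utilization, UTILIZATION_CATEGORIES)


@dataclass
class PSAConfig:
    """Probabilistic sensitivity analysis configuration.

    ``se_fraction`` is the standard error, as a fraction of the mean, applied
    to expert-sourced scalars (10% base case). The coefficient block carries
    the correlated draw for the trial-regression-derived per-cycle
    probabilities: logit-scale means plus a lower-triangular Cholesky factor.
    """

    se_fraction: float = 0.10
    n_iterations: int = 5000
    coefficient_block: dict = field(default_factory=dict)  # {names, mean, factor}

    def validate(self) -> None:
        if self.se_fraction < 0:
            raise ValidationError("psa.se_fraction must be >= 0")
        if self.n_iterations < 1:
            raise ValidationError("psa.n_iterations must be >= 1")
        if self.coefficient_block:
            names = self.coefficient_block.get("names", [])
            mean = self.coefficient_block.get("mean", [])
            factor = self.coefficient_block.get("factor", [])
            d = len(names)
            if len(mean) != d or len(factor) != d or any(len(row) != d for row in factor):
                raise ValidationError("psa.coefficient_block dimensions inconsistent")
            for i, row in enumerate(factor):
                if any(abs(row[j]) > 0 for j in range(i + 1, d)):
                    raise ValidationError("psa.coefficient_block.factor must be lower-triangular")


@dataclass
class ParameterSet:
    demographics: Demographics = field(default_factory=Demographics)
    settings: Settings = field(default_factory=Settings)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    risks: RiskInputs = field(default_factory=RiskInputs)
    psa: PSAConfig = field(default_factory=PSAConfig)
    life_table: LifeTable | None = None

    def validate(self) -> "ParameterSet":
        self.demographics.validate()
        self.settings.validate()
        self.costs.validate()
        self.utilities.validate()
        self.risks.validate()
        self.psa.validate()
        if self.life_table is None:
            raise ValidationError("life_table is required")
        needed = self.demographics.baseline_age + self.settings.tree_horizon + self.settings.horizon
        if self.life_table.max_age + 1 < needed:
            raise ValidationError(
                f"life table max age {self.life_table.max_age} below "
                f"baseline_age + horizon = {needed}"
            )
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            name: dataclasses.asdict(getattr(self, name))
            for name in ("demographics", "settings", "costs", "utilities", "risks", "psa")
        }
        return d

    @classmethod
    def from_dict(cls, data: dict, life_table: LifeTable | None = None,
                  log_defaults: bool = False) -> "ParameterSet":
        blocks = {}
        for name, klass in (
            ("demographics", Demographics),
            ("settings", Settings),
            ("costs", CostInputs),
            ("utilities", UtilityInputs),
            ("risks", RiskInputs),
            ("psa", PSAConfig),
        ):
            given = data.get(name, {}) or {}
            unknown = set(given) - {f.name for f in dataclasses.fields(klass)}
            if unknown:
                raise ValidationError(f"unknown field(s) in {name}: {sorted(unknown)}")
            if log_defaults:
                for f in dataclasses.fields(klass):
                    if f.name not in given:
                        tag = PROVENANCE.get(f"{name}.{f.name}", "package default")
                        logger.info("default used: %s.%s (%s)", name, f.name, tag)
            blocks[name] = klass(**given)
        return cls(life_table=life_table, **blocks)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def save(self, path) -> None:
        """Write the config (JSON or YAML by extension) and the life table CSV."""
        path = Path(path)
        data = self.to_dict()
        lt_path = path.with_suffix(".lifetable.csv")
        if self.life_table is not None:
            self.life_table.to_csv(lt_path)
            data["life_table"] = lt_path.name
            data["life_table_cause_deleted"] = self.life_table.cause_deleted
        text = (
            json.dumps(data, indent=2, sort_keys=True)
            if path.suffix.lower() == ".json"
            else yaml.safe_dump(data, sort_keys=True)
        )
        path.write_text(text)


# provenance tags used when logging defaulted fields
PROVENANCE = {
    "costs.ablation_procedure": "published DRG-derived unit cost",
    "costs.cv_hospitalization_per_cycle": "published unit cost",
    "costs.ed_visit_per_cycle": "published unit cost",
    "costs.outpatient_per_cycle": "published unit cost",
    "costs.pharm_cardioversion": "published unit cost",
    "costs.elec_cardioversion": "published unit cost",
    "costs.stroke_acute": "published unit cost",
    "costs.stroke_longterm_per_cycle": "published unit cost",
    "costs.hf_per_cycle": "published unit cost",
    "costs.pharma_per_cycle": "published per-cycle pharmacy cost",
    "utilities.decrement_st_episodic": "trial-derived decrement (published)",
    "utilities.decrement_lt_persistent": "assumed equal to ST-episodic (published)",
    "utilities.decrement_permanent": "published decrement",
    "utilities.stroke_short_decrement": "published decrement",
    "utilities.stroke_long_decrement": "published decrement",
    "utilities.hf_decrement": "published decrement",
    "utilities.baseline_norm": "SYNTHETIC placeholder (norm source unpublished)",
    "demographics.male_fraction": "SYNTHETIC placeholder (trial sex split unpublished)",
    "demographics.baseline_cha2ds2vasc": "SYNTHETIC placeholder",
    "risks.recurrence": "SYNTHETIC stand-in (trial IPD unpublished)",
    "risks.resolution": "SYNTHETIC stand-in (trial IPD unpublished)",
    "risks.reablation": "SYNTHETIC stand-in (trial IPD unpublished)",
    "risks.stroke_annual_by_score": "SYNTHETIC stand-in (expert rates unpublished)",
    "risks.stroke_state_rr_literature": "SYNTHETIC stand-in (source table unpublished)",
    "risks.stroke_severity_split": "SYNTHETIC placeholder",
    "risks.utilization": "SYNTHETIC stand-in (trial IPD unpublished)",
}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_parameters(config_path) -> ParameterSet:
    """Load and validate a ParameterSet from a JSON or YAML config file.

    The config may reference its life-table CSV by relative path under the
    key ``life_table``. Missing optional fields are filled with documented
    defaults; each default is provenance-tagged in the module log.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(config_path)
    text = config_path.read_text()
    try:
        if config_path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValidationError(f"cannot parse {config_path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValidationError(f"config {config_path} must be a mapping")

    life_table = None
    lt_ref = data.pop("life_table", None)
    cause_deleted = bool(data.pop("life_table_cause_deleted", True))
    if lt_ref is not None:
        lt_path = Path(lt_ref)
        if not lt_path.is_absolute():
            lt_path = config_path.parent / lt_path
        life_table = LifeTable.from_csv(lt_path, cause_deleted=cause_deleted)

    ps = ParameterSet.from_dict(data, life_table=life_table, log_defaults=True)
    return ps.validate()


# ---------------------------------------------------------------------------
# dot-path access and scenarios
# ---------------------------------------------------------------------------


def _step(obj: Any, key: str) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if not hasattr(obj, key):
            valid = [f.name for f in dataclasses.fields(obj)]
            raise ScenarioError(f"unknown parameter field {key!r} (valid: {valid})")
        return getattr(obj, key)
    if isinstance(obj, dict):
        if key not in obj:
            raise ScenarioError(f"unknown parameter key {key!r} (valid: {sorted(obj)})")
        return obj[key]
    if isinstance(obj, (list, tuple)):
        return obj[int(key)]
    raise ScenarioError(f"cannot descend into {type(obj).__name__} with key {key!r}")


def get_path(params: ParameterSet, path: str) -> Any:
    """Resolve a dot-notation parameter path, e.g. 'costs.ablation_procedure'."""
    obj: Any = params
    for key in path.split("."):
        obj = _step(obj, key)
    return obj


def set_path(params: ParameterSet, path: str, value: Any) -> None:
    keys = path.split(".")
    obj: Any = params
    for key in keys[:-1]:
        obj = _step(obj, key)
    last = keys[-1]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if not hasattr(obj, last):
            valid = [f.name for f in dataclasses.fields(obj)]
            raise ScenarioError(
                f"unknown parameter field {last!r} in path {path!r} (valid: {valid})"
            )
        setattr(obj, last, value)
    elif isinstance(obj, dict):
        if last not in obj:
            raise ScenarioError(f"unknown parameter key {last!r} in path {path!r}")
        obj[last] = value
    elif isinstance(obj, list):
        obj[int(last)] = value
    else:
        raise ScenarioError(f"cannot set into {type(obj).__name__} at {path!r}")


def _scale_in_place(node: Any, factor: float) -> Any:
    """Multiply every numeric leaf under a container node; returns scaled scalars."""
    if isinstance(node, bool):
        raise ScenarioError("cannot multiply a boolean parameter")
    if isinstance(node, (int, float)):
        return node * factor
    if isinstance(node, dict):
        for k in node:
            node[k] = _scale_in_place(node[k], factor)
        return node
    if isinstance(node, list):
        for i in range(len(node)):
            node[i] = _scale_in_place(node[i], factor)
        return node
    raise ScenarioError(f"cannot multiply node of type {type(node).__name__}")


@dataclass(frozen=True)
class Override:
    path: str
    op: str  # 'set' | 'multiply' | 'toggle'
    value: Any = None


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    overrides: tuple = ()
    description: str = ""


def apply_scenario(base: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return a new ParameterSet with the scenario's overrides applied.

    ``base`` is never modified. A 'set' value of the form '@some.path' is
    resolved against ``base`` before assignment (used for config-supplied
    alternative tables).
    """
    out = base.copy()
    for ov in scenario.overrides:
        if ov.op == "set":
            value = ov.value
            if isinstance(value, str) and value.startswith("@"):
                value = copy.deepcopy(get_path(base, value[1:]))
            set_path(out, ov.path, value)
        elif ov.op == "multiply":
            node = get_path(out, ov.path)
            scaled = _scale_in_place(copy.deepcopy(node), float(ov.value))
            set_path(out, ov.path, scaled)
        elif ov.op == "toggle":
            current = get_path(out, ov.path)
            if not isinstance(current, bool):
                raise ScenarioError(f"toggle target {ov.path!r} is not boolean")
            set_path(out, ov.path, not current)
        else:
            raise ScenarioError(f"unknown override op {ov.op!r}")
    return out


def builtin_scenarios() -> list[ScenarioSpec]:
    """The seven deterministic scenario analyses of the evaluation.

    The literature stroke-RR scenario reads its replacement table from the
    base ParameterSet (``risks.stroke_state_rr_literature``) because the
    source values are configuration inputs.
    """
    return [
        ScenarioSpec(
            "blanking_period",
            (Override("settings.blanking_period_active", "toggle"),),
            "12-week post-ablation blanking period implemented",
        ),
        ScenarioSpec(
            "recurrence_rr_up10",
            tuple(
                Override(f"risks.rr_recurrence_by_count.{k}", "multiply", 1.10)
                for k in (1, 2, 3)
            ),
            "RR of AF recurrence by number of previous ablations increased 10%",
        ),
        ScenarioSpec(
            "resolution_rr_up10",
            tuple(
                Override(f"risks.rr_resolution_by_count.{k}", "multiply", 1.10)
                for k in (1, 2, 3)
            ),
            "RR of AF resolution by number of previous ablations increased 10%",
        ),
        ScenarioSpec(
            "ablation_success_down30",
            (Override("risks.ablation_success", "multiply", 0.70),),
            "ablation success rate decreased 30% (proportionally)",
        ),
        ScenarioSpec(
            "stroke_incidence_down30",
            (Override("risks.stroke_annual_by_score", "multiply", 0.70),),
            "stroke incidence rate decreased 30% (proportionally)",
        ),
        ScenarioSpec(
            "literature_stroke_rr",
            (Override("risks.stroke_state_rr", "set", "@risks.stroke_state_rr_literature"),),
            "health-state stroke RRs replaced with literature-sourced values",
        ),
        ScenarioSpec(
            "hf_perm_rr_up10",
            (Override("risks.hf_rr_permanent", "multiply", 1.10),),
            "RR of heart failure in the permanent state increased 10%",
        ),
    ]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _numeric_leaves(prefix: str, node: Any) -> Iterable[tuple[str, float]]:
    if isinstance(node, bool):
        return
    if isinstance(node, (int, float)):
        yield prefix, float(node)
    elif isinstance(node, dict):
        for k, v in node.items():
            yield from _numeric_leaves(f"{prefix}.{k}", v)
    elif isinstance(node, (list, tuple)):
        for i, v in enumerate(node):
            yield from _numeric_leaves(f"{prefix}.{i}", v)


def _require_keys(path: str, mapping: dict, keys: Iterable[str]) -> None:
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ValidationError(f"{path} missing keys {missing}")
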