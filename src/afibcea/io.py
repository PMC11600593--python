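"""Result writers and the run manifest.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header row,
currency columns as unformatted floats — so every table round-trips through
``pandas.read_csv`` bit-exactly enough for regression comparison.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .economics import COST_CATEGORIES
from .model import DeterministicResult
from .psa import PSAResult

CATEGORY_LABELS = {
    "initial_procedure": "Initial procedure",
    "reablation": "Re-ablations",
    "healthcare_contacts": "Healthcare contact costs",
    "pharmaceutical": "Pharmaceutical costs",
    "adverse_events": "AF-related adverse events",
}


def config_hash(config_path) -> str:
    """SHA-256 of the raw config bytes (reproducible run fingerprint)."""
    return hashlib.sha256(Path(config_path).read_bytes()).hexdigest()


def write_manifest(
    out_dir, outputs: list[str], seed: int | None = None,
    config_path=None, scenario: str | None = None,
) -> Path:
    """Write the run manifest atomically alongside the output set."""
    out_dir = Path(out_dir)
    manifest = {
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config_sha256": config_hash(config_path) if config_path else None,
        "seed": seed,
        "scenario": scenario,
        "outputs": sorted(outputs),
    }
    path = out_dir / "manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(path)
    return path


def breakdown_frame(result: DeterministicResult) -> pd.DataFrame:
    """Per-patient deterministic cost breakdown (one row per category plus
    totals, QALYs and the ICER), intervention vs comparator vs incremental."""
    a, b = result.intervention.summary, result.comparator.summary
    rows = []
    for cat in COST_CATEGORIES:
        rows.append(
            {
                "outcome": CATEGORY_LABELS[cat],
                "cryoablation": a.cost_by_category[cat],
                "aad": b.cost_by_category[cat],
                "incremental": a.cost_by_category[cat] - b.cost_by_category[cat],
            }
        )
    rows.append(
        {
            "outcome": "Total cost per patient",
            "cryoablation": a.total_cost,
            "aad": b.total_cost,
            "incremental": result.ce.delta_cost,
        }
    )
    rows.append(
        {
            "outcome": "QALYs per patient",
            "cryoablation": a.qalys,
            "aad": b.qalys,
            "incremental": result.ce.delta_qalys,
        }
    )
    icer = result.ce.icer
    rows.append(
        {
            "outcome": "ICER",
            "cryoablation": np.nan,
            "aad": np.nan,
            "incremental": icer if isinstance(icer, float) else np.nan,
        }
    )
    return pd.DataFrame(rows, columns=["outcome", "cryoablation", "aad", "incremental"])


def additional_outcomes_frame(result: DeterministicResult) -> pd.DataFrame:
    """Time in state, life years, lifetime event rates, NNT and ablation counts."""
    a, b = result.intervention.summary, result.comparator.summary
    rows = []

    def row(outcome, va, vb, cost_per_event=np.nan, nnt=np.nan):
        rel = (va - vb) / vb if vb != 0 else np.nan
        rows.append(
            {
                "outcome": outcome,
                "cryoablation": va,
                "aad": vb,
                "incremental": va - vb,
                "relative_change": rel,
                "cost_per_event_avoided": cost_per_event,
                "nnt": nnt,
            }
        )

    for g, label in (
        ("NSR", "Years in normal sinus rhythm"),
        ("ST", "Years in short-term episodic AF"),
        ("LT", "Years in long-term persistent AF"),
        ("PERM", "Years in permanent AF"),
    ):
        row(label, a.time_in_states[g], b.time_in_states[g])
    row("Undiscounted life years", a.life_years_undisc, b.life_years_undisc)
    row("Discounted life years", a.life_years, b.life_years)
    sm, hm = result.stroke_metrics, result.hf_metrics
    row(
        "Lifetime stroke rate", sm.rate_intervention, sm.rate_comparator,
        cost_per_event=sm.cost_per_event_avoided if sm.cost_per_event_avoided is not None else np.nan,
        nnt=sm.nnt if sm.nnt is not None else np.nan,
    )
    row(
        "Lifetime heart failure rate", hm.rate_intervention, hm.rate_comparator,
        cost_per_event=hm.cost_per_event_avoided if hm.cost_per_event_avoided is not None else np.nan,
        nnt=hm.nnt if hm.nnt is not None else np.nan,
    )
    row("Re-ablations at twelve months", a.reablations_12m, b.reablations_12m)
    row("Re-ablations over horizon", a.reablations_horizon, b.reablations_horizon)
    return pd.DataFrame(rows)


def scenario_frame(rows: list[dict]) -> pd.DataFrame:
    """Scenario-analysis table: one row per scenario with ΔC, ΔE, ICER."""
    return pd.DataFrame(
        rows,
        columns=["scenario", "incremental_cost", "incremental_qalys", "icer"],
    )


def ce_plane_frame(psa: PSAResult) -> pd.DataFrame:
    """Per-iteration cost/QALY pairs and increments (cost-effectiveness plane)."""
    return pd.DataFrame(
        {
            "iteration": np.arange(psa.n_iterations),
            "cost_cryoablation": psa.cost_intervention,
            "cost_aad": psa.cost_comparator,
            "qaly_cryoablation": psa.qaly_intervention,
            "qaly_aad": psa.qaly_comparator,
            "delta_cost": psa.delta_cost,
            "delta_qalys": psa.delta_qalys,
        }
    )


def ceac_frame(psa: PSAResult) -> pd.DataFrame:
    return pd.DataFrame(
        {"wtp": psa.wtp_grid, "prob_cost_effective": psa.ceac_values}
    )


def write_deterministic_outputs(result: DeterministicResult, out_dir) -> list[str]:
    """Write the breakdown, additional outcomes and both cycle traces."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in (
        ("breakdown.csv", breakdown_frame(result)),
        ("additional_outcomes.csv", additional_outcomes_frame(result)),
        ("trace_cryoablation.csv", result.intervention.trace.to_frame()),
        ("trace_aad.csv", result.comparator.trace.to_frame()),
    ):
        frame.to_csv(out_dir / name, index=False)
        written.append(name)
    return written


def write_psa_outputs(psa: PSAResult, out_dir) -> list[str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ce_plane_frame(psa).to_csv(out_dir / "ce_plane.csv", index=False)
    ceac_frame(psa).to_csv(out_dir / "ceac.csv", index=False)
    (out_dir / "psa_summary.json").write_text(
        json.dumps(psa.summary(), indent=2, sort_keys=True)
    )
    return ["ce_plane.csv", "ceac.csv", "psa_summary.json"]
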