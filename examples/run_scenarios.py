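"""Scenario analyses: each built-in scenario re-runs the deterministic model
with one documented parameter change (blanking period, ±10% relative risks,
-30% ablation success or stroke incidence, literature stroke RRs).

Each row prints the incremental cost, incremental QALYs and ICER of
cryoablation versus drug therapy under that scenario; "Dominant" marks
scenarios where cryoablation both saves money and gains QALYs.
"""

from afibcea import (
    apply_scenario,
    builtin_scenarios,
    generate_parameter_set,
    run_deterministic,
)

params = generate_parameter_set()
print(f"{'scenario':<28}{'dCost (EUR)':>12}{'dQALY':>8}  ICER")
for name, p in [("base_case", params)] + [
    (s.name, apply_scenario(params, s)) for s in builtin_scenarios()
]:
    res = run_deterministic(p)
    icer = res.ce.icer
    icer_txt = "Dominant" if icer == "dominant" else f"{icer:,.0f}"
    print(f"{name:<28}{res.ce.delta_cost:>12,.0f}{res.ce.delta_qalys:>8.3f}  {icer_txt}")
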