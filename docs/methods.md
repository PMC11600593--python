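# Methods note

This note documents the model as implemented: its structure, assumptions,
parameters, numerical conventions, the synthetic-data stand-ins, and known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Model structure

**Hybrid design.** A one-year decision tree followed by a 40-year Markov
cohort phase, both on three-month cycles, both driven by the *same*
transition-matrix builder (`markov.build_transition_matrix`) so the two
components cannot drift apart. The tree restricts outcomes to the three
first-year health states (NSR, ST-episodic, death) by disabling
progression beyond ST during its four cycles; its end-of-year occupancy
— including the re-ablation substate counts — is the Markov phase's
initial allocation.

**State space.** 14 states: NSR_k, ST_k, LT_k for k ∈ {0..3}, permanent,
dead. k counts repeat ablations; the cryoablation arm's index procedure
counts toward the lifetime cap of three procedures but not toward k, so
cryoablation patients can receive at most two repeats (k ≤ 2 reachable)
and drug-arm patients three (k ≤ 3).

**Tree entry.** Both arms enter with the whole cohort symptomatic
(ST-episodic). The cryoablation arm pays the €8,121 procedure at entry
(undiscounted, t = 0); with probability `ablation_success` the first
90-day cycle is spent in NSR_0, otherwise in ST_0. The drug arm starts on
therapy in ST_0; any ablation it receives is a crossover, costed at the
same €8,121 and booked under re-ablations. This single-unit-cost choice
follows the published cost breakdown, which books drug-arm ablations as
re-ablation costs.

**Within-cycle order.** Death is evaluated first as a competing risk;
rhythm/ablation transitions apply to survivors (each conditional row is
scaled by 1 − p_death). Re-ablation from ST_k or LT_k moves to NSR_{k+1}
with probability `re-ablation rate × success` and to ST_{k+1} otherwise,
only while the lifetime cap permits. Recurrence and resolution are scaled
by RR(k) and capped into [0, 1]; joint exits from a state are
proportionally rescaled if they would exceed 1 (logged). LT→ST remission
is 0 by default but configurable. No half-cycle correction is applied
(the original model is a spreadsheet cohort model; a Settings switch
exists for sensitivity work).

**Blanking period (scenario).** When active, ablation-failure mass in the
procedure cycle is redirected to NSR_{k+1} — i.e. recurrence in the first
post-ablation quarter is not counted as treatment failure — and the same
rule applies to the index ablation. The blanked mass is tallied and
charged ST-level minus NSR-level contact costs for that one cycle, so the
blanked episode's healthcare utilization still accrues. Whether blanked
episodes incur cardioversion costs is not externally specified; they do
here (they are part of the ST contact-cost bundle), a flagged assumption.

## Clinical events and mortality

* **Rate conversion.** All annual inputs convert by
  `p_c = 1 − (1 − p_a)^{1/4}`; composing four cycles recovers the annual
  probability to 1e-12 (tested).
* **Stroke.** Annual incidence is looked up by the cohort's
  CHA₂DS₂-VASc score (baseline configurable, default 1; +1 at age 65, +1
  at 75), multiplied by a health-state RR, converted to a cycle
  probability. Events split over three severities (default 0.50/0.30/0.20,
  a placeholder — the split is unpublished); non-fatal strokes join a
  severity-specific prevalence accumulator that accrues the €391/cycle
  long-term cost and the long-term decrement every later cycle; the acute
  severity cost and short-term decrement apply in the event cycle.
* **Heart failure.** General-population age-band incidence times a
  permanent-state RR; onsets join an NYHA-split prevalence accumulator
  with per-cycle costs and decrements.
* **Prevalence bookkeeping.** Sequelae are cohort-level masses among the
  living, applied uniformly across living states, with deaths removing
  prevalence proportionally. This differs from per-state tracking but
  keeps the 14-state space intact and makes the mortality feedback
  well-defined for both the cohort engine and the microsimulation; at the
  event rates modelled here the state-mix error is second-order.
* **Mortality.** Annual hazards add: cause-deleted sex-weighted life-table
  background (+ stroke incidence × 30-day case fatality + prevalent-HF
  fraction × HF excess hazard), then convert to a quarterly probability.
  In the no-event limit the cohort survival curve reproduces the
  life-table survivor function to 1e-9 (tested). The exact published
  combination formula is in unavailable supplementary material; additive
  hazards is the standard convention and is this module's defining
  contract.

## Economics

Five reporting categories (initial procedure, re-ablations, healthcare
contacts, pharmaceutical, adverse events); the grand total equals the sum
of categories exactly. Contact and pharmacy costs apply per person-cycle
to all living states; procedure costs are event-driven. QALYs per cycle:
`0.25 × Σ occupancy × max(0, norm(age) − state decrement − prevalence
decrements)`, with new strokes taking their short-term decrement in the
event cycle; adverse-event decrements combine additively with state
decrements and floor at utility 0. Discounting is quarterly compound,
`(1.03)^(−0.25 t)` on a model-wide clock (tree cycles 0–3, Markov cycles
4–163), costs and effects at 3%/year each. ICER carries dominance flags
(`dominant`/`dominated`/`undefined`); NNT uses the ceiling of the
reciprocal absolute risk difference.

## Probabilistic sensitivity analysis

Gamma for costs and beta for probabilities/utility decrements, moment-
matched from (mean, SE); the default SE is 10% of the mean, the published
uncertainty level for expert-estimated parameters, applied here as the
blanket default because the per-parameter provenance split is not
recoverable. The six trial-regression-derived transition probabilities
(recurrence, resolution by arm; the two progressions) are drawn jointly:
logit-scale means with a lower-triangular Cholesky factor (config input;
the synthetic generator produces an exchangeable-correlation block,
ρ = 0.3, logit-scale σ ≈ 0.05). One root seed spawns per-iteration
substreams, so results are bit-identical under a fixed seed. Summaries:
empirical 2.5/97.5-percentile credible intervals; mean ICER as the ratio
of mean increments (per-iteration ICER averaging is unstable across the
plane); probability cost-effective from NMB > 0; CEAC over a WTP grid.
Setting `psa.se_fraction = 0` with an empty coefficient block makes every
draw degenerate and reproduces the deterministic run to 1e-9 relative
(tested) — the key cross-module oracle.

## Synthetic inputs

The generator emulates the *structure* of the unavailable trial-derived
inputs, not their values: cryoablation recurrence below drug-arm
recurrence (hazard-ratio scaling, default 0.40 on a 0.20 quarterly
drug-arm probability), resolution 0.45, RR(k) falling for recurrence and
rising for resolution with the ablation count, higher drug-arm crossover
ablation uptake (quarterly ST re-ablation 0.05 vs 0.02), ablation success
0.80, Gompertz life tables (b = 0.095; male/female level difference),
CHA₂DS₂-VASc-graded stroke incidence and age-banded heart-failure
incidence scaled so the lifetime stroke rate lands near 0.26. These
defaults were fixed once, at design time, so that the synthetic base case
sits in the qualitative regime the published evaluation reports — cryo:
fewer re-ablations (0.28 vs 1.17), ~40% less AF-state time, slightly
higher lifetime cost with a clear QALY gain — while making no claim to
reproduce the published numbers, which depend on unpublished prognostic
equations. What passing tests show is therefore that the *machinery* is
correct (conservation, oracles, closed forms), not that real-data inputs
would yield these outputs.

The generator does **not** emulate: time-varying re-ablation propensity
(real uptake concentrates early; the constant quarterly rates here trade
first-year against lifetime counts), covariate-driven heterogeneity,
anticoagulation effects on stroke, or seasonal/monitoring artefacts in
recurrence detection.

**Calibration** is a budgeted multiplicative coordinate search over an
explicit free-parameter list (never automatic, to avoid silently
overfitting the stand-in), minimizing the sum of |deviation|/tolerance
over named behavioural targets; it is monotone-improving and returns the
best-so-far on budget exhaustion.

## Numerical conventions and degenerate inputs

* Occupancy rows conserve mass to 1e-9 over 160 cycles; matrix rows are
  validated to 1e-10 at construction.
* Probability caps (RR × base > 1) saturate at 1 and are logged, not
  fatal; negative inputs are fatal.
* Time in states sums start-of-cycle occupancy × 0.25; with years dead it
  partitions the horizon exactly.
* An all-dead allocation yields identically zero accruals; empty living
  occupancy short-circuits utilization sums.
* Life tables require consecutive integer ages covering baseline age +
  41 years; CSV round-trips use `float_precision="round_trip"`.

## Problem sizes

Deterministic run: 4 + 160 cycles × 14 states, ~0.1 s. The packaged
analyses use: 100,000 microsimulation walkers over the full horizon for
the engine cross-check; 300 PSA iterations in the acceptance report and
60–200 in tests and examples (the CLI default remains 5,000, matching the
published analysis); a 60-run calibration budget. These sizes give
Monte-Carlo standard errors comfortably below the tolerances asserted.

## Known limitations

* Prevalence accumulators are uniform across living states (see above);
  per-state sequelae tracking would need a larger state space.
* Baseline utility norms by age/sex and the trial sex split are
  unpublished; both are flagged placeholders (linear decline from 0.887
  at 57.5, −0.004/year, floor 0.40; male fraction 0.65).
* The cohort ages deterministically (57.5 + 0.25 × cycle); no
  patient-level heterogeneity beyond sex weighting.
* The tree's internal granularity (four quarterly periods) is a design
  choice; the published model's internal tree structure is not described.
* No value-of-information analysis, tornado diagrams, societal costs,
  recurrent-stroke modelling or bleeding events.
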