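# Methods

## Model overview

The package implements a two-stage decision-analytic model from a US
healthcare-system perspective.

**Stage 1 — diagnostic decision tree.** A cohort of patients with IPMN under
evaluation for malignancy (pre-test probability 0.52) is classified by one of
two strategies — CT/MRI (Se 0.809, Sp 0.762) or CT/MRI plus one supplemental
FDG-PET/CT (Se 0.968, Sp 0.911) — into true/false positives and negatives.
Test positives undergo immediate pancreatic resection: the weighted surgery
cost (0.78/0.99 pancreatoduodenectomy at $28,623, 0.21/0.99 distal resection
at $13,900 → $25,499.94; the published resection-type proportions sum to
0.99 and are renormalized rather than assigning the residual to an unpriced
procedure) plus a $1,930 readmission cost is charged, a one-time 4.6%
perioperative mortality is applied, and survivors spend their first
post-operative year at utility 0.818. Test negatives enter surveillance at
utility 1.0; false negatives carry an undetected malignancy. Both strategies
are charged one CT/MRI exam ($492); the PET strategy additionally charges
one PET exam ($1,551) — the PET scan is supplemental, not a replacement.

**Stage 2 — Markov cohort model.** Annual cycles over a 15-year horizon
starting at age 64.3. Reportable states: SurveillanceBenign,
UndetectedMalignant, PostResectionBenign, PostResectionMalignant, Recurrence,
Death (absorbing). Internally the engine adds small tunnel states (first
post-operative year; optional five-year recurrence-risk chain) so that the
first-year utility 0.818 → long-term 0.896 step and time-limited recurrence
risks remain expressible as a plain Markov chain; tunnels aggregate back to
the six states in all exports.

Annual flows (all probabilities from the published input table):

| flow | probability |
| --- | --- |
| surveillance → malignant transformation | 2.23%/yr |
| undetected malignancy → disease death | 2.7%/yr |
| undetected malignancy → detection → surgery | strategy's own sensitivity (annual re-testing) |
| post-resection malignant → recurrence | 16.7%/yr (× 0.90 in the PET strategy) |
| recurrence → death | 28.3%/yr |
| any alive state → death | background q(age) from the life table |

Cause-specific risks combine with background mortality as independent
competing risks within a cycle: stay-alive probability
`(1 − q_age)(1 − q_cause)`; residual mass remains in the current state.
Delayed surgery (detected undetected-malignancy) charges the full surgery
event cost, including for the fraction that dies perioperatively; the
expected event cost is attached to the transition so the cohort engine and
the microsimulation oracle charge identical expectations.

Rewards: cycle *t* uses state membership at the start of cycle *t*
(no half-cycle correction by default), discounted by `(1.03)^(−t)`,
*t* = 0…14, so cycle-0 events are undiscounted. NMB = 100 000 · E − C.
Incremental results are reported for CT/MRI relative to the PET strategy
(matching the published sign convention); a strategy that is cheaper and
more effective dominates, and no ICER is reported under dominance.

## Structural variants and calibration

The original analysis was built in TreeAge and its exact state/reward wiring
is not published. Every wiring choice the published description leaves open
is an explicit axis of `StructureVariant` (128 combinations):

* **fn_detection** — undetected malignancy found by annual re-testing with
  the strategy's own sensitivity, or deterministically one year later;
* **recurrence_risk** — 16.7%/yr applied every post-resection cycle, only
  from the second post-operative year, only the first five years, or only
  once;
* **recurrence_cost** — $78,630 charged once on entry to Recurrence or in
  every cycle spent there (the source cost study reports phase-based cancer
  costs, which supports either reading);
* **background_mortality** — life-table mortality stacked onto every state,
  or applied only in states without a cohort-derived death rate (rates
  estimated from clinical cohorts already include all-cause deaths, so
  stacking double-counts);
* **post_resection_imaging** — whether the $492 annual surveillance exam
  continues after resection;
* **half_cycle_correction** — on/off.

The calibration harness (`ipmncea.calibration`) runs the full analysis under
every combination and scores it against the published results — both costs,
both QALY totals, both NMBs, incremental cost and effectiveness, the PET
-specificity threshold, and the QALY advantage at CT/MRI specificity
0.65/0.85 — normalizing each absolute deviation by a tolerance matched to
the published precision (5% on costs/NMB, 0.15 QALY on effectiveness,
$1,500 / 0.05 QALY on the incrementals, 3 percentage points on the
threshold, 0.05 QALY on the sensitivity points). The shipped default is the
best-scoring combination:

> annual re-testing · recurrence risk from the second post-operative year ·
> recurrence cost per cycle · background mortality in all states · no
> post-resection imaging cost · no half-cycle correction.

Under this default the package reproduces the published per-strategy costs
(within 1%), both NMBs (within 5%), the incremental cost (sign and
magnitude) and incremental effectiveness (within 0.05 QALY), and both
sensitivity-analysis QALY advantages (within 0.05 QALY). Two quantities
remain outside their reproduction tolerances and are reported as genuine
deviations rather than adjusted away:

* **absolute QALY totals** come out ≈ 0.28–0.31 lower than published. The
  printed transition probabilities imply more cumulative mortality than the
  published QALY level for any enumerated wiring that also reproduces the
  published cost level; variants that match the QALYs (e.g. not stacking
  background mortality onto cohort-derived rates) overshoot costs by
  10–13%. Cost and effectiveness could not be matched simultaneously.
* **the PET-specificity threshold** computes to ≈ 66.5% vs the published
  71.5%. The NMB-vs-specificity slope (≈ $650 per percentage point) matches
  the published figure's implied slope; the offset follows directly from
  the base-case NMB difference ($15.4k here vs $12.4k published, each NMB
  individually within 5%).

The corresponding acceptance tests fail by design; they assert the published
tolerances against honestly computed values.

## Life table

Background mortality comes from a two-column CSV (`age,qx`). The packaged
table (`us2017_smoothed_qx.csv`, ages 60–85) is a **synthetic,
Gompertz-smoothed stand-in** anchored at representative 2017 US
all-population levels (q₆₅ ≈ 0.0131, q₈₀ ≈ 0.0477), not a verbatim copy of
the official publication. Over the model's age span (64.3–78.3) the smoothed
values track the official all-population schedule to well within the
uncertainty that matters for the results. Lookups interpolate linearly
between integer ages (the cohort starts at the fractional age 64.3) and
clamp above the last tabulated age. `synthesize_life_table(a, b)` generates
deterministic Gompertz tables `qx = 1 − exp(−a·e^{b·age})` for tests and
experiments (defaults a = 2·10⁻⁵, b = 0.095, a comparable mortality level).

## Synthetic parameter sets and the microsimulation oracle

`generate_parameters(seed, scale)` perturbs every accuracy, cost, utility
and transition probability multiplicatively by `1 + scale·U(−1,1)` (default
scale 0.2, a generous envelope around the literature ranges), clamped to
validity; the death utility and the economic settings other than the
pre-test probability stay fixed. It emulates parameter uncertainty only —
not sampling noise, correlations between inputs, or subtype heterogeneity —
so property tests passing over this family show the engine is correct across
valid inputs, not that the base-case inputs are right.

`microsimulate(p, strategy, n, seed, lt)` pushes `n` individuals through the
identical decision tree and per-cycle categorical draws from the *same*
transition matrices, costs, utilities and discounting as the cohort engine.
Because it shares the matrices, agreement (within 3 standard errors at
n = 200 000, checked for 20 random parameter sets) validates the engine's
accumulation and discounting logic; the matrices themselves are validated by
hand-arithmetic unit tests.

## Numerical choices

* Transition-matrix rows are asserted to sum to 1 within 10⁻¹², and cohort
  mass is re-checked every cycle.
* Threshold analysis pre-samples the NMB difference at 50 points, errors on
  a non-monotone profile (reporting the sign pattern), returns "no crossing"
  for constant sign, and otherwise bisects the bracketing subinterval to an
  interval width of 10⁻⁴.
* DSA ranges default to ±20% of base, clamped to each field's validity
  range; ranges are validated before any model run. Tornado entries sort by
  incremental-cost bar width.
* Config files may give any scalar as a fraction or with a `_percent`
  suffix; the published "16.7" recurrence row is read as 16.7%/yr,
  consistent with the other rows.
* A resection-type mix not summing to 1 warns (the published mix is 78/21)
  and the weighted surgery cost renormalizes over the mix sum.

## Problem sizes

The cohort engine runs 15 cycles over ≤ 13 internal states (< 2 ms per
strategy); the full 128-variant calibration, including per-variant threshold
searches, takes a few seconds; microsimulation cross-checks use n = 200 000
individuals (standard errors ≈ $310 on cost, ≈ 0.008 QALY).

## Known limitations

* No probabilistic sensitivity analysis and no acceptability curves; the
  uncertainty analysis is deterministic (one-way + threshold), as in the
  source analysis.
* No IPMN subtype modelling (branch/main/mixed duct), no EUS/FNA arm, no
  repeated-PET surveillance strategies.
* The life table is a smoothed stand-in (above); absolute outputs shift by a
  few hundredths of a QALY under plausible alternative schedules.
* The published absolute QALY level and threshold are not reproduced within
  tolerance under any enumerated wiring (see the calibration section); the
  comparative conclusions (dominance of the PET strategy, sensitivity
  rankings) are reproduced and robust across every examined variant that
  matches the published cost level.
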