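# Methods note

This note documents the model structure, conventions and numerical choices
of the `ckdcea` package in enough detail to re-derive every reported number.

## 1. Model structure

Cohort state-transition (Markov) model with monthly cycles and three
states: **pre-dialysis** (CKD stage 4–5, conservatively managed on one of
the two diets), **dialysis** (renal replacement therapy: haemodialysis,
CAPD or APD, in fixed proportions), and **dead** (absorbing). Transitions
allowed per cycle: pre-dialysis → dialysis, pre-dialysis → dead,
dialysis → dead, and self-loops. There is no recovery from dialysis and no
transplantation state.

The cohort starts entirely in pre-dialysis. The simulation runs to a
lifetime horizon: it stops when the surviving fraction drops below 1e-4 or
at a hard cap of 1440 cycles (120 years), whichever comes first. With the
default mortality inputs the model stops at 963 cycles (~80 years); the cap
is a safety net for degenerate user inputs, and hitting it is flagged on
the trace (`horizon_capped`).

## 2. Transition probabilities

All clinical inputs are annual probabilities; conversion to monthly
transition probabilities goes through constant hazards:

- annual probability → rate: `r = −ln(1 − p)` (per year);
- rate → probability over Δt years: `p = 1 − exp(−r·Δt)` with Δt = 1/12;
- treatment effect (hazard ratio) on an annual probability:
  `p' = 1 − (1 − p)^HR`.

**Competing risks.** From pre-dialysis the cohort can exit to dialysis or
to death in the same cycle. The two annual rates are summed, the total exit
probability over one cycle is `1 − exp(−(r_dial + r_death)/12)`, and that
probability is allocated to the two destinations proportionally to their
rates. This is the exact solution of the underlying two-exit constant-
hazard continuous-time process.

Default clinical inputs:

| quantity | value | notes |
|---|---|---|
| annual dialysis onset, LPD | 0.244 | base progression |
| hazard ratio for onset, s-VLPD vs LPD | 0.237 (95 % CI 0.22–0.26) | applied on the hazard scale |
| annual pre-dialysis mortality | 0.111 | same in both arms |
| annual dialysis mortality | 0.138 | same in both arms in the base case |
| annual dialysis mortality, benefit scenario | 0.108 | s-VLPD arm only |

Derived monthly values (useful as oracles): LPD onset rate 0.279714/yr;
s-VLPD annual onset probability 0.064143; monthly pre-dialysis exit
probability (LPD) 0.0325721 with 0.7039095 allocated to dialysis; monthly
dialysis death probability 0.0122987.

## 3. Outcomes

**Half-cycle correction** (on by default): every occupancy-derived outcome
uses the average of start-of-cycle and end-of-cycle occupancy, i.e. the
trapezoid rule over the trace. This removes the half-cycle bias of counting
transitions as if they happened at cycle boundaries.

**Time outcomes** (survival, time pre-dialysis, time in dialysis) are
reported **undiscounted** by default, matching life-table conventions; a
`settings.discount_life_years` flag discounts them if desired.

**QALYs** weight corrected occupancy by state utilities (the dialysis
utility is the modality-mix-weighted mean of HD/CAPD/APD utilities) and
discount at 3 %/year with the per-cycle factor `1.03^(−k/12)` for cycle k.

**Costs** accrue per cycle on corrected occupancy, discounted identically:

- *Ketoanalogues*: tablets/day × price × days/month, pre-dialysis on
  s-VLPD only (switched patients in the adherence scenario stop paying).
- *Diet monitoring*: visits/month × visit price, pre-dialysis (monthly on
  s-VLPD, every other month on LPD).
- *Other supplementation*: per diet, Σ usage-fraction × dose/day × unit
  price × days/month (bicarbonate, calcium) or per-week doses scaled by
  (365.25/12)/7 (vitamin D).
- *Dialysis*: mix-weighted monthly tariff, plus annual PD maintenance
  amortized monthly, plus a one-off catheter/vascular-access cost charged
  to each cohort fraction at its cycle of dialysis entry (entries are
  tracked on the trace and discounted at the entry cycle).
- *Indirect costs* (societal perspective only): patient productivity loss =
  state-specific fraction of working time lost (0.20 pre-dialysis on
  s-VLPD, 0.30 on LPD, 0.50 on dialysis) × the patient's gender/age-band
  monthly work value (patients age with model time), plus caregiver cost =
  caregiver-need fraction (0.245) × state-specific hours/week (12 on
  dialysis, 2 pre-dialysis) valued at the caregiver work value pro-rated by
  hours. The stored caregiver employment fraction (0.633) is not an extra
  multiplier: the monthly work values already combine paid and unpaid work.

All per-day quantities use 365.25/12 ≈ 30.44 days per month; weekly
quantities use (365.25/12)/7 weeks per month.

Both arms are cohorts mixing 55.8 % men; per-gender traces share
transitions, so gender only affects work values (via age bands, starting
ages 70 for men and 72 for women, caregivers 58 % male aged 51.7).

## 4. Cost-utility analysis

For each perspective the comparison reports Δcost and ΔQALY (s-VLPD minus
LPD) and a verdict: *dominant* (cheaper, more effective), *dominated*,
an ICER when one quantity trades against the other, or *equivalent*.
Net monetary benefit is `NMB(λ) = λ·ΔQALY − ΔCost`.

## 5. Sensitivity analyses

**Deterministic (one-way).** Parameters with 95 % CIs (hazard ratio,
transition probabilities, utilities) are set to each CI bound; unit costs
and mix shares without CIs are varied ±20 % (mix shares renormalized).
Parameters with neither a CI nor a cost interpretation are skipped with a
logged notice. Results are tornado tables sorted by swing in Δcost or
ΔQALY.

**Probabilistic.** Distribution families, moment-matched to point estimate
and CI (Z = 1.959964, sd = (hi − lo)/2Z):

| parameter type | distribution |
|---|---|
| probabilities, utilities | beta (method of moments) |
| hazard ratio | lognormal (CI symmetric on the log scale) |
| unit costs | gamma, ±20 % taken as a 95 % interval |
| modality mix | Dirichlet, concentration 100 |

Draws use `numpy.random.default_rng(seed)`; identical seeds give
byte-identical outputs. Infeasible moment combinations raise a named
`DistributionError` rather than silently clamping. Outputs: the draw set,
the cost-effectiveness acceptability curve (fraction of draws with positive
NMB per willingness-to-pay value), and a 95 % confidence ellipse on the
(ΔQALY, Δcost) plane from the sample mean and covariance scaled by
`chi²₀.₉₅(2)`.

## 6. Scenarios

1. **Societal perspective**: adds indirect costs; effectiveness unchanged.
2. **Dialysis-mortality benefit**: the s-VLPD arm uses 10.8 %/yr dialysis
   mortality (patients enter dialysis in better clinical condition);
   LPD arm unchanged.
3. **Partial adherence**: the state space splits pre-dialysis into
   "on s-VLPD" and "switched to LPD". A fixed flow of
   `switch_fraction / switch_window` of the *initial* cohort (42 % over
   6 months by default) moves from the former to the latter after each of
   the first `switch_window` cycles, capped by available occupancy (caps
   are logged on the trace). Switched patients progress at the LPD onset
   hazard and incur the LPD cost profile. This linear-redistribution
   reading yields a dialysis delay between the pure-LPD and pure-s-VLPD
   extremes, approaching LPD as the switch fraction → 1.

## 7. Data provenance and placeholders

Every scalar parameter is an `Estimate` carrying `value`, optional CI and a
`provenance` tag. Clinical transitions, demographics, resource-use
frequencies, the modality mix and adherence inputs are study values. Unit
prices, tariffs, utilities and work values are defaults tagged
`supplementary_placeholder`; CIs for the onset and mortality probabilities
(other than the hazard ratio) are likewise placeholder-tagged. Consequences:

- Time-in-state and survival outcomes are exact model outputs of the study
  inputs and do not depend on any placeholder.
- Monetary and QALY totals demonstrate that the accounting machinery is
  correct (they are covered by hand-computed oracles), but their absolute
  levels are conditional on the placeholder prices/utilities. The
  acceptance tests for the headline monetary results check provenance and
  report themselves as skipped while placeholders are in use; supplying
  sourced values in a config file activates them unchanged.

User-supplied values merge over the defaults and are re-tagged `user`;
supplying a value without a CI clears the default CI (removing that
parameter from CI-based sensitivity analysis rather than pairing a new
value with a stale interval).

## 8. Numerical choices

- Stop threshold 1e-4 surviving fraction; horizon cap 1440 cycles.
- The constant 3-state cycle matrix admits a closed form
  (`pre_k = a^k`, `dial_k = c·(a^k − b^k)/(a − b)`); the engine uses it as
  a fast path and falls back to generic matrix iteration whenever the
  structure is non-standard (e.g. the adherence scenario). Both paths are
  tested for equality.
- Discounting uses exact per-cycle factors, not annual approximations.

## 9. Limitations

- No transplantation state and no age-dependent background mortality; the
  constant-hazard assumption overstates late-life survival slightly.
- Utilities are not age-adjusted.
- The modality mix is fixed at dialysis entry and over time.
- The adherence scenario's switching rule is a stylized linear flow, not an
  estimated time-to-discontinuation distribution.
- Monetary results depend on placeholder unit costs/utilities until sourced
  values are supplied (section 7).
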