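# ckdcea

A Markov cohort cost-utility model of a ketoanalogue-supplemented
very-low-protein diet (s-VLPD) versus a conventional low-protein diet (LPD)
in chronic kidney disease (CKD) stages 4–5, from the perspective of the
Italian National Health Service (NHS) and of society.

## Scientific background

Nutritional therapy is one of the few interventions that can delay the need
for renal replacement therapy (RRT) in advanced CKD. A very-low-protein diet
(0.3–0.4 g/kg/day) supplemented with ketoanalogues of essential amino acids
substantially reduces the rate of progression to dialysis compared with a
standard low-protein diet (0.6 g/kg/day). Dialysis is both costly and
associated with lower quality of life, so delaying it may save money and
gain quality-adjusted life years (QALYs) at the same time — the intervention
can be *dominant*.

This package quantifies that trade-off with a cohort state-transition model
and reports survival, time on and off dialysis, QALYs, disaggregated costs,
incremental results, deterministic and probabilistic sensitivity analyses,
and three scenario analyses.

## The model

Three health states with monthly cycles over a lifetime horizon:

```
pre-dialysis  ──►  dialysis  ──►  dead
      └──────────────────────────────┘
```

Death is absorbing and there is no return from dialysis to pre-dialysis.
Annual probabilities are converted to rates, `r = −ln(1 − p)`, and treatment
effects are applied on the hazard scale: the s-VLPD arm uses
`p' = 1 − (1 − p)^HR` with HR = 0.237 on the annual dialysis-onset
probability of 24.4 %. Competing exits from the pre-dialysis state (dialysis
onset vs death) are combined by summing hazards and allocating the total
exit probability proportionally to the component rates. A half-cycle
correction is applied to all occupancy-derived outcomes. QALYs and costs are
discounted at 3 %/year; state times and survival are reported undiscounted
(a `discount_life_years` setting is available).

Costs on the NHS perspective comprise ketoanalogue tablets (18/day while
pre-dialysis on s-VLPD), dietary monitoring visits, other supplementation
(bicarbonate, vitamin D, calcium), and dialysis (modality-mix-weighted
tariffs for haemodialysis, CAPD and APD, a one-off catheter/access cost at
dialysis entry, and amortized home-dialysis maintenance). The societal
perspective adds productivity losses of patients and caregivers, valued from
gender- and age-specific monthly work values.

Scenarios: (1) societal perspective; (2) a dialysis-mortality benefit in the
s-VLPD arm (10.8 %/yr instead of 13.8 %/yr, reflecting better clinical
condition at dialysis entry after ketoanalogue treatment); (3) partial
adherence, in which 42 % of the s-VLPD cohort switches to LPD behaviour over
the first six months.

See [docs/methods.md](docs/methods.md) for the full methods note, parameter
tables and limitations.

## Worked example

The base case with default parameters:

```bash
ckdcea run --out-dir results
```

prints (and writes to `results/base_case.tsv`):

```
                           outcome          LPD       s-VLPD         delta
                  Survival (years)     7.285618     7.877539      0.591920
              Time pre-RRT (years)     2.516764     5.436330      2.919566
          Time in dialysis (years)     4.768854     2.441208     -2.327646
                             QALYs     4.118695     4.814246      0.695551
Total costs (NHS perspective, EUR) 69497.518267 46712.823988 -22784.694278
               Ketoanalogues (EUR)     0.000000 12332.412267  12332.412267
             Diet monitoring (EUR)   281.446153  1125.476821    844.030668
                    Dialysis (EUR) 68747.679424 32579.197009 -36168.482415
       Other supplementation (EUR)   468.392690   675.737891    207.345202
```

The supplemented diet delays dialysis by about 2.9 undiscounted years,
gains about 0.59 years of survival, and — even paying for the ketoanalogue
tablets and extra monitoring — lowers total discounted costs through avoided
dialysis, so it dominates. (Monetary figures above use clearly-tagged
placeholder unit costs and utilities; see "Placeholder values" below.
Time-in-state and survival outcomes depend only on the clinical transition
inputs and are final.)

The dialysis-mortality-benefit scenario:

```bash
ckdcea scenario --kind mortality --out-dir results
```

```
                  Survival (years)     7.285618     8.603769      1.318151
          Time in dialysis (years)     4.768854     3.167412     -1.601442
```

A probabilistic sensitivity analysis (seed required for reproducibility):

```bash
ckdcea psa --n 200 --seed 42 --out-dir results
# PSA (200 draws, seed 42): mean delta cost -22564.64 EUR, mean delta QALY 0.6743
```

Other commands: `ckdcea dsa` (one-way tornado tables), `ckdcea scenario
--kind societal|adherence`, `ckdcea fixtures` (export the default parameter
file to YAML for editing). Add `--plot` to `psa`/`dsa` for PNG figures
(requires the `plot` extra). Every command writes a `manifest.json`
recording the command, config, seed and outputs.

Parameters can be overridden with a partial YAML file merged over the
defaults:

```yaml
# my_params.yaml
transition:
  hr_dialysis_svlpd: {value: 0.30, ci_low: 0.25, ci_high: 0.36}
costs:
  ketoanalogue_price_per_tablet: 0.35
```

```bash
ckdcea run --config my_params.yaml
```

## Placeholder values

Clinical transition inputs, demographics, resource-use frequencies and the
dialysis modality mix are study values. Unit prices (ketoanalogue tablet,
visit and dialysis tariffs), health-state utilities and work values were not
available to this implementation; they ship as sensible defaults tagged
`supplementary_placeholder` in the parameter registry. All time-in-state
results are unaffected by these placeholders. Monetary and QALY totals are
internally consistent but should only be quoted after substituting sourced
unit costs and utilities via a config file; the acceptance tests for the
headline monetary results detect placeholders and report themselves as
skipped until then.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers parameter validation and round-tripping, closed-form
oracles for the Markov engine, hand-computed cost oracles, property-based
tests (hypothesis), sensitivity-analysis distribution checks, scenario
invariants, the CLI, and the acceptance criteria in
`tests/test_acceptance.py`.

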