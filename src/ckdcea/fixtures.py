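"""Default parameter sets and randomized valid sets for testing.

The default set carries the clinical and resource-use inputs of the Italian
CKD stage 4–5 cost-utility analysis verbatim (dialysis-onset and mortality
probabilities, the dialysis-onset hazard ratio, cohort demographics, the
census dialysis-modality mix, supplement usage, monitoring frequencies,
scenario parameters).  Unit prices, tariffs, utilities and the monthly
work-value table come from supplementary fee schedules that are not part of
this package; they ship as order-of-magnitude placeholders tagged
``supplementary_placeholder`` whose only job is to keep every cost and QALY
code path exercised.  Analyses of euro-denominated results with the
placeholder values are structural checks, not estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .params import (
    AdherenceScenarioInputs,
    CohortDemographics,
    DialysisMix,
    Estimate,
    IndirectCostInputs,
    ModelSettings,
    ParameterSet,
    SupplementProfile,
    SupplementUse,
    TransitionInputs,
    UnitCosts,
    Utilities,
    WorkValueBand,
    WorkValueTable,
)


def _paper(value: float, lo: float | None = None, hi: float | None = None) -> Estimate:
    return Estimate(value=value, ci_low=lo, ci_high=hi, provenance="paper")


def _placeholder(value: float, lo: float | None = None, hi: float | None = None) -> Estimate:
    return Estimate(
        value=value, ci_low=lo, ci_high=hi, provenance="supplementary_placeholder"
    )


def default_parameters() -> ParameterSet:
    """The registry defaults: primary-source values plus tagged placeholders."""
    transition = TransitionInputs(
        # 24.4 %/yr dialysis onset on the low-protein diet; CI bounds for the
        # sensitivity analyses are placeholders (the source CI is not in the
        # primary text)
        p_dialysis_annual_lpd=Estimate(
            value=0.244, ci_low=0.20, ci_high=0.29,
            provenance="supplementary_placeholder",
        ),
        hr_dialysis_svlpd=_paper(0.237, 0.22, 0.26),
        p_death_pre_annual=Estimate(
            value=0.111, ci_low=0.09, ci_high=0.135,
            provenance="supplementary_placeholder",
        ),
        p_death_dialysis_annual=Estimate(
            value=0.138, ci_low=0.115, ci_high=0.16,
            provenance="supplementary_placeholder",
        ),
        p_death_dialysis_annual_scenario=_paper(0.108),
    )
    demographics = CohortDemographics(
        fraction_male=_paper(0.558),
        age_male=_paper(70.0),
        age_female=_paper(72.0),
    )
    mix = DialysisMix(share_hd=0.838, share_capd=0.077, share_apd=0.085)
    unit_costs = UnitCosts(
        ketoanalogue_per_tablet=_placeholder(0.40),
        tablets_per_day_keto=_paper(18.0),  # 6 tablets three times daily
        monitoring_visit=_placeholder(20.0),
        monitoring_interval_svlpd_months=1,
        monitoring_interval_lpd_months=2,
        tariff_hd_monthly=_placeholder(1600.0),
        tariff_capd_monthly=_placeholder(1200.0),
        tariff_apd_monthly=_placeholder(1200.0),
        pd_catheter_placement=_placeholder(1500.0),
        pd_annual_maintenance=_placeholder(500.0),
        bicarbonate_per_tablet=_placeholder(0.05),
        vitamin_d_per_tablet=_placeholder(0.50),
        calcium_per_tablet=_placeholder(0.10),
    )
    supplements = SupplementProfile(
        lpd={
            "bicarbonate": SupplementUse(usage_fraction=0.51, dose_tablets=6.4),
            "vitamin_d": SupplementUse(
                usage_fraction=0.54, dose_tablets=1.0, dose_period="week"
            ),
            "calcium": SupplementUse(usage_fraction=0.50, dose_tablets=6.9),
        },
        svlpd={
            "bicarbonate": SupplementUse(usage_fraction=0.29, dose_tablets=4.4),
            "vitamin_d": SupplementUse(
                usage_fraction=0.22, dose_tablets=1.0, dose_period="week"
            ),
            "calcium": SupplementUse(usage_fraction=0.50, dose_tablets=6.3),
        },
    )
    utilities = Utilities(
        u_pre_dialysis=_placeholder(0.80, 0.75, 0.85),
        u_hd=_placeholder(0.60, 0.55, 0.65),
        u_capd=_placeholder(0.62, 0.57, 0.67),
        u_apd=_placeholder(0.64, 0.59, 0.69),
    )
    work_table = WorkValueTable(
        bands=[
            # paid + unpaid work, EUR/month; placeholder magnitudes
            WorkValueBand(gender="male", age_min=15, age_max=65, value=2000.0),
            WorkValueBand(gender="female", age_min=15, age_max=65, value=1500.0),
            WorkValueBand(gender="male", age_min=65, age_max=75, value=800.0),
            WorkValueBand(gender="female", age_min=65, age_max=75, value=700.0),
            WorkValueBand(gender="male", age_min=75, age_max=200, value=500.0),
            WorkValueBand(gender="female", age_min=75, age_max=200, value=450.0),
        ]
    )
    indirect = IndirectCostInputs(
        monthly_work_value=work_table,
        time_lost_fraction_hd=0.50,
        time_lost_fraction_capd=0.30,
        time_lost_fraction_apd=0.20,
        caregiver_need_fraction=0.245,
        caregiver_hours_week_hd=12.0,
        caregiver_hours_week_pd=2.0,
        caregiver_employed_fraction=0.633,
        caregiver_fraction_male=0.58,
        caregiver_age=51.7,
        reference_weekly_hours=40.0,
    )
    return ParameterSet(
        transition=transition,
        demographics=demographics,
        dialysis_mix=mix,
        unit_costs=unit_costs,
        supplements=supplements,
        utilities=utilities,
        indirect=indirect,
        settings=ModelSettings(),
        adherence=AdherenceScenarioInputs(
            switch_fraction=_paper(0.42), switch_window_months=6
        ),
    )


def has_placeholder_costs(params: ParameterSet) -> bool:
    """True when any euro-denominated or utility input still carries the
    ``supplementary_placeholder`` tag, i.e. monetary/QALY outputs are
    structural only."""
    estimates = [est for _, est in params.unit_costs._cost_fields()]
    estimates += [
        params.utilities.u_pre_dialysis,
        params.utilities.u_hd,
        params.utilities.u_capd,
        params.utilities.u_apd,
    ]
    if any(e.provenance == "supplementary_placeholder" for e in estimates):
        return True
    return any(
        b.provenance == "supplementary_placeholder"
        for b in params.indirect.monthly_work_value.bands
    )


def _jitter_estimate(est: Estimate, rng: np.random.Generator, jitter: float,
                     *, lo: float = 0.0, hi: float | None = None,
                     strict_hi: bool = False) -> Estimate:
    factor = 1.0 + rng.uniform(-jitter, jitter)
    value = est.value * factor
    if hi is not None:
        cap = hi - 1e-9 if strict_hi else hi
        value = min(value, cap)
    value = max(value, lo)
    ci_low, ci_high = est.ci_low, est.ci_high
    if est.has_ci:
        ci_low = min(est.ci_low, value)
        ci_high = max(est.ci_high, value)
        if hi is not None and ci_high > hi:
            ci_high = hi
    return Estimate(
        value=value, ci_low=ci_low, ci_high=ci_high, provenance=est.provenance
    )


@dataclass
class FixtureBundle:
    """A base set plus seed-stamped perturbed sets and their generation log."""

    base: ParameterSet
    perturbed: list[ParameterSet]
    seed: int
    jitter: float
    log: list[dict] = dc_field(default_factory=list)

    def log_json(self) -> str:
        return json.dumps(self.log, indent=2)


def random_valid_parameters(seed: int, jitter: float = 0.2) -> ParameterSet:
    """A deterministic, validated perturbation of the default set.

    Each numeric input is scaled by an independent factor in
    ``[1 - jitter, 1 + jitter]`` and then clipped / renormalized back into
    its valid range; jitter 0 returns the defaults unchanged.
    """
    if not 0.0 <= jitter <= 0.5:
        raise ValueError(f"jitter must be in [0, 0.5]; got {jitter}")
    params = default_parameters()
    if jitter == 0.0:
        return params
    rng = np.random.default_rng(seed)
    p = params.model_copy(deep=True)

    t = p.transition
    t.p_dialysis_annual_lpd = _jitter_estimate(
        t.p_dialysis_annual_lpd, rng, jitter, hi=1.0, strict_hi=True
    )
    t.hr_dialysis_svlpd = _jitter_estimate(t.hr_dialysis_svlpd, rng, jitter)
    t.p_death_pre_annual = _jitter_estimate(
        t.p_death_pre_annual, rng, jitter, hi=1.0, strict_hi=True
    )
    t.p_death_dialysis_annual = _jitter_estimate(
        t.p_death_dialysis_annual, rng, jitter, hi=1.0, strict_hi=True
    )
    if t.p_death_dialysis_annual_scenario is not None:
        # the scenario value must stay below the base dialysis mortality
        scen = _jitter_estimate(
            t.p_death_dialysis_annual_scenario, rng, jitter, hi=1.0, strict_hi=True
        )
        if scen.value >= t.p_death_dialysis_annual.value:
            scen = scen.replace_value(t.p_death_dialysis_annual.value * 0.75)
        t.p_death_dialysis_annual_scenario = scen

    shares = np.array(
        [p.dialysis_mix.share_hd, p.dialysis_mix.share_capd, p.dialysis_mix.share_apd]
    )
    shares = shares * (1.0 + rng.uniform(-jitter, jitter, size=3))
    shares = shares / shares.sum()
    p.dialysis_mix = DialysisMix(
        share_hd=float(shares[0]), share_capd=float(shares[1]),
        share_apd=float(shares[2]), provenance=p.dialysis_mix.provenance,
    )

    u = p.unit_costs
    for name, _ in list(u._cost_fields()):
        setattr(u, name, _jitter_estimate(getattr(u, name), rng, jitter))
    u.tablets_per_day_keto = _jitter_estimate(u.tablets_per_day_keto, rng, jitter)

    ut = p.utilities
    for name in ("u_pre_dialysis", "u_hd", "u_capd", "u_apd"):
        setattr(ut, name, _jitter_estimate(getattr(ut, name), rng, jitter, hi=1.0))

    for arm in (p.supplements.lpd, p.supplements.svlpd):
        for agent, use in arm.items():
            arm[agent] = SupplementUse(
                usage_fraction=min(
                    1.0, use.usage_fraction * (1.0 + rng.uniform(-jitter, jitter))
                ),
                dose_tablets=use.dose_tablets * (1.0 + rng.uniform(-jitter, jitter)),
                dose_period=use.dose_period,
                provenance=use.provenance,
            )

    if p.adherence is not None:
        p.adherence.switch_fraction = _jitter_estimate(
            p.adherence.switch_fraction, rng, jitter, hi=1.0
        )
    return ParameterSet.model_validate(p.model_dump())


def fixture_bundle(seed: int, n: int = 5, jitter: float = 0.2) -> FixtureBundle:
    """Base set plus ``n`` perturbed sets with a JSON-able generation log."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    perturbed, log = [], []
    for s in child_seeds:
        perturbed.append(random_valid_parameters(int(s), jitter))
        log.append({"seed": int(s), "jitter": jitter})
    return FixtureBundle(
        base=default_parameters(), perturbed=perturbed, seed=seed,
        jitter=jitter, log=log,
    )
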