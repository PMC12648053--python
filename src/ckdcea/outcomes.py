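"""Outcome and cost accounting over a cohort trace.

Converts state occupancy into life-years, per-state times, QALYs and
itemized discounted costs under the payer (NHS) or societal perspective.
Times are reported undiscounted by default; QALYs and costs are discounted
at the annual rate in the model settings.  All per-day resource use is
converted with 365.25/12 days per month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import engine
from .params import (
    CohortDemographics,
    DialysisMix,
    IndirectCostInputs,
    ModelSettings,
    ParameterSet,
    SupplementProfile,
    UnitCosts,
    Utilities,
)

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass
class OutcomeSummary:
    """Aggregate outcomes for one strategy under one perspective."""

    strategy: str
    perspective: str
    survival_years: float
    time_pre_dialysis_years: float
    time_dialysis_years: float
    qalys: float
    cost_items: dict[str, float]

    @property
    def total_cost(self) -> float:
        return float(sum(self.cost_items.values()))

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "perspective": self.perspective,
            "survival_years": self.survival_years,
            "time_pre_dialysis_years": self.time_pre_dialysis_years,
            "time_dialysis_years": self.time_dialysis_years,
            "qalys": self.qalys,
            "cost_items": dict(self.cost_items),
            "total_cost": self.total_cost,
        }


def discount_factors(n_cycles: int, settings: ModelSettings) -> np.ndarray:
    """Per-cycle discount factors ``(1 + r)^(-k/12)`` for cycles 0..n-1."""
    k = np.arange(n_cycles)
    years = k * settings.cycle_length_months / engine.MONTHS_PER_YEAR
    return (1.0 + settings.discount_rate_annual) ** (-years)


def _pre_state_names(trace: engine.CohortTrace) -> list[str]:
    return [s for s in trace.states if s in engine.PRE_STATES]


def accumulate_time(
    trace: engine.CohortTrace,
    state: str,
    settings: ModelSettings,
    *,
    discounted: bool = False,
) -> float:
    """Expected years spent in ``state`` (sum of per-cycle credited occupancy
    times the cycle length, optionally discounted)."""
    occ = trace.cycle_occupancy(state, settings.half_cycle_correction)
    if discounted:
        occ = occ * discount_factors(len(occ), settings)
    return float(occ.sum() * trace.cycle_months / engine.MONTHS_PER_YEAR)


def time_pre_dialysis(trace: engine.CohortTrace, settings: ModelSettings,
                      *, discounted: bool = False) -> float:
    return sum(
        accumulate_time(trace, s, settings, discounted=discounted)
        for s in _pre_state_names(trace)
    )


def dialysis_utility(utilities: Utilities, mix: DialysisMix) -> float:
    """Mix-weighted mean utility across dialysis modalities."""
    return (
        mix.share_hd * utilities.u_hd.value
        + mix.share_capd * utilities.u_capd.value
        + mix.share_apd * utilities.u_apd.value
    )


def compute_qalys(
    trace: engine.CohortTrace,
    utilities: Utilities,
    mix: DialysisMix,
    settings: ModelSettings,
) -> float:
    """Discounted quality-adjusted life-years for one trace.  All
    pre-dialysis states (including the switched state of the adherence
    scenario) carry the pre-dialysis utility."""
    u_dial = dialysis_utility(utilities, mix)
    total = 0.0
    for state in _pre_state_names(trace):
        total += utilities.u_pre_dialysis.value * accumulate_time(
            trace, state, settings, discounted=True
        )
    total += u_dial * accumulate_time(trace, engine.DIAL, settings, discounted=True)
    return total


def dialysis_monthly_cost(unit: UnitCosts, mix: DialysisMix) -> float:
    """Census-weighted outpatient tariff plus amortized annual peritoneal
    dialysis maintenance, per patient-month in dialysis."""
    tariff = (
        mix.share_hd * unit.tariff_hd_monthly.value
        + mix.share_capd * unit.tariff_capd_monthly.value
        + mix.share_apd * unit.tariff_apd_monthly.value
    )
    maintenance = unit.pd_annual_maintenance.value * mix.share_pd / 12.0
    return tariff + maintenance


_AGENT_PRICE_FIELD = {
    "bicarbonate": "bicarbonate_per_tablet",
    "vitamin_d": "vitamin_d_per_tablet",
    "calcium": "calcium_per_tablet",
}


def supplement_monthly_cost(
    profile: SupplementProfile, unit: UnitCosts, strategy: str
) -> float:
    """Expected monthly cost of bicarbonate / vitamin D / calcium for one
    diet arm: usage fraction x tablets per month x unit price."""
    if strategy not in engine.STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    arm = profile.lpd if strategy == "lpd" else profile.svlpd
    total = 0.0
    for agent, use in arm.items():
        price = getattr(unit, _AGENT_PRICE_FIELD[agent]).value
        if use.dose_period == "day":
            doses_per_month = use.dose_tablets * DAYS_PER_MONTH
        elif use.dose_period == "week":
            doses_per_month = use.dose_tablets * DAYS_PER_MONTH / 7.0
        else:  # pragma: no cover - rejected at validation
            raise ValueError(f"unknown dose period {use.dose_period!r}")
        total += use.usage_fraction * doses_per_month * price
    return total


def ketoanalogue_monthly_cost(unit: UnitCosts) -> float:
    """Ketoanalogue supplementation cost per patient-month on the
    very-low-protein diet (average adult posology, 6 tablets thrice daily)."""
    return unit.ketoanalogue_per_tablet.value * unit.tablets_per_day_keto.value * DAYS_PER_MONTH


def monitoring_monthly_cost(unit: UnitCosts, strategy: str) -> float:
    """Dietary monitoring: one consultation per month on the
    very-low-protein diet, one every two months on the low-protein diet."""
    interval = (
        unit.monitoring_interval_svlpd_months
        if strategy == "svlpd"
        else unit.monitoring_interval_lpd_months
    )
    return unit.monitoring_visit.value / interval


def _blended_work_value(
    table, fraction_male: float, age_male: float, age_female: float
) -> float:
    return fraction_male * table.lookup("male", age_male) + (
        1.0 - fraction_male
    ) * table.lookup("female", age_female)


def indirect_monthly_cost(
    indirect: IndirectCostInputs,
    mix: DialysisMix,
    demographics: CohortDemographics,
    cycle: int,
    cycle_months: float = 1.0,
) -> float:
    """Societal cost per patient-month in dialysis: productivity loss
    (fraction of the month lost per modality, valued at the gender/age-
    specific monthly work value) plus informal caregiver time (weekly hours
    scaled against a reference working week).

    Patient age advances with model time; the caregiver profile is constant.
    """
    years_elapsed = cycle * cycle_months / engine.MONTHS_PER_YEAR
    frac_male = demographics.fraction_male.value
    patient_value = _blended_work_value(
        indirect.monthly_work_value,
        frac_male,
        demographics.age_male.value + years_elapsed,
        demographics.age_female.value + years_elapsed,
    )
    time_lost = (
        mix.share_hd * indirect.time_lost_fraction_hd
        + mix.share_capd * indirect.time_lost_fraction_capd
        + mix.share_apd * indirect.time_lost_fraction_apd
    )
    productivity = time_lost * patient_value

    caregiver_value = _blended_work_value(
        indirect.monthly_work_value,
        indirect.caregiver_fraction_male,
        indirect.caregiver_age,
        indirect.caregiver_age,
    )
    hours_week = (
        mix.share_hd * indirect.caregiver_hours_week_hd
        + mix.share_pd * indirect.caregiver_hours_week_pd
    )
    caregiver = (
        indirect.caregiver_need_fraction
        * (hours_week / indirect.reference_weekly_hours)
        * caregiver_value
    )
    return productivity + caregiver


def strategy_costs(
    trace: engine.CohortTrace,
    params: ParameterSet,
    strategy: str,
    perspective: str,
    settings: Optional[ModelSettings] = None,
) -> dict[str, float]:
    """Itemized discounted lifetime costs for one strategy.

    Ketoanalogues accrue only while on the very-low-protein diet (the
    ``pre_switched`` state of the adherence scenario reverts to the
    low-protein-diet cost profile); monitoring and the other supplements
    accrue in all pre-dialysis states at the profile of the diet actually
    followed; dialysis tariffs accrue in the dialysis state; peritoneal
    catheter placement is charged once per new dialysis entrant times the
    peritoneal share; indirect items only under the societal perspective.
    """
    if perspective not in ("nhs", "societal"):
        raise ValueError(f"unknown perspective {perspective!r}")
    if settings is None:
        settings = params.settings
    unit = params.unit_costs
    mix = params.dialysis_mix
    hcc = settings.half_cycle_correction

    n = trace.n_cycles
    disc = discount_factors(n, settings)

    # months credited to each diet profile per cycle
    svlpd_months = np.zeros(n)
    lpd_months = np.zeros(n)
    for state in _pre_state_names(trace):
        occ = trace.cycle_occupancy(state, hcc) * trace.cycle_months
        on_svlpd = (strategy == "svlpd" and state == engine.PRE) or state == engine.PRE_SVLPD
        if on_svlpd:
            svlpd_months += occ
        else:
            lpd_months += occ
    dial_months = trace.cycle_occupancy(engine.DIAL, hcc) * trace.cycle_months

    items: dict[str, float] = {}
    items["ketoanalogue"] = float(
        (svlpd_months * disc).sum() * ketoanalogue_monthly_cost(unit)
    )
    items["monitoring"] = float(
        (svlpd_months * disc).sum() * monitoring_monthly_cost(unit, "svlpd")
        + (lpd_months * disc).sum() * monitoring_monthly_cost(unit, "lpd")
    )
    items["other_supplements"] = float(
        (svlpd_months * disc).sum() * supplement_monthly_cost(params.supplements, unit, "svlpd")
        + (lpd_months * disc).sum() * supplement_monthly_cost(params.supplements, unit, "lpd")
    )
    dialysis_running = float((dial_months * disc).sum() * dialysis_monthly_cost(unit, mix))
    catheter = float(
        (trace.new_dialysis_entries * disc).sum()
        * mix.share_pd
        * unit.pd_catheter_placement.value
    )
    items["dialysis"] = dialysis_running + catheter

    if perspective == "societal":
        indirect_per_month = np.array(
            [
                indirect_monthly_cost(
                    params.indirect, mix, params.demographics, k, trace.cycle_months
                )
                for k in range(n)
            ]
        )
        items["indirect"] = float((dial_months * disc * indirect_per_month).sum())
    return items


def summarize(
    trace: engine.CohortTrace,
    params: ParameterSet,
    strategy: str,
    perspective: Optional[str] = None,
    settings: Optional[ModelSettings] = None,
) -> OutcomeSummary:
    """Full outcome summary (times, QALYs, itemized costs) for one trace."""
    if settings is None:
        settings = params.settings
    if perspective is None:
        perspective = settings.perspective
    disc_times = settings.discount_life_years
    t_pre = time_pre_dialysis(trace, settings, discounted=disc_times)
    t_dial = accumulate_time(trace, engine.DIAL, settings, discounted=disc_times)
    return OutcomeSummary(
        strategy=strategy,
        perspective=perspective,
        survival_years=t_pre + t_dial,
        time_pre_dialysis_years=t_pre,
        time_dialysis_years=t_dial,
        qalys=compute_qalys(trace, params.utilities, params.dialysis_mix, settings),
        cost_items=strategy_costs(trace, params, strategy, perspective, settings),
    )
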