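"""Parameter registry: typed model inputs with provenance and uncertainty.

Every numeric model input is stored as an :class:`Estimate` carrying a point
value, an optional 95 % confidence interval (used by the deterministic and
probabilistic sensitivity analyses), and a provenance tag distinguishing
values printed in the primary clinical/cost sources (``paper``) from
order-of-magnitude placeholders standing in for unit prices, tariffs,
utilities and work values that are only available in supplementary cost
schedules (``supplementary_placeholder``), and from user overrides
(``user``).

The full set is serialized to / loaded from a strict YAML document: unknown
keys are rejected, since a silently ignored typo in a health-economic model
can move results by tens of thousands of euro.
"""

from __future__ import annotations

import math
from typing import ClassVar, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

Provenance = Literal["paper", "supplementary_placeholder", "user"]

SUM_TOL = 1e-9


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class Estimate(StrictModel):
    """A scalar model input: point value, optional 95 % CI, provenance tag.

    When no CI is given the parameter is treated as fixed in the
    deterministic sensitivity analysis (rather than inventing a range) and
    degenerate in the probabilistic one.
    """

    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    provenance: Provenance = "paper"

    @model_validator(mode="after")
    def _check_ci(self) -> "Estimate":
        has_low = self.ci_low is not None
        has_high = self.ci_high is not None
        if has_low != has_high:
            raise ValueError("ci_low and ci_high must be given together")
        if has_low and not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError(
                f"CI [{self.ci_low}, {self.ci_high}] does not bracket value {self.value}"
            )
        return self

    @property
    def has_ci(self) -> bool:
        return (
            self.ci_low is not None
            and self.ci_high is not None
            and self.ci_high > self.ci_low
        )

    def replace_value(self, value: float) -> "Estimate":
        """Copy with a new point value; CI is dropped (no longer meaningful)."""
        return Estimate(value=value, provenance=self.provenance)


def _require_prob(est: Estimate, name: str, *, strict_upper: bool = True) -> None:
    hi_ok = est.value < 1.0 if strict_upper else est.value <= 1.0
    if not (0.0 <= est.value and hi_ok):
        upper = "1)" if strict_upper else "1]"
        raise ValueError(f"{name} must be a probability in [0, {upper}; got {est.value}")


class TransitionInputs(StrictModel):
    """Annual transition inputs for the three-state disease model.

    ``p_dialysis_annual_lpd`` is the annual probability of starting dialysis
    under the low-protein diet; the supplemented very-low-protein diet arm
    scales the corresponding hazard by ``hr_dialysis_svlpd``.  Mortality is
    state-specific and constant over time.  The scenario dialysis mortality
    applies only in the dialysis-mortality-benefit scenario.
    """

    p_dialysis_annual_lpd: Estimate
    hr_dialysis_svlpd: Estimate
    p_death_pre_annual: Estimate
    p_death_dialysis_annual: Estimate
    p_death_dialysis_annual_scenario: Optional[Estimate] = None

    @model_validator(mode="after")
    def _check(self) -> "TransitionInputs":
        _require_prob(self.p_dialysis_annual_lpd, "p_dialysis_annual_lpd")
        _require_prob(self.p_death_pre_annual, "p_death_pre_annual")
        _require_prob(self.p_death_dialysis_annual, "p_death_dialysis_annual")
        if self.p_death_dialysis_annual_scenario is not None:
            _require_prob(
                self.p_death_dialysis_annual_scenario,
                "p_death_dialysis_annual_scenario",
            )
        if self.hr_dialysis_svlpd.value <= 0:
            raise ValueError(
                f"hr_dialysis_svlpd must be > 0; got {self.hr_dialysis_svlpd.value}"
            )
        return self


class CohortDemographics(StrictModel):
    fraction_male: Estimate
    age_male: Estimate
    age_female: Estimate

    @model_validator(mode="after")
    def _check(self) -> "CohortDemographics":
        _require_prob(self.fraction_male, "fraction_male", strict_upper=False)
        if self.age_male.value <= 0 or self.age_female.value <= 0:
            raise ValueError("ages must be positive")
        return self


class DialysisMix(StrictModel):
    """Modality shares among prevalent dialysis patients (census weights)."""

    share_hd: float
    share_capd: float
    share_apd: float
    provenance: Provenance = "paper"

    @model_validator(mode="after")
    def _check(self) -> "DialysisMix":
        shares = (self.share_hd, self.share_capd, self.share_apd)
        if any(s < 0 for s in shares):
            raise ValueError(f"dialysis mix shares must be >= 0; got {shares}")
        if abs(sum(shares) - 1.0) > SUM_TOL:
            raise ValueError(f"dialysis mix shares must sum to 1; got {sum(shares)}")
        return self

    @property
    def share_pd(self) -> float:
        return self.share_capd + self.share_apd

    def renormalized(self) -> "DialysisMix":
        total = self.share_hd + self.share_capd + self.share_apd
        return DialysisMix(
            share_hd=self.share_hd / total,
            share_capd=self.share_capd / total,
            share_apd=self.share_apd / total,
            provenance=self.provenance,
        )


class UnitCosts(StrictModel):
    """Unit prices and tariffs (EUR).  Tariff/price levels come from
    supplementary fee schedules and ship as tagged placeholders; resource
    quantities (tablets per day, visit intervals) are primary inputs."""

    ketoanalogue_per_tablet: Estimate
    tablets_per_day_keto: Estimate
    monitoring_visit: Estimate
    monitoring_interval_svlpd_months: int = Field(ge=1)
    monitoring_interval_lpd_months: int = Field(ge=1)
    tariff_hd_monthly: Estimate
    tariff_capd_monthly: Estimate
    tariff_apd_monthly: Estimate
    pd_catheter_placement: Estimate
    pd_annual_maintenance: Estimate
    bicarbonate_per_tablet: Estimate
    vitamin_d_per_tablet: Estimate
    calcium_per_tablet: Estimate

    @model_validator(mode="after")
    def _check(self) -> "UnitCosts":
        for name, est in self._cost_fields():
            if est.value < 0:
                raise ValueError(f"{name} must be >= 0; got {est.value}")
        return self

    def _cost_fields(self):
        for name in (
            "ketoanalogue_per_tablet",
            "monitoring_visit",
            "tariff_hd_monthly",
            "tariff_capd_monthly",
            "tariff_apd_monthly",
            "pd_catheter_placement",
            "pd_annual_maintenance",
            "bicarbonate_per_tablet",
            "vitamin_d_per_tablet",
            "calcium_per_tablet",
        ):
            yield name, getattr(self, name)


DosePeriod = Literal["day", "week"]


class SupplementUse(StrictModel):
    """Usage of one supplemental agent in one diet arm."""

    usage_fraction: float = Field(ge=0.0, le=1.0)
    dose_tablets: float = Field(ge=0.0)
    dose_period: DosePeriod = "day"
    provenance: Provenance = "paper"


class SupplementProfile(StrictModel):
    """Per-arm usage of sodium bicarbonate, vitamin D and calcium — the
    supplements whose use differed significantly between the two diets."""

    lpd: dict[str, SupplementUse]
    svlpd: dict[str, SupplementUse]

    KNOWN_AGENTS: ClassVar[tuple[str, ...]] = ("bicarbonate", "vitamin_d", "calcium")

    @model_validator(mode="after")
    def _check(self) -> "SupplementProfile":
        for arm_name, arm in (("lpd", self.lpd), ("svlpd", self.svlpd)):
            for agent in arm:
                if agent not in self.KNOWN_AGENTS:
                    raise ValueError(
                        f"unknown supplement agent {agent!r} in arm {arm_name}"
                    )
        return self


class Utilities(StrictModel):
    """Health-state preference weights on the 0 (death) – 1 (full health)
    scale; dialysis utility is modality-specific and mix-weighted."""

    u_pre_dialysis: Estimate
    u_hd: Estimate
    u_capd: Estimate
    u_apd: Estimate

    @model_validator(mode="after")
    def _check(self) -> "Utilities":
        for name in ("u_pre_dialysis", "u_hd", "u_capd", "u_apd"):
            est = getattr(self, name)
            if not (0.0 <= est.value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]; got {est.value}")
        return self


class WorkValueBand(StrictModel):
    """Monthly value of paid and unpaid work for one gender / age band."""

    gender: Literal["male", "female"]
    age_min: float = Field(ge=0.0)
    age_max: float
    value: float = Field(ge=0.0)
    provenance: Provenance = "supplementary_placeholder"

    @model_validator(mode="after")
    def _check(self) -> "WorkValueBand":
        if self.age_max < self.age_min:
            raise ValueError("age_max must be >= age_min")
        return self


class WorkValueTable(StrictModel):
    bands: list[WorkValueBand]

    def lookup(self, gender: str, age: float) -> float:
        """Value for a half-open age band ``[age_min, age_max)``; the last
        matching-gender band is treated as open-ended above."""
        last = None
        for band in self.bands:
            if band.gender != gender:
                continue
            if band.age_min <= age < band.age_max:
                return band.value
            last = band
        if last is not None and age >= last.age_max:
            return last.value
        raise KeyError(f"no work-value band for (gender={gender!r}, age={age:.1f})")


class IndirectCostInputs(StrictModel):
    """Inputs for the societal perspective: patient productivity loss during
    dialysis and informal caregiver time."""

    monthly_work_value: WorkValueTable
    time_lost_fraction_hd: float = Field(ge=0.0, le=1.0)
    time_lost_fraction_capd: float = Field(ge=0.0, le=1.0)
    time_lost_fraction_apd: float = Field(ge=0.0, le=1.0)
    caregiver_need_fraction: float = Field(ge=0.0, le=1.0)
    caregiver_hours_week_hd: float = Field(ge=0.0)
    caregiver_hours_week_pd: float = Field(ge=0.0)
    caregiver_employed_fraction: float = Field(ge=0.0, le=1.0)
    caregiver_fraction_male: float = Field(ge=0.0, le=1.0)
    caregiver_age: float = Field(gt=0.0)
    # conversion from caregiver hours/week to a fraction of the monthly work
    # value; a full working week is the reference
    reference_weekly_hours: float = Field(default=40.0, gt=0.0)


Perspective = Literal["nhs", "societal"]


class ModelSettings(StrictModel):
    """Simulation conventions: monthly cycles, 3 %/yr discounting of costs
    and QALYs, half-cycle correction, lifetime horizon with an occupancy
    stopping rule.  Life-years are reported undiscounted by default (the
    survival outputs are interpretable only on the natural time scale);
    ``discount_life_years`` applies the discount to times as well."""

    cycle_length_months: float = 1.0
    discount_rate_annual: float = Field(default=0.03, ge=0.0)
    horizon_max_cycles: int = Field(default=1440, ge=1)
    stop_threshold_alive: float = Field(default=1e-4, gt=0.0, lt=1.0)
    half_cycle_correction: bool = True
    perspective: Perspective = "nhs"
    discount_life_years: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ModelSettings":
        if self.cycle_length_months != 1.0:
            raise ValueError("cycle length is fixed at 1 month")
        return self


class AdherenceScenarioInputs(StrictModel):
    """Partial-adherence scenario: a fraction of the very-low-protein-diet
    cohort abandons the diet, switching linearly over the first months."""

    switch_fraction: Estimate
    switch_window_months: int = Field(default=6, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "AdherenceScenarioInputs":
        _require_prob(self.switch_fraction, "switch_fraction", strict_upper=False)
        return self


class ParameterSet(StrictModel):
    """The complete, validated input set for one model configuration."""

    transition: TransitionInputs
    demographics: CohortDemographics
    dialysis_mix: DialysisMix
    unit_costs: UnitCosts
    supplements: SupplementProfile
    utilities: Utilities
    indirect: IndirectCostInputs
    settings: ModelSettings = ModelSettings()
    adherence: Optional[AdherenceScenarioInputs] = None

    def with_settings(self, **overrides) -> "ParameterSet":
        new = self.model_copy(deep=True)
        new.settings = self.settings.model_copy(update=overrides)
        return new


class ParameterError(ValueError):
    """Raised when a parameter file fails validation."""


def _merge_with_defaults(default: dict, override: dict, path: str = "") -> dict:
    """Deep-merge a (possibly partial) user config over the default dump.

    A scalar supplied where an Estimate lives is promoted to a ``user``
    estimate; an explicit ``value`` without a ``provenance`` key is tagged
    ``user`` as well.  Unknown keys are left in place so that strict
    validation rejects them by name.
    """
    merged = dict(default)
    for key, node in override.items():
        where = f"{path}.{key}" if path else key
        if key not in default:
            merged[key] = node  # surfaces as an "extra field" validation error
            continue
        base = default[key]
        is_estimate = isinstance(base, dict) and "value" in base
        if is_estimate and isinstance(node, (int, float)) and not isinstance(node, bool):
            merged[key] = {**base, "value": float(node), "ci_low": None,
                           "ci_high": None, "provenance": "user"}
        elif is_estimate and isinstance(node, dict):
            updated = {**base, **node}
            if "value" in node:
                # an explicit value without a CI means "no CI": the parameter
                # is then fixed in DSA rather than inheriting a stale range
                updated["ci_low"] = node.get("ci_low")
                updated["ci_high"] = node.get("ci_high")
                if "provenance" not in node:
                    updated["provenance"] = "user"
            merged[key] = updated
        elif isinstance(base, dict) and isinstance(node, dict):
            merged[key] = _merge_with_defaults(base, node, where)
        else:
            merged[key] = node
    return merged


def loads_parameters(text: str, *, merge_defaults: bool = True) -> ParameterSet:
    """Parse a YAML parameter document into a validated :class:`ParameterSet`.

    With ``merge_defaults`` (the default) the document may be partial: absent
    fields take the registry defaults and explicitly supplied values are
    tagged with ``user`` provenance.  Without it the document must be
    complete (as produced by :func:`serialize_parameters`).
    """
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterError("parameter document must be a mapping")
    if merge_defaults:
        from .fixtures import default_parameters

        raw = _merge_with_defaults(default_parameters().model_dump(), raw)
    try:
        return ParameterSet.model_validate(raw)
    except ValidationError as exc:
        raise ParameterError(str(exc)) from exc


def load_parameters(path, *, merge_defaults: bool = True) -> ParameterSet:
    """Load and validate a parameter file (see :func:`loads_parameters`)."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_parameters(fh.read(), merge_defaults=merge_defaults)


def serialize_parameters(params: ParameterSet) -> str:
    """Serialize a parameter set to YAML; round-trip stable under
    :func:`loads_parameters`."""
    data = params.model_dump(exclude_none=True)
    return yaml.safe_dump(data, sort_keys=False, default_flow_style=False)


def save_parameters(params: ParameterSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_parameters(params))
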