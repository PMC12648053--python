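"""Deterministic (one-way) and probabilistic sensitivity analyses.

DSA conventions: euro-denominated unit costs and the dialysis-modality mix
move ±20 % around the base case (the mix is renormalized after perturbing
one share); clinical-efficacy and utility parameters move to their 95 % CI
bounds.  A parameter without a CI is skipped rather than given an invented
range.

PSA conventions: probabilities and utilities are drawn from beta
distributions moment-matched to (point, CI); the dialysis-onset hazard
ratio from a log-normal matched to its CI; unit costs from gamma
distributions with the ±20 % band read as a 95 % interval; the modality mix
from a Dirichlet centred on the census shares.  All draws derive from a
single seeded generator, so draw sets are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cea, engine, outcomes
from .params import DialysisMix, Estimate, ParameterSet

logger = logging.getLogger(__name__)

#: total Dirichlet concentration for the modality-mix draws
DEFAULT_MIX_CONCENTRATION = 100.0
#: relative half-width of the cost band, read as a 95 % interval in the PSA
DEFAULT_COST_REL_RANGE = 0.20

Z95 = 1.959963984540054  # two-sided 95 % normal quantile


# ---------------------------------------------------------------------------
# shared evaluation
# ---------------------------------------------------------------------------


def evaluate(params: ParameterSet, perspective: str = "nhs") -> cea.CEAResult:
    """Run both arms and return the incremental comparison."""
    s = params.settings
    t = params.transition
    lpd = outcomes.summarize(
        engine.run_strategy(t, "lpd", s), params, "lpd", perspective
    )
    svlpd = outcomes.summarize(
        engine.run_strategy(t, "svlpd", s), params, "svlpd", perspective
    )
    return cea.compare(lpd, svlpd)


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class DsaEntry:
    parameter: str
    low: float
    high: float
    delta_cost_low: float
    delta_cost_high: float
    delta_qaly_low: float
    delta_qaly_high: float

    @property
    def cost_range(self) -> float:
        return abs(self.delta_cost_high - self.delta_cost_low)

    @property
    def qaly_range(self) -> float:
        return abs(self.delta_qaly_high - self.delta_qaly_low)


Setter = Callable[[ParameterSet, float], None]


def _estimate_paths(params: ParameterSet) -> list[tuple[str, Estimate, Setter, str]]:
    """Perturbable scalar parameters: (name, estimate, setter, kind).

    kind is ``ci`` (move to CI bounds; skipped without a CI) or ``cost``
    (±20 % multiplicative band).
    """
    entries: list[tuple[str, Estimate, Setter, str]] = []

    def t_set(fname: str) -> Setter:
        def setter(p: ParameterSet, v: float) -> None:
            est = getattr(p.transition, fname)
            setattr(p.transition, fname, est.replace_value(v))
        return setter

    for fname in (
        "p_dialysis_annual_lpd",
        "hr_dialysis_svlpd",
        "p_death_pre_annual",
        "p_death_dialysis_annual",
    ):
        entries.append(
            (f"transition.{fname}", getattr(params.transition, fname), t_set(fname), "ci")
        )

    def u_set(fname: str) -> Setter:
        def setter(p: ParameterSet, v: float) -> None:
            est = getattr(p.utilities, fname)
            setattr(p.utilities, fname, est.replace_value(v))
        return setter

    for fname in ("u_pre_dialysis", "u_hd", "u_capd", "u_apd"):
        entries.append(
            (f"utilities.{fname}", getattr(params.utilities, fname), u_set(fname), "ci")
        )

    def c_set(fname: str) -> Setter:
        def setter(p: ParameterSet, v: float) -> None:
            est = getattr(p.unit_costs, fname)
            setattr(p.unit_costs, fname, est.replace_value(v))
        return setter

    for fname, est in params.unit_costs._cost_fields():
        entries.append((f"unit_costs.{fname}", est, c_set(fname), "cost"))
    return entries


def _perturbed_mix(mix: DialysisMix, share_name: str, factor: float) -> DialysisMix:
    """Scale one share by ``factor`` and renormalize the three shares."""
    shares = {
        "share_hd": mix.share_hd,
        "share_capd": mix.share_capd,
        "share_apd": mix.share_apd,
    }
    shares[share_name] *= factor
    total = sum(shares.values())
    return DialysisMix(
        **{k: v / total for k, v in shares.items()}, provenance=mix.provenance
    )


def run_dsa(
    params: ParameterSet,
    perspective: str = "nhs",
    cost_rel_range: float = DEFAULT_COST_REL_RANGE,
) -> list[DsaEntry]:
    """One-way DSA over all eligible parameters.

    Returns one entry per parameter with the incremental cost and QALYs at
    the low and high input values; entries are sortable by
    :attr:`DsaEntry.cost_range` / :attr:`DsaEntry.qaly_range` for the two
    tornado diagrams.
    """
    entries: list[DsaEntry] = []

    def run_at(setter_val) -> cea.CEAResult:
        return evaluate(setter_val, perspective)

    for name, est, setter, kind in _estimate_paths(params):
        if kind == "ci":
            if not est.has_ci:
                logger.info("DSA: %s has no CI; skipped", name)
                continue
            low, high = est.ci_low, est.ci_high
        else:
            low = est.value * (1.0 - cost_rel_range)
            high = est.value * (1.0 + cost_rel_range)
            if low == high:  # zero cost: nothing to vary
                logger.info("DSA: %s has zero-width range; skipped", name)
                continue
        results = []
        for bound in (low, high):
            p = params.model_copy(deep=True)
            setter(p, bound)
            results.append(run_at(p))
        r_lo, r_hi = results
        entries.append(
            DsaEntry(
                parameter=name,
                low=low,
                high=high,
                delta_cost_low=r_lo.delta_cost,
                delta_cost_high=r_hi.delta_cost,
                delta_qaly_low=r_lo.delta_qaly,
                delta_qaly_high=r_hi.delta_qaly,
            )
        )

    for share_name in ("share_hd", "share_capd", "share_apd"):
        results, bounds = [], []
        for factor in (1.0 - cost_rel_range, 1.0 + cost_rel_range):
            p = params.model_copy(deep=True)
            p.dialysis_mix = _perturbed_mix(params.dialysis_mix, share_name, factor)
            bounds.append(getattr(p.dialysis_mix, share_name))
            results.append(run_at(p))
        r_lo, r_hi = results
        entries.append(
            DsaEntry(
                parameter=f"dialysis_mix.{share_name}",
                low=bounds[0],
                high=bounds[1],
                delta_cost_low=r_lo.delta_cost,
                delta_cost_high=r_hi.delta_cost,
                delta_qaly_low=r_lo.delta_qaly,
                delta_qaly_high=r_hi.delta_qaly,
            )
        )
    return entries


def dsa_frame(entries: Sequence[DsaEntry], sort_by: str = "cost") -> pd.DataFrame:
    """Tornado-ordered table (widest incremental-cost or -QALY range first)."""
    df = pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "delta_cost_low": [e.delta_cost_low for e in entries],
            "delta_cost_high": [e.delta_cost_high for e in entries],
            "delta_qaly_low": [e.delta_qaly_low for e in entries],
            "delta_qaly_high": [e.delta_qaly_high for e in entries],
        }
    )
    key = "cost_range" if sort_by == "cost" else "qaly_range"
    df["cost_range"] = (df["delta_cost_high"] - df["delta_cost_low"]).abs()
    df["qaly_range"] = (df["delta_qaly_high"] - df["delta_qaly_low"]).abs()
    return df.sort_values(key, ascending=False, ignore_index=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


class DistributionError(ValueError):
    """Raised when a PSA distribution cannot be matched to a parameter."""


def _beta_from_moments(name: str, mean: float, sd: float) -> stats.rv_frozen:
    if not 0.0 < mean < 1.0:
        raise DistributionError(
            f"{name}: beta moment match needs mean in (0,1); got {mean}"
        )
    max_sd = math.sqrt(mean * (1.0 - mean))
    if sd >= max_sd:
        raise DistributionError(
            f"{name}: sd {sd} infeasible for beta with mean {mean}"
        )
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return stats.beta(mean * nu, (1.0 - mean) * nu)


def _gamma_from_moments(name: str, mean: float, sd: float) -> stats.rv_frozen:
    if mean <= 0 or sd <= 0:
        raise DistributionError(f"{name}: gamma needs positive mean and sd")
    shape = (mean / sd) ** 2
    return stats.gamma(shape, scale=sd**2 / mean)


def _lognormal_from_ci(name: str, point: float, lo: float, hi: float) -> stats.rv_frozen:
    if not 0 < lo <= point <= hi:
        raise DistributionError(
            f"{name}: log-normal CI must satisfy 0 < low <= point <= high"
        )
    sigma = (math.log(hi) - math.log(lo)) / (2 * Z95)
    return stats.lognorm(s=sigma, scale=point)


def _ci_sd(est: Estimate) -> float:
    return (est.ci_high - est.ci_low) / (2 * Z95)


@dataclass
class PsaDrawSet:
    """Per-draw sampled inputs and incremental outcomes."""

    seed: int
    n_draws: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    delta_survival: np.ndarray
    samples: pd.DataFrame
    perspective: str = "nhs"

    def frame(self) -> pd.DataFrame:
        df = self.samples.copy()
        df.insert(0, "draw", np.arange(self.n_draws))
        df["delta_cost"] = self.delta_cost
        df["delta_qaly"] = self.delta_qaly
        df["delta_survival"] = self.delta_survival
        return df


def sample_psa(
    params: ParameterSet,
    n: int,
    seed: int,
    *,
    perspective: str = "nhs",
    cost_rel_range: float = DEFAULT_COST_REL_RANGE,
    mix_concentration: Optional[float] = DEFAULT_MIX_CONCENTRATION,
) -> PsaDrawSet:
    """Draw ``n`` parameter sets and run the model once per draw.

    Parameters without a CI are held fixed; ``cost_rel_range=0`` fixes the
    unit costs and ``mix_concentration=None`` fixes the modality mix, which
    together with degenerate CIs reproduces the base case in every draw.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    rng = np.random.default_rng(seed)

    scalar_specs = []  # (name, setter, frozen distribution or None)
    for name, est, setter, kind in _estimate_paths(params):
        if kind == "ci":
            if not est.has_ci:
                continue
            if name == "transition.hr_dialysis_svlpd":
                dist = _lognormal_from_ci(name, est.value, est.ci_low, est.ci_high)
            else:
                dist = _beta_from_moments(name, est.value, _ci_sd(est))
        else:
            if cost_rel_range <= 0 or est.value == 0:
                continue
            dist = _gamma_from_moments(
                name, est.value, cost_rel_range * est.value / Z95
            )
        scalar_specs.append((name, setter, dist))

    columns: dict[str, np.ndarray] = {}
    for name, _, dist in scalar_specs:
        columns[name] = dist.rvs(size=n, random_state=rng)

    if mix_concentration is not None:
        base_mix = params.dialysis_mix
        alpha = (
            np.array([base_mix.share_hd, base_mix.share_capd, base_mix.share_apd])
            * mix_concentration
        )
        mix_draws = rng.dirichlet(alpha, size=n)
        columns["dialysis_mix.share_hd"] = mix_draws[:, 0]
        columns["dialysis_mix.share_capd"] = mix_draws[:, 1]
        columns["dialysis_mix.share_apd"] = mix_draws[:, 2]
    else:
        mix_draws = None

    samples = pd.DataFrame(columns)
    dc = np.empty(n)
    dq = np.empty(n)
    ds = np.empty(n)
    for i in range(n):
        p = params.model_copy(deep=True)
        for name, setter, _ in scalar_specs:
            setter(p, float(columns[name][i]))
        if mix_draws is not None:
            p.dialysis_mix = DialysisMix(
                share_hd=float(mix_draws[i, 0]),
                share_capd=float(mix_draws[i, 1]),
                share_apd=float(mix_draws[i, 2]),
                provenance=params.dialysis_mix.provenance,
            )
        result = evaluate(p, perspective)
        dc[i] = result.delta_cost
        dq[i] = result.delta_qaly
        ds[i] = result.delta_survival
    return PsaDrawSet(
        seed=seed,
        n_draws=n,
        delta_cost=dc,
        delta_qaly=dq,
        delta_survival=ds,
        samples=samples,
        perspective=perspective,
    )


# ---------------------------------------------------------------------------
# CEAC and confidence ellipse
# ---------------------------------------------------------------------------


@dataclass
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def as_dict(self) -> dict:
        return {
            "wtp": self.wtp.tolist(),
            "probability": self.probability.tolist(),
        }


def ceac(draws: PsaDrawSet, wtp_grid: Sequence[float]) -> CeacCurve:
    """Fraction of draws with positive net monetary benefit at each
    willingness-to-pay threshold."""
    if draws.n_draws == 0:
        raise ValueError("draw set is empty")
    wtp = np.asarray(wtp_grid, dtype=float)
    nmb = wtp[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    return CeacCurve(wtp=wtp, probability=(nmb > 0).mean(axis=1))


@dataclass
class Ellipse:
    """Confidence ellipse on the (delta QALY, delta cost) plane from the
    sample mean and covariance, scaled by the chi-square(2) quantile."""

    center: np.ndarray
    semi_axes: np.ndarray
    angle_rad: float
    coverage: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "center": self.center.tolist(),
            "semi_axes": self.semi_axes.tolist(),
            "angle_rad": self.angle_rad,
            "coverage": self.coverage,
            "degenerate": self.degenerate,
        }

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for an (n, 2) array of (delta_qaly, delta_cost)."""
        pts = np.atleast_2d(points) - self.center
        cos_t, sin_t = math.cos(self.angle_rad), math.sin(self.angle_rad)
        rot = np.array([[cos_t, sin_t], [-sin_t, cos_t]])
        local = pts @ rot.T
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (local[:, 0] / self.semi_axes[0]) ** 2 + (
                local[:, 1] / self.semi_axes[1]
            ) ** 2
        return val <= 1.0 + 1e-12


def confidence_ellipse(points: np.ndarray | PsaDrawSet,
                       coverage: float = 0.95) -> Ellipse:
    """Ellipse parameters for the PSA cloud (or any (n, 2) point set)."""
    if isinstance(points, PsaDrawSet):
        pts = np.column_stack([points.delta_qaly, points.delta_cost])
    else:
        pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 draws for a covariance ellipse")
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1); got {coverage}")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    degenerate = bool(np.any(eigvals <= 1e-300))
    eigvals = np.clip(eigvals, 0.0, None)
    scale = stats.chi2.ppf(coverage, df=2)
    # eigh returns ascending eigenvalues; report the major axis first
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    semi_axes = np.sqrt(eigvals * scale)
    angle = math.atan2(eigvecs[1, 0], eigvecs[0, 0])
    return Ellipse(
        center=center,
        semi_axes=semi_axes,
        angle_rad=angle,
        coverage=coverage,
        degenerate=degenerate,
    )
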