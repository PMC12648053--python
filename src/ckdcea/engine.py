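"""Markov cohort engine: rate/probability conversions and the lifetime trace.

The disease model has three states — pre-dialysis, dialysis, dead — with
death absorbing and no return from dialysis to pre-dialysis.  Annual
transition probabilities are converted to constant hazards; competing exits
from the pre-dialysis state within one monthly cycle are handled by summing
the annual hazards, converting the summed hazard to a single per-cycle exit
probability, and allocating exits proportionally to the hazards.  This is
the discrete-time analogue of the continuous-time competing-risk model and
matches its closed-form state times to within one cycle length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .params import ModelSettings, TransitionInputs

MONTHS_PER_YEAR = 12.0

# canonical state labels
PRE = "pre_dialysis"
DIAL = "dialysis"
DEAD = "dead"
PRE_SVLPD = "pre_svlpd"
PRE_SWITCHED = "pre_switched"

BASE_STATES = (PRE, DIAL, DEAD)
ADHERENCE_STATES = (PRE_SVLPD, PRE_SWITCHED, DIAL, DEAD)

#: states during which patients are on their assigned pre-dialysis diet
PRE_STATES = frozenset({PRE, PRE_SVLPD, PRE_SWITCHED})

Strategy = str  # "lpd" | "svlpd"
STRATEGIES = ("lpd", "svlpd")


def annual_prob_to_rate(p_annual: float) -> float:
    """Convert an annual transition probability to a constant annual hazard,
    ``-ln(1 - p)``.  Inverse of :func:`rate_to_prob` at one year."""
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"annual probability must be in [0, 1); got {p_annual}")
    return -math.log1p(-p_annual)


def rate_to_prob(rate_annual: float, years: float = 1.0) -> float:
    """Probability of an event within ``years`` under constant hazard."""
    if rate_annual < 0:
        raise ValueError(f"rate must be >= 0; got {rate_annual}")
    return -math.expm1(-rate_annual * years)


def apply_hazard_ratio(p_annual: float, hr: float) -> float:
    """Scale an annual probability by a hazard ratio on the hazard scale:
    ``1 - (1 - p)^hr``.  A HR of 1 is the identity; 0 removes the event."""
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"annual probability must be in [0, 1); got {p_annual}")
    if hr < 0:
        raise ValueError(f"hazard ratio must be >= 0; got {hr}")
    return -math.expm1(hr * math.log1p(-p_annual))


def per_cycle_exit_split(
    rates_annual: Sequence[float], cycle_months: float
) -> tuple[float, np.ndarray]:
    """Exit probability and destination allocation for competing risks.

    Returns the total per-cycle exit probability
    ``1 - exp(-sum(rates) * cycle_months / 12)`` and the per-destination
    shares (proportional to each hazard).  With all rates zero the exit
    probability is 0 and the allocation is NaN (flagged as undefined).
    """
    rates = np.asarray(rates_annual, dtype=float)
    if np.any(rates < 0):
        raise ValueError(f"rates must be >= 0; got {rates_annual}")
    if cycle_months <= 0:
        raise ValueError(f"cycle_months must be > 0; got {cycle_months}")
    total = float(rates.sum())
    p_exit = -math.expm1(-total * cycle_months / MONTHS_PER_YEAR)
    if total == 0.0:
        return 0.0, np.full(rates.shape, np.nan)
    return p_exit, rates / total


def _pre_dialysis_row(
    p_onset_annual: float, p_death_annual: float, cycle_months: float
) -> np.ndarray:
    r_onset = annual_prob_to_rate(p_onset_annual)
    r_death = annual_prob_to_rate(p_death_annual)
    p_exit, shares = per_cycle_exit_split([r_onset, r_death], cycle_months)
    if p_exit == 0.0:
        return np.array([1.0, 0.0, 0.0])
    return np.array([1.0 - p_exit, p_exit * shares[0], p_exit * shares[1]])


def dialysis_monthly_death_prob(p_death_dialysis_annual: float,
                                cycle_months: float = 1.0) -> float:
    """Per-cycle death probability in the dialysis state."""
    rate = annual_prob_to_rate(p_death_dialysis_annual)
    return rate_to_prob(rate, cycle_months / MONTHS_PER_YEAR)


def build_cycle_matrix(
    inputs: TransitionInputs,
    strategy: Strategy,
    settings: ModelSettings,
    *,
    p_death_dialysis_annual: Optional[float] = None,
) -> np.ndarray:
    """Row-stochastic 3x3 per-cycle transition matrix over ``BASE_STATES``.

    For the s-VLPD strategy the dialysis-onset probability is scaled by the
    hazard ratio before rate conversion.  ``p_death_dialysis_annual``
    overrides the base dialysis mortality (used by the mortality-benefit
    scenario).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    p_onset = inputs.p_dialysis_annual_lpd.value
    if strategy == "svlpd":
        p_onset = apply_hazard_ratio(p_onset, inputs.hr_dialysis_svlpd.value)
    cm = settings.cycle_length_months
    pre_row = _pre_dialysis_row(p_onset, inputs.p_death_pre_annual.value, cm)
    p_dd = p_death_dialysis_annual
    if p_dd is None:
        p_dd = inputs.p_death_dialysis_annual.value
    p_death_cycle = dialysis_monthly_death_prob(p_dd, cm)
    return np.array(
        [
            pre_row,
            [0.0, 1.0 - p_death_cycle, p_death_cycle],
            [0.0, 0.0, 1.0],
        ]
    )


@dataclass
class CohortTrace:
    """Per-cycle state occupancy for one strategy.

    ``occupancy`` has one row per time point (``n_cycles + 1`` rows, row 0
    the initial vector).  ``new_dialysis_entries[k]`` is the fraction of the
    cohort entering dialysis during cycle ``k`` — needed to charge one-off
    peritoneal-dialysis costs at entry.
    """

    states: tuple[str, ...]
    occupancy: np.ndarray
    cycle_months: float
    new_dialysis_entries: np.ndarray
    horizon_capped: bool = False
    switch_capped_cycles: list[int] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"unknown state {state!r}; trace states: {self.states}")

    def state_occupancy(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.state_index(state)]

    def cycle_occupancy(self, state: str, half_cycle_correction: bool) -> np.ndarray:
        """Occupancy credited to each cycle: the average of start- and
        end-of-cycle occupancy under half-cycle correction, otherwise the
        end-of-cycle value."""
        occ = self.state_occupancy(state)
        if half_cycle_correction:
            return 0.5 * (occ[:-1] + occ[1:])
        return occ[1:]

    def alive(self) -> np.ndarray:
        dead = self.state_occupancy(DEAD)
        return 1.0 - dead

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "month", df["cycle"] * self.cycle_months)
        entries = np.concatenate([[0.0], self.new_dialysis_entries])
        df["new_dialysis_entries"] = entries
        df["cumulative_deaths"] = self.state_occupancy(DEAD)
        return df


MatrixProvider = Union[np.ndarray, Callable[[int], np.ndarray]]
PostTransition = Callable[[int, np.ndarray], np.ndarray]


def _is_base_structure(m: np.ndarray) -> bool:
    return (
        m.shape == (3, 3)
        and m[1, 0] == 0.0
        and np.array_equal(m[2], [0.0, 0.0, 1.0])
    )


def _run_constant_base(m: np.ndarray, settings: ModelSettings) -> CohortTrace:
    """Closed-form trace for a constant 3-state matrix: pre-dialysis
    occupancy is geometric and dialysis occupancy is a difference of
    geometric series, so the whole trace vectorizes."""
    a, c = m[0, 0], m[0, 1]
    b = m[1, 1]
    n_max = settings.horizon_max_cycles
    k = np.arange(n_max + 1)
    pre = a ** k.astype(float)
    if abs(a - b) > 1e-12:
        dial = c * (pre - b ** k.astype(float)) / (a - b)
    else:
        dial = c * k * a ** np.maximum(k - 1, 0).astype(float)
        dial[0] = 0.0
    alive = pre + dial
    below = np.nonzero(alive < settings.stop_threshold_alive)[0]
    if below.size:
        n = int(below[0])
        capped = False
    else:
        n = n_max
        capped = True
    pre, dial = pre[: n + 1], dial[: n + 1]
    occupancy = np.column_stack([pre, dial, 1.0 - pre - dial])
    return CohortTrace(
        states=BASE_STATES,
        occupancy=occupancy,
        cycle_months=settings.cycle_length_months,
        new_dialysis_entries=pre[:-1] * c,
        horizon_capped=capped,
    )


def run_cohort(
    matrix: MatrixProvider,
    settings: ModelSettings,
    *,
    states: tuple[str, ...] = BASE_STATES,
    initial: Optional[np.ndarray] = None,
    post_transition: Optional[PostTransition] = None,
) -> CohortTrace:
    """Iterate the cohort until the alive fraction falls below the stopping
    threshold or the horizon cap is reached.

    The whole cohort starts in the (first) pre-dialysis state.  ``matrix``
    is a constant matrix or a per-cycle provider; ``post_transition`` may
    inject scheduled flows (e.g. diet switching) after each cycle's
    transitions and must conserve total occupancy.
    """
    if (
        not callable(matrix)
        and post_transition is None
        and initial is None
        and states == BASE_STATES
        and _is_base_structure(np.asarray(matrix))
    ):
        return _run_constant_base(np.asarray(matrix, dtype=float), settings)
    n = len(states)
    dead_idx = states.index(DEAD)
    dial_idx = states.index(DIAL)
    pre_indices = [i for i, s in enumerate(states) if s in PRE_STATES]
    if initial is None:
        initial = np.zeros(n)
        initial[0] = 1.0
    v = np.asarray(initial, dtype=float).copy()
    rows = [v.copy()]
    entries = []
    capped = True
    for k in range(settings.horizon_max_cycles):
        m = matrix(k) if callable(matrix) else matrix
        new_dial = float(sum(v[i] * m[i, dial_idx] for i in pre_indices))
        v = v @ m
        if post_transition is not None:
            v = post_transition(k, v)
        rows.append(v.copy())
        entries.append(new_dial)
        if 1.0 - v[dead_idx] < settings.stop_threshold_alive:
            capped = False
            break
    return CohortTrace(
        states=states,
        occupancy=np.array(rows),
        cycle_months=settings.cycle_length_months,
        new_dialysis_entries=np.array(entries),
        horizon_capped=capped,
    )


def run_strategy(
    inputs: TransitionInputs,
    strategy: Strategy,
    settings: ModelSettings,
    *,
    p_death_dialysis_annual: Optional[float] = None,
) -> CohortTrace:
    """Convenience wrapper: build the per-cycle matrix for a strategy and run
    the lifetime cohort."""
    m = build_cycle_matrix(
        inputs, strategy, settings, p_death_dialysis_annual=p_death_dialysis_annual
    )
    return run_cohort(m, settings)
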