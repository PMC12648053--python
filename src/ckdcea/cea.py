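"""Incremental cost-effectiveness comparison and net monetary benefit."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .outcomes import OutcomeSummary

#: verdict labels
DOMINANT = "dominant"  # cheaper and more effective
DOMINATED = "dominated"  # costlier and less effective
ICER = "icer"  # trade-off: report the ratio
COST_ONLY = "cost-difference only"  # equal effectiveness, unequal cost
EQUIVALENT = "equivalent"


@dataclass
class CEAResult:
    """Incremental comparison of the supplemented very-low-protein diet
    against the low-protein diet (deltas are intervention minus comparator)."""

    delta_cost: float
    delta_qaly: float
    delta_survival: float
    verdict: str
    icer: Optional[float]
    perspective: str

    def as_dict(self) -> dict:
        out = {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_survival": self.delta_survival,
            "verdict": self.verdict,
            "perspective": self.perspective,
        }
        if self.icer is not None:
            out["icer"] = self.icer
        return out


def compare(a: OutcomeSummary, b: OutcomeSummary) -> CEAResult:
    """Compare strategy ``b`` against comparator ``a`` (b minus a).

    Dominance short-circuits the ICER: a ratio of a saving over a health
    gain (or of extra cost over a health loss) is not interpretable as a
    price per QALY, so only the trade-off quadrants report one.
    """
    if a.perspective != b.perspective:
        raise ValueError(
            f"perspectives differ: {a.perspective!r} vs {b.perspective!r}"
        )
    dc = b.total_cost - a.total_cost
    dq = b.qalys - a.qalys
    ds = b.survival_years - a.survival_years
    icer: Optional[float] = None
    if dc < 0 and dq > 0:
        verdict = DOMINANT
    elif dc > 0 and dq < 0:
        verdict = DOMINATED
    elif dq == 0:
        verdict = COST_ONLY if dc != 0 else EQUIVALENT
    else:
        verdict = ICER
        icer = dc / dq
    return CEAResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_survival=ds,
        verdict=verdict,
        icer=icer,
        perspective=a.perspective,
    )


def net_monetary_benefit(result: CEAResult, wtp: float) -> float:
    """``wtp * delta_qaly - delta_cost``: positive means the intervention is
    cost-effective at willingness-to-pay ``wtp`` (EUR per QALY)."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be >= 0; got {wtp}")
    return wtp * result.delta_qaly - result.delta_cost
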