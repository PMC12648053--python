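"""Static figure writers: cost-effectiveness plane, CEAC, tornado diagram.

Plotting is optional; matplotlib is imported lazily so the analysis modules
work without it.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np

from .sensitivity import CeacCurve, DsaEntry, Ellipse, PsaDrawSet, dsa_frame


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_ce_plane(draws: PsaDrawSet, ellipse: Ellipse, path: str | Path) -> None:
    """Incremental cost vs incremental QALY scatter with the confidence
    ellipse; the lower-right quadrant is dominance of the intervention."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws.delta_qaly, draws.delta_cost, s=6, alpha=0.4,
               color="#1f6fb4", label="PSA draws")
    theta = np.linspace(0, 2 * math.pi, 200)
    local = np.column_stack(
        [ellipse.semi_axes[0] * np.cos(theta), ellipse.semi_axes[1] * np.sin(theta)]
    )
    cos_t, sin_t = math.cos(ellipse.angle_rad), math.sin(ellipse.angle_rad)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    boundary = local @ rot.T + ellipse.center
    ax.plot(boundary[:, 0], boundary[:, 1], color="#b41f2e",
            label=f"{ellipse.coverage:.0%} ellipse")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs (s-VLPD vs LPD)")
    ax.set_ylabel("Incremental cost (EUR)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: CeacCurve, path: str | Path) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.probability, color="#1f6fb4")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Willingness to pay (EUR per QALY)")
    ax.set_ylabel("Probability s-VLPD is cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(entries: Sequence[DsaEntry], outcome: str, path: str | Path,
                 top: int = 12) -> None:
    """Horizontal bars of the incremental-cost (or -QALY) swing per
    parameter, widest first."""
    if outcome not in ("cost", "qaly"):
        raise ValueError(f"outcome must be 'cost' or 'qaly'; got {outcome!r}")
    df = dsa_frame(entries, sort_by=outcome).head(top).iloc[::-1]
    lo = df[f"delta_{outcome}_low"]
    hi = df[f"delta_{outcome}_high"]
    left = np.minimum(lo, hi)
    width = (hi - lo).abs()
    plt = _axes()
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1.2))
    ax.barh(df["parameter"], width, left=left, color="#1f6fb4", alpha=0.8)
    label = "Incremental cost (EUR)" if outcome == "cost" else "Incremental QALYs"
    ax.set_xlabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
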