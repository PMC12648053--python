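"""Report writers: base-case table, trace export, JSON results."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import engine
from .scenarios import ScenarioResult

_COST_ROW_LABELS = {
    "ketoanalogue": "Ketoanalogues",
    "monitoring": "Diet monitoring",
    "dialysis": "Dialysis",
    "other_supplements": "Other supplementation",
    "indirect": "Indirect costs",
}
_COST_ROW_ORDER = ("ketoanalogue", "monitoring", "dialysis", "other_supplements",
                   "indirect")


def results_table(result: ScenarioResult) -> pd.DataFrame:
    """Three-column results table (LPD, s-VLPD, delta) with survival,
    per-state time, QALY and itemized cost rows."""
    lpd, sv = result.lpd, result.svlpd
    rows: list[tuple[str, float, float]] = [
        ("Survival (years)", lpd.survival_years, sv.survival_years),
        ("Time pre-RRT (years)", lpd.time_pre_dialysis_years, sv.time_pre_dialysis_years),
        ("Time in dialysis (years)", lpd.time_dialysis_years, sv.time_dialysis_years),
        ("QALYs", lpd.qalys, sv.qalys),
        (
            f"Total costs ({result.perspective.upper()} perspective, EUR)",
            lpd.total_cost,
            sv.total_cost,
        ),
    ]
    for key in _COST_ROW_ORDER:
        if key in lpd.cost_items:
            rows.append(
                (f"  {_COST_ROW_LABELS[key]} (EUR)", lpd.cost_items[key], sv.cost_items[key])
            )
    df = pd.DataFrame(rows, columns=["outcome", "LPD", "s-VLPD"])
    df["delta"] = df["s-VLPD"] - df["LPD"]
    return df


def write_table(df: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    elif fmt == "json":
        path.write_text(df.to_json(orient="records", indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_scenario_json(result: ScenarioResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.as_dict(), indent=2))


def write_trace(trace: engine.CohortTrace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
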