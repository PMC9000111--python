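"""ICER and dominance arithmetic plus result-table builders.

The cost-effectiveness plane convention: x = incremental QALYs,
y = incremental cost.  Lower-right quadrant (more QALYs, lower cost) is
dominance of the intervention; upper-left is being dominated.  The ICER
delta_cost / delta_qaly is only a meaningful ratio in the two trade-off
quadrants; in tables it is truncated toward zero to whole CHF while JSON
carries full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

LABEL_DOMINANT = "dominant"
LABEL_DOMINATED = "dominated"
LABEL_TRADEOFF_NE = "cost-effective trade-off (NE quadrant)"
LABEL_SAVING_PER_QALY_LOST = "saving per QALY lost (SW quadrant)"
LABEL_INDIFFERENT = "indifferent"


@dataclass(frozen=True)
class IcerVerdict:
    delta_cost: float
    delta_qaly: float
    icer: float | None  # CHF per QALY, full precision; None when suppressed
    icer_display: int | None  # truncated toward zero for tables
    label: str

    def to_dict(self) -> dict:
        return asdict(self)


def compute_icer(delta_cost: float, delta_qaly: float, qaly_epsilon: float = 1e-6) -> IcerVerdict:
    """Classify an (incremental cost, incremental QALY) pair.

    dominant    <=> cheaper and more effective (cost < 0, QALY > 0)
    dominated   <=> costlier and less effective (cost > 0, QALY < 0)
    NE quadrant <=> costlier and more effective: CHF per QALY gained
    SW quadrant <=> cheaper and less effective: CHF saving per QALY lost
    |delta_qaly| below ``qaly_epsilon`` suppresses the ratio (label only).
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("incremental cost and QALY must be finite")
    if delta_cost == 0 and delta_qaly == 0:
        return IcerVerdict(delta_cost, delta_qaly, None, None, LABEL_INDIFFERENT)

    if delta_qaly > 0 and delta_cost < 0:
        return IcerVerdict(delta_cost, delta_qaly, None, None, LABEL_DOMINANT)
    if delta_qaly < 0 and delta_cost > 0:
        return IcerVerdict(delta_cost, delta_qaly, None, None, LABEL_DOMINATED)
    # boundary cases: one delta exactly zero -> weak dominance, no ratio
    if delta_qaly == 0 or abs(delta_qaly) < qaly_epsilon:
        label = LABEL_DOMINANT if delta_cost < 0 else LABEL_DOMINATED
        return IcerVerdict(delta_cost, delta_qaly, None, None, label)
    if delta_cost == 0:
        label = LABEL_DOMINANT if delta_qaly > 0 else LABEL_DOMINATED
        return IcerVerdict(delta_cost, delta_qaly, None, None, label)

    ratio = delta_cost / delta_qaly
    label = LABEL_TRADEOFF_NE if delta_qaly > 0 else LABEL_SAVING_PER_QALY_LOST
    return IcerVerdict(delta_cost, delta_qaly, ratio, math.trunc(ratio), label)


def descriptive_table(values: pd.DataFrame, value_col: str,
                      by: list[str] | None = None) -> pd.DataFrame:
    """Mean/SD/min/max/median summary by grouping columns (arm, country...)."""
    if values.empty:
        raise ValueError("empty input")
    by = by or []
    def summarize(s: pd.Series) -> pd.Series:
        s = s.dropna()
        return pd.Series({"N": len(s), "mean": s.mean(), "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
                          "min": s.min(), "max": s.max(), "median": s.median()})
    if by:
        return values.groupby(by, observed=True)[value_col].apply(summarize).unstack().reset_index()
    return summarize(values[value_col]).to_frame().T


def coefficient_table(fit_summary: pd.DataFrame) -> pd.DataFrame:
    """Round a coefficient frame for display: costs to whole CHF, QALYs to 3 dp.

    Expects columns equation (cost/qaly), term, estimate, ci_low, ci_high.
    Full precision is preserved in the input; only this view rounds.
    """
    out = fit_summary.copy()
    is_cost = out["equation"] == "cost"
    for col in ("estimate", "ci_low", "ci_high"):
        out.loc[is_cost, col] = out.loc[is_cost, col].round(0)
        out.loc[~is_cost, col] = out.loc[~is_cost, col].round(3)
    return out


def subgroup_table(results: list[dict]) -> pd.DataFrame:
    """Subgroup/country summary in the layout: name, deltas, CIs, ICER/label."""
    if not results:
        raise ValueError("empty input")
    rows = []
    for r in results:
        verdict = compute_icer(r["delta_cost"], r["delta_qaly"]) if np.isfinite(r["delta_cost"]) else None
        rows.append({
            "name": r["name"],
            "delta_cost": round(r["delta_cost"]) if np.isfinite(r["delta_cost"]) else np.nan,
            "cost_ci_low": round(r.get("cost_ci_low", np.nan)) if np.isfinite(r.get("cost_ci_low", np.nan)) else np.nan,
            "cost_ci_high": round(r.get("cost_ci_high", np.nan)) if np.isfinite(r.get("cost_ci_high", np.nan)) else np.nan,
            "delta_qaly": round(r["delta_qaly"], 3) if np.isfinite(r["delta_qaly"]) else np.nan,
            "qaly_ci_low": round(r.get("qaly_ci_low", np.nan), 3),
            "qaly_ci_high": round(r.get("qaly_ci_high", np.nan), 3),
            "icer": verdict.icer_display if verdict and verdict.icer_display is not None else "",
            "label": verdict.label if verdict else r.get("label", "not fitted"),
        })
    return pd.DataFrame(rows)
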