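"""EQ-5D-5L valuation and QALY computation.

Scores five-dimension, five-level health profiles against a value set
(a mapping from the 3,125 health states to utilities) and turns a
patient's utility trajectory into quality-adjusted life years over a
one-year horizon by the trapezium rule, with utility fixed at zero from
the date of death.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIMENSIONS = ("mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression")

#: Scheduled assessment days: 6-month pre-baseline recall point, baseline,
#: and telephone follow-ups at 2, 6 and 12 months.
SCHEDULED_DAYS = (-183, 0, 61, 183, 365)

#: Days per year used to convert an area in utility-days into utility-years.
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ValueSet:
    """Mapping from 5-digit EQ-5D-5L profiles to utilities.

    ``mapping`` keys are profile strings such as ``"21345"``; full health
    ``"11111"`` must map to 1.0.  ``floor`` is the worst utility in the set
    and may be negative (many national value sets dip below zero).
    """

    label: str
    mapping: dict[str, float] = field(repr=False)
    floor: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.mapping.get("11111", np.nan) - 1.0) > 1e-12:
            raise ValueError(f"value set {self.label!r}: profile 11111 must map to 1.0")

    def utility(self, profile: str) -> float:
        try:
            return self.mapping[profile]
        except KeyError:
            raise KeyError(f"profile {profile!r} not covered by value set {self.label!r}") from None


def toy_value_set(label: str = "toy-test", decrement: float = 0.05) -> ValueSet:
    """Deterministic additive value set for tests: 1 - decrement * sum(level-1).

    Covers all 3,125 profiles; with the default decrement the floor (profile
    55555) is exactly 0.0.
    """
    mapping: dict[str, float] = {}
    for state in np.ndindex(5, 5, 5, 5, 5):
        levels = [s + 1 for s in state]
        profile = "".join(str(l) for l in levels)
        mapping[profile] = 1.0 - decrement * sum(l - 1 for l in levels)
    floor = min(mapping.values())
    return ValueSet(label=label, mapping=mapping, floor=floor)


def shifted_toy_value_set(label: str, shift: float) -> ValueSet:
    """Toy value set with every non-full-health state shifted by ``shift``.

    Stands in for distinct national crosswalk tariffs in country-level
    analyses when the licensed tables are not available; synthetic.
    """
    base = toy_value_set(label=label)
    mapping = {p: (1.0 if p == "11111" else u + shift) for p, u in base.mapping.items()}
    return ValueSet(label=label, mapping=mapping, floor=min(mapping.values()))


def load_value_set(path, label: str | None = None) -> ValueSet:
    """Load a value set from a CSV with columns ``state`` and ``utility``."""
    df = pd.read_csv(path, dtype={"state": str})
    mapping = dict(zip(df["state"], df["utility"].astype(float)))
    return ValueSet(label=label or str(path), mapping=mapping, floor=float(df["utility"].min()))


def score_eq5d(levels, value_set: ValueSet) -> float:
    """Score one observation's five dimension levels against a value set.

    ``levels`` is a sequence of five integers in 1..5 (the order of
    :data:`DIMENSIONS`).  Any missing (NaN/None) dimension makes the whole
    score missing — the score is left for multiple imputation, never
    partially valued.
    """
    vals = list(levels)
    if len(vals) != 5:
        raise ValueError("expected exactly five dimension levels")
    if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
        return float("nan")
    ivals = [int(v) for v in vals]
    if any(not 1 <= v <= 5 for v in ivals):
        raise ValueError(f"dimension levels must be in 1..5, got {ivals}")
    return value_set.utility("".join(str(v) for v in ivals))


def score_utility_table(utilities: pd.DataFrame, value_set: ValueSet) -> pd.DataFrame:
    """Score a long-format utility table, adding a ``utility`` column.

    Rows must carry the five dimension columns; rows with any missing
    dimension get a missing utility.  A pre-existing ``utility`` column is
    overwritten (re-scoring with a different value set).
    """
    out = utilities.copy()
    lv = out[list(DIMENSIONS)].to_numpy(dtype=float)
    complete = ~np.isnan(lv).any(axis=1)
    util = np.full(len(out), np.nan)
    if complete.any():
        ints = lv[complete].astype(int)
        if ints.min() < 1 or ints.max() > 5:
            raise ValueError("dimension levels outside 1..5")
        profiles = ["".join(map(str, row)) for row in ints]
        util[complete] = [value_set.utility(p) for p in profiles]
    out["utility"] = util
    return out


@dataclass(frozen=True)
class QalyResult:
    patient_id: object
    qaly: float  # NaN when no usable post-baseline observation
    utility_baseline: float
    utility_minus6m: float
    n_observations_used: int


def compute_qaly(
    days,
    utilities,
    death_day: float | None = None,
    horizon_days: float = 365.0,
    followup_days: float | None = None,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """QALYs for one patient by trapezium-rule area under the utility curve.

    ``days``/``utilities`` are the scored observations sorted by day;
    missing utilities are skipped (they are imputed upstream, not bridged
    here).  The curve is piecewise linear between observed points from day 0
    to the horizon.  From ``death_day`` onward utility is fixed at 0, with a
    linear segment from the last pre-death observation down to 0 at the
    death day.  For patients alive but followed up for less than the
    horizon, the area runs to min(followup, horizon); either way the area in
    utility-days is divided by ``days_per_year``.

    Returns NaN when no non-missing observation at day >= 0 exists.
    """
    days = np.asarray(days, dtype=float)
    utilities = np.asarray(utilities, dtype=float)
    keep = (days >= 0) & ~np.isnan(utilities)
    if death_day is not None:
        keep &= days < death_day
    d, u = days[keep], utilities[keep]

    if death_day is not None and death_day <= 0:
        return 0.0
    if d.size == 0:
        if death_day is not None:
            # died before contributing any usable observation: no anchor to
            # interpolate from, QALY is the death-truncated zero curve only
            # if death is at day 0; otherwise the pre-death segment is
            # unobserved and the QALY is missing.
            return float("nan")
        return float("nan")

    end = float(horizon_days)
    if followup_days is not None:
        end = min(end, float(followup_days))
    if death_day is not None:
        end = float(horizon_days)  # zeros run to the horizon after death

    # build node list: observed points, death drop, horizon extension
    xs = list(d)
    ys = list(u)
    if xs[0] > 0:
        xs.insert(0, 0.0)
        ys.insert(0, u[0])  # carry first observation back to day 0
    if death_day is not None:
        dd = min(float(death_day), end)
        xs.append(dd)
        ys.append(0.0)
        if dd < end:
            xs.append(end)
            ys.append(0.0)
    elif xs[-1] < end:
        xs.append(end)
        ys.append(ys[-1])  # carry last observation forward
    xs_arr = np.asarray(xs)
    ys_arr = np.asarray(ys)
    inside = xs_arr <= end + 1e-12
    xs_arr, ys_arr = xs_arr[inside], ys_arr[inside]
    if xs_arr[-1] < end and death_day is None:
        pass  # truncated at followup end
    area = float(np.trapezoid(ys_arr, xs_arr))
    return area / days_per_year


def qaly_table(
    utilities: pd.DataFrame,
    patients: pd.DataFrame,
    horizon_days: float = 365.0,
    days_per_year: float = DAYS_PER_YEAR,
) -> pd.DataFrame:
    """Per-patient QALYs plus the baseline and pre-baseline utility covariates.

    ``utilities`` must be scored (have a ``utility`` column); ``patients``
    provides ``death_day`` and ``followup_days``.  The pre-baseline (-6
    month) observation is reported only as a covariate, never integrated.
    """
    pats = patients.set_index("patient_id")
    rows = []
    for pid, grp in utilities.sort_values("timepoint_day").groupby("patient_id"):
        death = pats.at[pid, "death_day"] if pid in pats.index else np.nan
        death = None if pd.isna(death) else float(death)
        fup = pats.at[pid, "followup_days"] if pid in pats.index else horizon_days
        pre = grp[grp["timepoint_day"] < 0]
        post = grp[grp["timepoint_day"] >= 0]
        base = post[post["timepoint_day"] == 0]
        q = compute_qaly(
            post["timepoint_day"].to_numpy(),
            post["utility"].to_numpy(),
            death_day=death,
            horizon_days=horizon_days,
            followup_days=float(fup),
            days_per_year=days_per_year,
        )
        rows.append(
            QalyResult(
                patient_id=pid,
                qaly=q,
                utility_baseline=float(base["utility"].iloc[0]) if len(base) else float("nan"),
                utility_minus6m=float(pre["utility"].iloc[0]) if len(pre) else float("nan"),
                n_observations_used=int(post["utility"].notna().sum()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
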