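"""Resource-use pricing: local unit costs, PPP conversion, perspectives.

Turns long-format resource-use events into per-category and total
per-patient costs in PPP-adjusted Swiss francs (CHF).  The healthcare
perspective sums six medical categories plus the intervention-delivery
cost (intervention arm only); the societal perspective adds informal care
valued at the country's average hourly wage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HEALTHCARE_CATEGORIES = (
    "hospitalization",
    "rehabilitation",
    "medical_visit",
    "nursing_visit_home",
    "nursing_home",
    "drug",
)
ALL_CATEGORIES = HEALTHCARE_CATEGORIES + ("informal_care", "intervention_delivery")

COUNTRIES = ("CH", "IE", "BE", "NL")


@dataclass(frozen=True)
class UnitCostTable:
    """(country, category[, item_code]) -> unit cost in 2018 local currency."""

    table: pd.DataFrame  # columns: country, category, item_code, unit_cost, currency

    def lookup(self, country: str, category: str, item_code: str = "") -> float:
        t = self.table
        hit = t[(t["country"] == country) & (t["category"] == category) & (t["item_code"].fillna("") == item_code)]
        if hit.empty:
            raise KeyError(f"no unit cost for ({country}, {category}, {item_code!r})")
        return float(hit["unit_cost"].iloc[0])


@dataclass(frozen=True)
class PPPIndex:
    """Country -> multiplicative factor converting local currency to CHF."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        for c, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"PPP factor for {c} must be strictly positive")
        if abs(self.factors.get("CH", 1.0) - 1.0) > 1e-12:
            raise ValueError("CH factor must be 1 (costs are expressed in CHF)")

    def factor(self, country: str) -> float:
        try:
            return self.factors[country]
        except KeyError:
            raise KeyError(f"no PPP factor for country {country!r}") from None


def example_unit_costs() -> UnitCostTable:
    """A self-consistent fictitious 2018-style unit-cost pack (synthetic).

    Ships for tests and the synthetic pipeline; real analyses load national
    tariffs from CSV instead.  Units: hospitalization/rehabilitation/
    nursing-home days, visits, drug packs, informal-care hours.
    """
    base = {
        "hospitalization": 1800.0,
        "rehabilitation": 700.0,
        "medical_visit": 120.0,
        "nursing_visit_home": 95.0,
        "nursing_home": 280.0,
        "drug": 38.0,
        "informal_care": 32.0,
    }
    # local price levels relative to CH, roughly offset by the PPP factors
    level = {"CH": 1.0, "IE": 0.82, "BE": 0.68, "NL": 0.74}
    rows = [
        {"country": c, "category": cat, "item_code": "", "unit_cost": round(u * level[c], 2),
         "currency": "CHF" if c == "CH" else "EUR"}
        for c in COUNTRIES
        for cat, u in base.items()
    ]
    for c in COUNTRIES:
        rows.append({"country": c, "category": "intervention_delivery", "item_code": "physician_minutes",
                     "unit_cost": round(2.0 * level[c], 3), "currency": "CHF" if c == "CH" else "EUR"})
        rows.append({"country": c, "category": "intervention_delivery", "item_code": "pharmacist_minutes",
                     "unit_cost": round(80.0 / 60.0 * level[c], 3), "currency": "CHF" if c == "CH" else "EUR"})
    return UnitCostTable(pd.DataFrame(rows))


def example_ppp() -> PPPIndex:
    """Fictitious PPP factors anchored at CH = 1 (synthetic)."""
    return PPPIndex({"CH": 1.0, "IE": 1.18, "BE": 1.42, "NL": 1.31})


def load_unit_costs(path) -> UnitCostTable:
    df = pd.read_csv(path, dtype={"item_code": str})
    df["item_code"] = df["item_code"].fillna("")
    return UnitCostTable(df)


def load_ppp(path) -> PPPIndex:
    df = pd.read_csv(path)
    return PPPIndex(dict(zip(df["country"], df["factor"].astype(float))))


def price_resource_use(
    events: pd.DataFrame,
    unit_costs: UnitCostTable,
    patients: pd.DataFrame,
) -> pd.DataFrame:
    """Per-patient, per-category costs in *local currency*.

    ``events`` columns: patient_id, category, item_code (optional), quantity,
    event_day.  Each event contributes quantity x unit cost; an event with a
    missing quantity marks its whole (patient, category) cell missing for
    multiple imputation.  Events after a patient's follow-up end are
    excluded (within-trial horizon).  Raises on any unpriced
    (country, category) pair, listing the offenders.
    """
    ev = events.copy()
    if "item_code" not in ev.columns:
        ev["item_code"] = ""
    ev["item_code"] = ev["item_code"].fillna("")
    country = patients.set_index("patient_id")["country"]
    fup = patients.set_index("patient_id")["followup_days"]
    ev["country"] = ev["patient_id"].map(country)
    ev = ev[ev["event_day"].fillna(0) <= ev["patient_id"].map(fup).fillna(np.inf)]

    bad = set()
    cost_tab = unit_costs.table.copy()
    cost_tab["item_code"] = cost_tab["item_code"].fillna("")
    merged = ev.merge(cost_tab[["country", "category", "item_code", "unit_cost"]],
                      on=["country", "category", "item_code"], how="left")
    missing_price = merged["unit_cost"].isna()
    if missing_price.any():
        bad = set(map(tuple, merged.loc[missing_price, ["country", "category", "item_code"]].itertuples(index=False)))
        raise KeyError(f"unpriced (country, category, item) pairs: {sorted(bad)}")
    if (merged["quantity"].dropna() < 0).any():
        raise ValueError("negative resource-use quantities")

    merged["cost"] = merged["quantity"] * merged["unit_cost"]
    wide = merged.pivot_table(index="patient_id", columns="category", values="cost",
                              aggfunc="sum", dropna=False)
    # a NaN quantity anywhere in a cell poisons that cell (treated-as-missing rule)
    out = pd.DataFrame(index=patients["patient_id"], columns=list(ALL_CATEGORIES), dtype=float).fillna(0.0)
    for cat in wide.columns:
        out.loc[wide.index, cat] = wide[cat]
        out[cat] = out[cat].astype(float)
    out = out.fillna(0.0)
    poisoned = merged[merged["quantity"].isna()]
    for pid, cat in poisoned[["patient_id", "category"]].itertuples(index=False):
        out.at[pid, cat] = np.nan
    return out.reset_index()


def convert_ppp(costs: pd.DataFrame, patients: pd.DataFrame, ppp: PPPIndex) -> pd.DataFrame:
    """Multiply every cost column by the patient's country PPP factor."""
    out = costs.copy()
    country = patients.set_index("patient_id")["country"]
    factors = costs["patient_id"].map(country).map(lambda c: ppp.factor(c)).to_numpy()
    for cat in out.columns:
        if cat != "patient_id":
            out[cat] = out[cat].to_numpy() * factors
    return out


def intervention_cost(staff_minutes: dict[str, float], hourly_wages: dict[str, float],
                      software_cost_per_patient: float) -> float:
    """Delivery cost for one intervention-arm patient, in CHF."""
    if software_cost_per_patient < 0 or any(v < 0 for v in staff_minutes.values()):
        raise ValueError("negative intervention-cost inputs")
    total = software_cost_per_patient
    for role, minutes in staff_minutes.items():
        total += minutes * hourly_wages[role] / 60.0
    return total


def informal_care_cost(hours: float, hourly_wage: float) -> float:
    """Informal (family caregiver) care valued at the average hourly wage."""
    if hours < 0 or hourly_wage < 0:
        raise ValueError("negative informal-care inputs")
    return hours * hourly_wage


def total_costs(costs_chf: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Attach healthcare and societal totals (and missing flags) to CHF costs.

    total_healthcare = six medical categories + intervention delivery
    (the delivery column is forced to 0 for control patients);
    total_societal = total_healthcare + informal care.  A missing category
    makes the totals missing, to be completed after imputation.
    """
    out = costs_chf.copy()
    arm = patients.set_index("patient_id")["arm"]
    is_control = out["patient_id"].map(arm).eq("control").to_numpy()
    out.loc[is_control, "intervention_delivery"] = 0.0
    hc_cols = list(HEALTHCARE_CATEGORIES) + ["intervention_delivery"]
    out["total_healthcare"] = out[hc_cols].sum(axis=1, skipna=False)
    out["total_societal"] = out["total_healthcare"] + out["informal_care"]
    return out
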