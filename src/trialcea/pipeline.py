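"""End-to-end orchestration: raw trial tables -> pooled CEA results.

The chain is: score EQ-5D-5L responses against a value set, price and
PPP-convert resource use, assemble the per-patient wide table (utility
score per scheduled assessment, CHF cost per category), multiply-impute
its missing cells with the multilevel joint model, then compute QALYs and
cost totals on each completed dataset and fit the chosen model variant,
pooling by Rubin's rules.
"""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from . import costing, eq5d, impute, models
from .costing import HEALTHCARE_CATEGORIES, PPPIndex, UnitCostTable
from .eq5d import SCHEDULED_DAYS, ValueSet
from .synthetic import TrialData

logger = logging.getLogger(__name__)

UTILITY_COLS = {d: f"util_{'m' if d < 0 else ''}{abs(d)}" for d in SCHEDULED_DAYS}
COST_COLS = {c: f"cost_{c}" for c in costing.ALL_CATEGORIES}
MI_COST_TARGETS = tuple(f"cost_{c}" for c in HEALTHCARE_CATEGORIES)

#: Fully observed covariates driving the imputation model.
MI_PREDICTORS = (
    "age", "female", "edu_high_school", "edu_university", "smoker",
    "alcohol_units_week", "n_drugs_baseline", "n_comorbidities_baseline",
    "n_hosp_prior_year", "housebound", "nursing_home_baseline", "dementia",
    "index_duration", "medical_ward", "country_IE", "country_BE", "country_NL",
    "observation_time", "died",
)


def build_wide_table(data: TrialData, value_set: ValueSet,
                     unit_costs: UnitCostTable, ppp: PPPIndex,
                     software_cost_per_patient: float = 10.0,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient wide table of utility scores and CHF category costs.

    Returns ``(wide, structural_zeros)``; the latter flags utility cells at
    assessments scheduled on or after the patient's death (zero by the
    death rule, excluded from imputation).
    """
    patients = models.add_design_columns(data.patients)

    scored = eq5d.score_utility_table(data.utilities, value_set)
    util = scored.pivot_table(index="patient_id", columns="timepoint_day",
                              values="utility", dropna=False)
    wide = patients.set_index("patient_id").copy()
    for day, col in UTILITY_COLS.items():
        wide[col] = util[day] if day in util.columns else np.nan

    local = costing.price_resource_use(data.resource_use, unit_costs, data.patients)
    chf = costing.convert_ppp(local, data.patients, ppp)
    chf = chf.set_index("patient_id")
    is_interv = wide["arm"] == "intervention"
    chf.loc[is_interv[chf.index], "intervention_delivery"] += software_cost_per_patient
    for cat, col in COST_COLS.items():
        wide[col] = chf[cat]
    wide.loc[~is_interv, COST_COLS["intervention_delivery"]] = 0.0

    struct = pd.DataFrame(False, index=wide.index, columns=list(UTILITY_COLS.values()))
    death = wide["death_day"]
    for day, col in UTILITY_COLS.items():
        struct[col] = death.notna() & (death <= day)
        wide.loc[struct[col], col] = 0.0
    wide = wide.reset_index()
    struct.index = wide.index
    return wide, struct


def default_imputation_spec(value_set: ValueSet, m: int = 5, n_iterations: int = 100,
                            seed: int = 0, random_structure: str = "intercepts_only",
                            ) -> impute.ImputationSpec:
    targets = tuple(UTILITY_COLS.values()) + MI_COST_TARGETS
    clip = {c: (value_set.floor, 1.0) for c in UTILITY_COLS.values()}
    return impute.ImputationSpec(
        targets=targets, predictors=MI_PREDICTORS, log_targets=MI_COST_TARGETS,
        clip=clip, m=m, n_iterations=n_iterations, seed=seed,
        random_structure=random_structure,
        slope_covariate="observation_time" if random_structure == "intercepts_and_slopes" else None,
    )


def recompute_totals(df: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive healthcare and societal totals from the category columns."""
    out = df.copy()
    hc = [COST_COLS[c] for c in HEALTHCARE_CATEGORIES] + [COST_COLS["intervention_delivery"]]
    out["total_healthcare"] = out[hc].sum(axis=1, skipna=False)
    out["total_societal"] = out["total_healthcare"] + out[COST_COLS["informal_care"]]
    return out


def completed_to_analysis(completed: pd.DataFrame, horizon_days: float = 365.0) -> pd.DataFrame:
    """QALYs and cost totals for one completed (post-imputation) wide table."""
    out = completed.copy()
    post_days = [d for d in SCHEDULED_DAYS if d >= 0]
    cols = [UTILITY_COLS[d] for d in post_days]
    u = out[cols].to_numpy(dtype=float)
    death = out["death_day"].to_numpy(dtype=float)
    qalys = np.empty(len(out))
    for i in range(len(out)):
        dd = None if np.isnan(death[i]) else float(death[i])
        qalys[i] = eq5d.compute_qaly(post_days, u[i], death_day=dd, horizon_days=horizon_days)
    out["qaly"] = qalys
    out["utility_baseline"] = out[UTILITY_COLS[0]]
    out["utility_minus6m"] = out[UTILITY_COLS[-183]]
    return recompute_totals(out)


def impute_and_analyze(wide: pd.DataFrame, struct: pd.DataFrame,
                       spec: impute.ImputationSpec) -> list[pd.DataFrame]:
    """Multiply-impute the wide table and derive the analysis datasets."""
    t0 = time.perf_counter()
    completed = impute.fit_and_impute(wide, spec, structural_zeros=struct)
    logger.info("imputation (m=%d) took %.1fs", spec.m, time.perf_counter() - t0)
    return [completed_to_analysis(c) for c in completed]


def complete_case_analysis(wide: pd.DataFrame) -> pd.DataFrame:
    """Observed-data analysis table: only patients with all elements present."""
    df = completed_to_analysis(wide)
    return df[df["qaly"].notna() & df["total_healthcare"].notna()].copy()


def run_full_cea(data: TrialData, value_set: ValueSet | None = None,
                 unit_costs: UnitCostTable | None = None, ppp: PPPIndex | None = None,
                 m: int = 5, n_iterations: int = 100, variant: str = "joint",
                 perspective: str = "healthcare", seed: int = 0,
                 software_cost_per_patient: float = 10.0,
                 model_spec: models.CovariateSpec | None = None) -> dict:
    """Raw (possibly incomplete) trial tables -> pooled CEA result."""
    value_set = value_set or eq5d.toy_value_set()
    unit_costs = unit_costs or costing.example_unit_costs()
    ppp = ppp or costing.example_ppp()
    wide, struct = build_wide_table(data, value_set, unit_costs, ppp, software_cost_per_patient)
    spec = default_imputation_spec(value_set, m=m, n_iterations=n_iterations, seed=seed)
    datasets = impute_and_analyze(wide, struct, spec)
    result = models.run_cea(datasets, variant=variant, spec=model_spec, perspective=perspective)
    return {"result": result, "datasets": datasets, "wide": wide, "structural_zeros": struct}
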