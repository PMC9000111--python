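"""Country-level analyses, interaction tests and protocol subgroups.

Country-specific CEAs re-run the whole chain on one country's patients
with the locally relevant value set and unit costs, and without country
dummies.  Heterogeneity of the per-country incremental estimates is
tested two ways: a qualitative (sign-crossing) interaction test with a
chi-bar-squared null, and a quantitative homogeneity (Cochran Q) test
against chi-squared with countries - 1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from . import models, pipeline
from .costing import PPPIndex, UnitCostTable
from .eq5d import ValueSet
from .synthetic import TrialData

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityResult:
    test: str  # qualitative | quantitative
    statistic: float
    p_value: float
    effects: tuple[float, ...]
    ses: tuple[float, ...]
    detail: dict = field(default_factory=dict)


def gail_simon_qualitative_test(effects, ses) -> HeterogeneityResult:
    """Qualitative (crossover) interaction test.

    Q+ sums (effect/se)^2 over positive effects, Q- over negative ones; the
    statistic min(Q+, Q-) is referred to the chi-bar-squared mixture
    sum_h C(g-1, h) (1/2)^(g-1) P(chi2_h > q).  All effects sharing a sign
    gives statistic 0 and p = 1 (no qualitative interaction is possible).
    """
    effects = np.asarray(effects, dtype=float)
    ses = np.asarray(ses, dtype=float)
    g = effects.size
    if g < 2 or not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("need >= 2 groups with finite positive SEs")
    z2 = (effects / ses) ** 2
    q_plus = float(z2[effects > 0].sum())
    q_minus = float(z2[effects < 0].sum())
    q = min(q_plus, q_minus)
    if q == 0.0:
        p = 1.0
    else:
        p = sum(comb(g - 1, h) * 0.5 ** (g - 1) * stats.chi2.sf(q, h) for h in range(1, g))
        p = float(min(p, 1.0))
    return HeterogeneityResult("qualitative", q, p, tuple(effects), tuple(ses),
                               {"q_plus": q_plus, "q_minus": q_minus})


def quantitative_interaction_test(effects, ses) -> HeterogeneityResult:
    """Cochran Q homogeneity test of the group effects (chi2, df = g - 1)."""
    effects = np.asarray(effects, dtype=float)
    ses = np.asarray(ses, dtype=float)
    g = effects.size
    if g < 2 or not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("need >= 2 groups with finite positive SEs")
    w = 1.0 / ses ** 2
    mean = float((w * effects).sum() / w.sum())
    q = float((w * (effects - mean) ** 2).sum())
    p = float(stats.chi2.sf(q, g - 1))
    return HeterogeneityResult("quantitative", q, p, tuple(effects), tuple(ses),
                               {"pooled_effect": mean, "df": g - 1})


def country_cea(data: TrialData, country: str, value_set: ValueSet,
                unit_costs: UnitCostTable, ppp: PPPIndex, m: int = 5,
                n_iterations: int = 100, variant: str = "joint",
                perspective: str = "healthcare", seed: int = 0) -> models.CEAResult:
    """Full-chain CEA restricted to one country with its local value set.

    The country's patients are re-scored with the local valuation
    algorithm, re-imputed within the subset (by arm), and fitted with the
    main covariate specification minus the country dummies.
    """
    keep = data.patients["country"] == country
    if not keep.any():
        raise ValueError(f"no patients from country {country!r}")
    pids = set(data.patients.loc[keep, "patient_id"])
    sub = TrialData(
        patients=data.patients[keep].reset_index(drop=True),
        utilities=data.utilities[data.utilities["patient_id"].isin(pids)].reset_index(drop=True),
        resource_use=data.resource_use[data.resource_use["patient_id"].isin(pids)].reset_index(drop=True),
        truth=data.truth,
    )
    spec = models.CovariateSpec().drop(["country_IE", "country_BE", "country_NL"])
    out = pipeline.run_full_cea(sub, value_set=value_set, unit_costs=unit_costs, ppp=ppp,
                                m=m, n_iterations=n_iterations, variant=variant,
                                perspective=perspective, seed=seed, model_spec=spec)
    return out["result"]


@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    column: str  # patient column the filter applies to
    predicate: object  # callable Series -> boolean mask
    drop_covariates: tuple[str, ...] = ()  # axis covariate(s) removed from the fit


def protocol_subgroups() -> list[SubgroupSpec]:
    """The protocol-defined subgroup axes (each axis partitions the sample)."""
    return [
        SubgroupSpec("Only female", "female", lambda s: s == 1, ("female",)),
        SubgroupSpec("Only male", "female", lambda s: s == 0, ("female",)),
        SubgroupSpec("Community-dwelling", "nursing_home_baseline", lambda s: s == 0,
                     ("nursing_home_baseline",)),
        SubgroupSpec("Nursing homes", "nursing_home_baseline", lambda s: s == 1,
                     ("nursing_home_baseline",)),
        SubgroupSpec("Medical ward", "medical_ward", lambda s: s == 1, ("medical_ward",)),
        SubgroupSpec("Surgical ward", "medical_ward", lambda s: s == 0, ("medical_ward",)),
        SubgroupSpec("Age 70-79", "age", lambda s: s < 80, ()),
        SubgroupSpec("Age 80-89", "age", lambda s: (s >= 80) & (s < 90), ()),
        SubgroupSpec("Age 90+", "age", lambda s: s >= 90, ()),
        SubgroupSpec("N. drugs: 5-9", "n_drugs_baseline", lambda s: s <= 9, ()),
        SubgroupSpec("N. drugs: >= 10", "n_drugs_baseline", lambda s: s >= 10, ()),
        SubgroupSpec("N. comorbidities: 3-6", "n_comorbidities_baseline", lambda s: s <= 6, ()),
        SubgroupSpec("N. comorbidities: >= 7", "n_comorbidities_baseline", lambda s: s >= 7, ()),
    ]


def subgroup_cea(datasets: list[pd.DataFrame], subgroups: list[SubgroupSpec] | None = None,
                 variant: str = "joint", perspective: str = "healthcare",
                 spec: models.CovariateSpec | None = None) -> pd.DataFrame:
    """Re-run the pooled CEA within each subgroup of the imputed datasets.

    The axis-defining covariate is dropped from its own subgroup fit (it is
    constant there).  Subgroups retaining fewer than 2 clusters per arm are
    flagged and not fitted.
    """
    subgroups = subgroups if subgroups is not None else protocol_subgroups()
    base_spec = spec or models.CovariateSpec()
    rows = []
    for sg in subgroups:
        subsets = [d[sg.predicate(d[sg.column])] for d in datasets]
        n = len(subsets[0])
        enough = n > 0 and all(
            s.groupby("arm")["cluster_id"].nunique().reindex(
                ["control", "intervention"]).fillna(0).min() >= 2
            for s in subsets)
        if not enough:
            rows.append({"name": sg.name, "n": n, "delta_cost": np.nan, "delta_qaly": np.nan,
                         "label": "not fitted (<2 clusters per arm)"})
            logger.warning("subgroup %s flagged: fewer than 2 clusters per arm", sg.name)
            continue
        sub_spec = base_spec.drop(sg.drop_covariates) if sg.drop_covariates else base_spec
        try:
            res = models.run_cea(subsets, variant=variant, spec=sub_spec, perspective=perspective)
        except np.linalg.LinAlgError:
            rows.append({"name": sg.name, "n": n, "delta_cost": np.nan, "delta_qaly": np.nan,
                         "label": "not fitted (singular design)"})
            logger.warning("subgroup %s flagged: singular design", sg.name)
            continue
        rows.append({"name": sg.name, "n": n,
                     "delta_cost": res.delta_cost.estimate,
                     "cost_ci_low": res.delta_cost.ci_low, "cost_ci_high": res.delta_cost.ci_high,
                     "delta_qaly": res.delta_qaly.estimate,
                     "qaly_ci_low": res.delta_qaly.ci_low, "qaly_ci_high": res.delta_qaly.ci_high,
                     "icer": res.verdict.icer_display, "label": res.verdict.label})
    return pd.DataFrame(rows)
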