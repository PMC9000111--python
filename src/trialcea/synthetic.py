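"""Synthetic trial generator.

Emulates a four-country European cluster-randomized trial in multimorbid
older adults (>=70 years, >=3 chronic conditions, >=5 regular drugs):
~2,000 patients in ~110 clusters (54 intervention / 56 control), EQ-5D-5L
assessments at -6 months, baseline and 2/6/12 months, six medical resource
categories plus informal care and intervention delivery, ~19% one-year
mortality, strongly right-skewed annual costs (trial-wide mean ~44,000,
median ~24,000 CHF), and configurable true incremental effects so that
parameter recovery can be verified.

Missingness is applied in a separate pass (MCAR, MAR as a logistic
function of observed covariates, or MNAR additionally shifted by the
to-be-deleted value), so complete "truth" tables remain available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .costing import (
    HEALTHCARE_CATEGORIES,
    PPPIndex,
    UnitCostTable,
    example_ppp,
    example_unit_costs,
)
from .eq5d import SCHEDULED_DAYS

#: Trial-calibrated country shares (CH, IE, BE, NL).
DEFAULT_COUNTRY_WEIGHTS = {"CH": 822 / 2008, "IE": 346 / 2008, "BE": 388 / 2008, "NL": 452 / 2008}

#: Mean annual cost share per medical category (sums to 1) and the
#: probability that a patient uses the category at all.
CATEGORY_SHARES = {
    "hospitalization": 0.55,
    "rehabilitation": 0.08,
    "medical_visit": 0.06,
    "nursing_visit_home": 0.07,
    "nursing_home": 0.14,
    "drug": 0.10,
}
CATEGORY_OCCURRENCE = {
    "hospitalization": 0.85,
    "rehabilitation": 0.25,
    "medical_visit": 0.95,
    "nursing_visit_home": 0.45,
    "nursing_home": 0.15,
    "drug": 1.0,
}
#: Extra lognormal sigma per category on top of the shared patient frailty.
CATEGORY_SIGMA = {
    "hospitalization": 0.55,
    "rehabilitation": 0.60,
    "medical_visit": 0.40,
    "nursing_visit_home": 0.50,
    "nursing_home": 0.45,
    "drug": 0.45,
}


@dataclass(frozen=True)
class MissingnessSpec:
    """Element-wise deletion of utility scores and cost categories.

    Rates are per element (one utility timepoint, one cost category); the
    defaults are calibrated so that, together with withdrawal-driven
    censoring, ~8% of patients lack >=1 cost element and ~26% lack >=1
    element needed for QALY estimation.  MAR weights act on the logit scale
    with the intercept solved so the realized mean rate matches the request;
    MNAR adds ``mnar_delta`` times the standardized to-be-deleted value.
    """

    mechanism: str = "MAR"  # MCAR | MAR | MNAR
    rate_utility: float = 0.046
    rate_cost: float = 0.0138
    mar_weights: dict[str, float] = field(
        default_factory=lambda: {"dementia": 1.2, "housebound": 0.6, "age_decades": 0.3}
    )
    mnar_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        for r in (self.rate_utility, self.rate_cost):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")


@dataclass(frozen=True)
class TrialConfig:
    """Generator configuration; the defaults are the emulated trial's conditions."""

    n_patients: int = 2008
    country_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    n_clusters_intervention: int = 54
    n_clusters_control: int = 56
    true_delta_cost: float = 0.0  # CHF, effect on total healthcare cost
    true_delta_qaly: float = 0.0  # utility-years
    cluster_sd_cost: float = 4000.0  # CHF, SD of cluster-level mean-cost shifts
    cluster_sd_utility: float = 0.04  # utility scale
    mean_total_cost: float = 44000.0  # CHF, trial-wide annual mean (medical)
    cost_sigma_patient: float = 0.85  # shared lognormal frailty; drives mean>>median
    cost_family: str = "lognormal"  # lognormal | gamma
    utility_baseline_mean: float = 0.72
    utility_sd: float = 0.30
    utility_ar1: float = 0.75  # autocorrelation between successive assessments
    utility_time_trend: float = 0.0  # per-year drift of the latent mean
    cost_utility_corr: float = -0.3  # frailty loading linking high cost to low utility
    death_hazard: float = 0.191  # one-year death probability
    withdrawal_prob: float = 0.064  # withdrawal + loss to follow-up, censoring
    informal_care_mean: float = 6000.0  # CHF per year among users
    informal_care_prob: float = 0.5
    software_cost_per_patient: float = 10.0
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.country_weights.values()) - 1.0) > 1e-9:
            raise ValueError("country_weights must sum to 1")
        if self.n_clusters_intervention < 2 or self.n_clusters_control < 2:
            raise ValueError("need at least 2 clusters per arm")
        n_clusters = self.n_clusters_intervention + self.n_clusters_control
        if n_clusters > self.n_patients:
            raise ValueError("more clusters than patients is infeasible")
        for name in ("death_hazard", "withdrawal_prob", "informal_care_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cost_family not in ("lognormal", "gamma"):
            raise ValueError("cost_family must be 'lognormal' or 'gamma'")


@dataclass
class TrialData:
    """The three trial tables plus the generating truth."""

    patients: pd.DataFrame
    utilities: pd.DataFrame  # long: patient_id, timepoint_day, 5 dimensions
    resource_use: pd.DataFrame  # long: patient_id, category, item_code, quantity, event_day
    truth: dict

    def write_csv(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(d / "patients.csv", index=False)
        self.utilities.to_csv(d / "utilities.csv", index=False)
        self.resource_use.to_csv(d / "resource_use.csv", index=False)


def _allocate_clusters(config: TrialConfig) -> pd.DataFrame:
    """Clusters per (arm, country), largest-remainder allocation, >=1 each."""
    rows = []
    cid = 0
    for arm, n_cl in (("intervention", config.n_clusters_intervention),
                      ("control", config.n_clusters_control)):
        ideal = {c: config.country_weights[c] * n_cl for c in config.country_weights}
        counts = {c: max(1, int(np.floor(v))) for c, v in ideal.items()}
        while sum(counts.values()) < n_cl:
            rem = {c: ideal[c] - counts[c] for c in counts}
            counts[max(rem, key=rem.get)] += 1
        while sum(counts.values()) > n_cl:
            rem = {c: ideal[c] - counts[c] for c in counts if counts[c] > 1}
            counts[min(rem, key=rem.get)] -= 1
        for c, k in counts.items():
            for _ in range(k):
                rows.append({"cluster_id": f"cl{cid:03d}", "arm": arm, "country": c})
                cid += 1
    return pd.DataFrame(rows)


def _draw_patients(config: TrialConfig, clusters: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    countries = list(config.country_weights)
    weights = np.array([config.country_weights[c] for c in countries])
    country = rng.choice(countries, size=n, p=weights)
    cluster_id = np.empty(n, dtype=object)
    for c in countries:
        pool = clusters.loc[clusters["country"] == c, "cluster_id"].to_numpy()
        idx = np.flatnonzero(country == c)
        cluster_id[idx] = rng.choice(pool, size=idx.size)
    arm = pd.Series(cluster_id).map(clusters.set_index("cluster_id")["arm"]).to_numpy()

    age = np.minimum(70.0 + rng.lognormal(np.log(9.0), 0.5, n), 102.0)
    female = rng.random(n) < 0.447
    education = rng.choice(["less-than-high-school", "high-school", "university"],
                           size=n, p=[0.5, 0.3, 0.2])
    smoker = rng.random(n) < 0.10
    alcohol = np.round(rng.exponential(3.0, n), 1)
    n_drugs = 5 + rng.poisson(4.0, n)
    n_comorb = 3 + rng.poisson(3.0, n)
    n_hosp_prior = rng.poisson(0.8, n)
    housebound = rng.random(n) < 0.12
    nursing_home = rng.random(n) < 0.08
    dementia = rng.random(n) < 0.12
    index_ward = rng.choice(["medical", "surgical"], size=n, p=[0.7, 0.3])
    index_duration = np.round(np.minimum(rng.lognormal(np.log(9.0), 0.6, n), 90.0), 0)

    died = rng.random(n) < config.death_hazard
    death_day = np.where(died, np.ceil(rng.uniform(0.0, 365.0, n)), np.nan)
    withdrew = (~died) & (rng.random(n) < config.withdrawal_prob / max(1e-12, 1 - config.death_hazard))
    withdraw_day = np.ceil(rng.uniform(30.0, 365.0, n))
    followup = np.where(died, death_day, np.where(withdrew, withdraw_day, 365.0))

    return pd.DataFrame({
        "patient_id": [f"p{i:04d}" for i in range(n)],
        "cluster_id": cluster_id,
        "country": country,
        "arm": arm,
        "age": np.round(age, 1),
        "female": female.astype(int),
        "education": education,
        "smoker": smoker.astype(int),
        "alcohol_units_week": alcohol,
        "n_drugs_baseline": n_drugs,
        "n_comorbidities_baseline": n_comorb,
        "n_hosp_prior_year": n_hosp_prior,
        "housebound": housebound.astype(int),
        "nursing_home_baseline": nursing_home.astype(int),
        "dementia": dementia.astype(int),
        "index_ward": index_ward,
        "index_duration": index_duration,
        "followup_days": followup,
        "death_day": death_day,
    })


def _utility_latent_mean(patients: pd.DataFrame, frailty: np.ndarray, config: TrialConfig,
                         cluster_u: pd.Series) -> np.ndarray:
    p = patients
    mu = (config.utility_baseline_mean
          - 0.004 * (p["age"].to_numpy() - 79.0)
          - 0.12 * p["dementia"].to_numpy()
          - 0.10 * p["housebound"].to_numpy()
          - 0.08 * p["nursing_home_baseline"].to_numpy()
          - 0.010 * (p["n_comorbidities_baseline"].to_numpy() - 6.0)
          - 0.005 * (p["n_drugs_baseline"].to_numpy() - 9.0)
          + config.cost_utility_corr * 0.10 * frailty
          + p["cluster_id"].map(cluster_u).to_numpy())
    return mu


def _qaly_shift_factor(config: TrialConfig, mu: np.ndarray) -> float:
    """Expected QALY change per unit of post-baseline latent-utility shift.

    Accounts for (a) the trapezium weights of the scheduled assessments
    (baseline is unshifted, randomization precedes any effect), (b) death
    truncating the shifted period, and (c) clipping of the latent utility to
    [0, 1], which attenuates a mean shift by the probability mass strictly
    inside the interval.
    """
    # trapezium weight of days 61/183/365 within [0, 365] for a survivor
    w_survivor = (91.5 + 152.0 + 91.0) / 365.25
    # death day ~ U(0, 365): E[ integral of min(t/61, 1) up to death ] / 365.25
    e_trunc = (61.0 ** 3 / 366.0 / 365.0 + ((365.0 ** 2 - 61.0 ** 2) / 2.0 - 30.5 * 304.0) / 365.0)
    w_dead = e_trunc / 365.25
    p = config.death_hazard
    w = config.withdrawal_prob
    # withdrawal censors at ~U(30, 365); roughly half the shifted period is lost
    time_factor = ((1.0 - p - w * (1 - p)) * w_survivor + p * w_dead
                   + w * (1 - p) * 0.55 * w_survivor)
    def inside(shift: float) -> float:
        return float(np.mean(
            norm.cdf((1.0 - mu - shift) / config.utility_sd)
            - norm.cdf((0.0 - mu - shift) / config.utility_sd)))
    # clipping attenuates the mean shift by the interior probability mass,
    # evaluated at the shift midpoint (fixed point, a few iterations)
    factor = time_factor * inside(0.0)
    for _ in range(4):
        shift = config.true_delta_qaly / factor if factor > 0 else 0.0
        factor = time_factor * inside(shift / 2.0)
    return factor


def _latent_utilities(patients: pd.DataFrame, config: TrialConfig, frailty: np.ndarray,
                      cluster_u: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Clipped AR(1) utility per patient at every scheduled day (wide)."""
    n = len(patients)
    mu = _utility_latent_mean(patients, frailty, config, cluster_u)
    qshift = 0.0
    if config.true_delta_qaly != 0.0:
        qshift = config.true_delta_qaly / _qaly_shift_factor(config, mu)
    is_interv = (patients["arm"] == "intervention").to_numpy()

    phi, sd = config.utility_ar1, config.utility_sd
    lat = np.empty((n, len(SCHEDULED_DAYS)))
    e = rng.standard_normal((n, len(SCHEDULED_DAYS)))
    lat[:, 0] = mu + sd * e[:, 0]
    for t in range(1, len(SCHEDULED_DAYS)):
        lat[:, t] = mu + phi * (lat[:, t - 1] - mu) + sd * np.sqrt(1 - phi ** 2) * e[:, t]
    if config.utility_time_trend != 0.0:
        years = np.array(SCHEDULED_DAYS) / 365.25
        lat += config.utility_time_trend * years[None, :]
    # intervention effect from the first post-baseline assessment onward
    post = np.array([d > 0 for d in SCHEDULED_DAYS])
    lat[np.ix_(is_interv, post)] += qshift
    return pd.DataFrame(np.clip(lat, 0.0, 1.0), columns=[f"day_{d}" for d in SCHEDULED_DAYS],
                        index=patients["patient_id"])


def _utilities_long(patients: pd.DataFrame, latent: pd.DataFrame,
                    rng: np.random.Generator) -> pd.DataFrame:
    """EQ-5D-5L responses from latent utilities via the additive toy rule.

    The total decrement d = (1 - u)/0.05 is stochastically rounded (floor
    plus a Bernoulli on the fractional part, which is mean-preserving) and
    allocated uniformly at random over the five dimensions (each capped at
    level 5).  Assessments stop at death or withdrawal; the pre-baseline
    recall point and baseline are always collected at enrollment.
    """
    rows = []
    fup = patients.set_index("patient_id")["followup_days"]
    death = patients.set_index("patient_id")["death_day"]
    caps = np.array([4, 4, 4, 4, 4])
    for pid, lat in latent.iterrows():
        for day, u in zip(SCHEDULED_DAYS, lat.to_numpy()):
            if day > 0:
                if day > fup[pid]:
                    continue
                dd = death[pid]
                if not np.isnan(dd) and day >= dd:
                    continue
            dec = (1.0 - u) / 0.05
            d_int = int(np.floor(dec))
            if rng.random() < dec - d_int:
                d_int += 1
            d_int = min(max(d_int, 0), 20)
            alloc = rng.multivariate_hypergeometric(caps, d_int)
            rows.append((pid, day, *(alloc + 1)))
    return pd.DataFrame(rows, columns=["patient_id", "timepoint_day", "mobility", "self_care",
                                       "usual_activities", "pain_discomfort", "anxiety_depression"])


def _expected_delivery_cost(config: TrialConfig, unit_costs: UnitCostTable, ppp: PPPIndex) -> float:
    """Mean CHF delivery cost per intervention patient, weighted by country."""
    total = 0.0
    for c, w in config.country_weights.items():
        phys = unit_costs.lookup(c, "intervention_delivery", "physician_minutes")
        pharm = unit_costs.lookup(c, "intervention_delivery", "pharmacist_minutes")
        total += w * ((30.0 * phys + 45.0 * pharm) * ppp.factor(c) + config.software_cost_per_patient)
    return total


def _cost_tables(patients: pd.DataFrame, config: TrialConfig, frailty: np.ndarray,
                 cluster_b: pd.Series, unit_costs: UnitCostTable, ppp: PPPIndex,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resource-use events whose priced CHF value realizes the cost model.

    Target CHF amounts per category are generated first (shared lognormal
    patient frailty x multiplicative cluster shift x covariate profile x
    category-specific noise, with occurrence indicators), then converted
    into quantities with the local unit cost and PPP factor so that the
    costing chain reproduces them exactly.  Returns (events, truth per
    patient in CHF).
    """
    p = patients
    n = len(p)
    is_interv = (p["arm"] == "intervention").to_numpy()

    # covariate profile on the log scale, empirically normalized to mean 1
    log_profile = (0.010 * (p["age"].to_numpy() - 79.0)
                   + 1.10 * p["nursing_home_baseline"].to_numpy()
                   + 0.04 * (p["n_comorbidities_baseline"].to_numpy() - 6.0)
                   + 0.03 * (p["n_drugs_baseline"].to_numpy() - 9.0)
                   + 0.15 * np.minimum(p["n_hosp_prior_year"].to_numpy(), 4)
                   + 0.20 * p["housebound"].to_numpy()
                   + 0.10 * p["dementia"].to_numpy()
                   + 0.10 * (p["index_ward"] == "medical").to_numpy()
                   + 0.010 * (p["index_duration"].to_numpy() - 9.0))
    profile = np.exp(log_profile)
    profile /= profile.mean()

    sz = config.cost_sigma_patient
    frail_mult = np.exp(sz * frailty - 0.5 * sz ** 2)
    cluster_mult = p["cluster_id"].map(cluster_b).to_numpy()

    deliv_exp = _expected_delivery_cost(config, unit_costs, ppp)
    arm_factor = np.where(
        is_interv, 1.0 + (config.true_delta_cost - deliv_exp) / config.mean_total_cost, 1.0
    )

    base = config.mean_total_cost * profile * frail_mult * cluster_mult * arm_factor
    truth = pd.DataFrame({"patient_id": p["patient_id"]})
    events = []
    country = p["country"].to_numpy()
    fup = p["followup_days"].to_numpy()
    for cat in HEALTHCARE_CATEGORIES:
        share, occ, sig = CATEGORY_SHARES[cat], CATEGORY_OCCURRENCE[cat], CATEGORY_SIGMA[cat]
        use = rng.random(n) < occ
        if cat == "nursing_home":  # residents always accrue nursing-home cost
            use |= p["nursing_home_baseline"].to_numpy().astype(bool)
            occ_eff = np.where(p["nursing_home_baseline"], 1.0, occ)
        else:
            occ_eff = occ
        if config.cost_family == "lognormal":
            noise = np.exp(sig * rng.standard_normal(n) - 0.5 * sig ** 2)
        else:  # gamma with the same mean and log-scale spread
            shape = 1.0 / (np.exp(sig ** 2) - 1.0)
            noise = rng.gamma(shape, 1.0 / shape, n)
        chf = np.where(use, base * share / occ_eff * noise, 0.0)
        truth[cat] = chf
        for c in np.unique(country):
            unit = unit_costs.lookup(c, cat) * ppp.factor(c)
            sel = np.flatnonzero((country == c) & (chf > 0))
            for i in sel:
                events.append((p["patient_id"].iloc[i], cat, "",
                               chf[i] / unit, float(np.floor(rng.uniform(0, min(365.0, fup[i]) + 1)))))

    # informal care: arm-neutral by default, shares the frailty
    use_ic = rng.random(n) < config.informal_care_prob
    noise_ic = np.exp(0.6 * rng.standard_normal(n) - 0.18)
    chf_ic = np.where(use_ic, config.informal_care_mean / config.informal_care_prob
                      * profile * frail_mult * cluster_mult * noise_ic, 0.0)
    truth["informal_care"] = chf_ic
    for c in np.unique(country):
        unit = unit_costs.lookup(c, "informal_care") * ppp.factor(c)
        for i in np.flatnonzero((country == c) & (chf_ic > 0)):
            events.append((p["patient_id"].iloc[i], "informal_care", "",
                           chf_ic[i] / unit, float(np.floor(rng.uniform(0, min(365.0, fup[i]) + 1)))))

    # intervention delivery: trial-observed staff minutes, intervention arm only
    phys_min = np.maximum(rng.normal(30.0, 5.0, n), 0.0)
    pharm_min = np.maximum(rng.normal(45.0, 8.0, n), 0.0)
    for i in np.flatnonzero(is_interv):
        events.append((p["patient_id"].iloc[i], "intervention_delivery", "physician_minutes",
                       phys_min[i], 0.0))
        events.append((p["patient_id"].iloc[i], "intervention_delivery", "pharmacist_minutes",
                       pharm_min[i], 0.0))

    ev = pd.DataFrame(events, columns=["patient_id", "category", "item_code", "quantity", "event_day"])
    return ev, truth


def generate_trial(config: TrialConfig, unit_costs: UnitCostTable | None = None,
                   ppp: PPPIndex | None = None) -> TrialData:
    """Generate one complete synthetic trial (no missingness applied)."""
    unit_costs = unit_costs or example_unit_costs()
    ppp = ppp or example_ppp()
    ss = np.random.SeedSequence(config.seed)
    rng_pat, rng_util, rng_cost, rng_cluster = [np.random.Generator(np.random.PCG64(s))
                                                for s in ss.spawn(4)]

    clusters = _allocate_clusters(config)
    patients = _draw_patients(config, clusters, rng_pat)

    s_b = config.cluster_sd_cost / config.mean_total_cost
    cluster_b = pd.Series(
        np.exp(rng_cluster.normal(0.0, s_b, len(clusters)) - 0.5 * s_b ** 2),
        index=clusters["cluster_id"],
    )
    cluster_u = pd.Series(rng_cluster.normal(0.0, config.cluster_sd_utility, len(clusters)),
                          index=clusters["cluster_id"])
    frailty = rng_cost.standard_normal(len(patients))

    latent = _latent_utilities(patients, config, frailty, cluster_u, rng_util)
    utilities = _utilities_long(patients, latent, rng_util)
    resource_use, cost_truth = _cost_tables(patients, config, frailty, cluster_b,
                                            unit_costs, ppp, rng_cost)

    truth = {
        "true_delta_cost": config.true_delta_cost,
        "true_delta_qaly": config.true_delta_qaly,
        "latent_utilities": latent,
        "cost_chf": cost_truth,
    }
    return TrialData(patients=patients, utilities=utilities, resource_use=resource_use, truth=truth)


def _solve_intercept(logits: np.ndarray, rate: float) -> float:
    """Intercept a such that mean(sigmoid(a + logits)) == rate."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf

    def f(a: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(a + logits))))) - rate

    return brentq(f, -30.0, 30.0)


def _mar_logits(patients: pd.DataFrame, spec: MissingnessSpec) -> np.ndarray:
    z = np.zeros(len(patients))
    for name, w in spec.mar_weights.items():
        if name == "age_decades":
            z += w * (patients["age"].to_numpy() - 79.0) / 10.0
        else:
            z += w * patients[name].to_numpy().astype(float)
    return z


def apply_missingness(data: TrialData, spec: MissingnessSpec | None = None,
                      seed: int = 0) -> TrialData:
    """Delete utility scores and cost-category elements per the mechanism.

    Utility deletion blanks all five dimension responses of the selected
    assessment (the score is missing as a whole).  Cost deletion blanks the
    quantities of the selected (patient, category) cell, or inserts a
    missing-quantity marker row when the patient had no event in that
    category (an unobserved cell is not a known zero).  Deaths and follow-up
    information are never deleted.  Baseline/pre-baseline assessments,
    collected in person at enrollment, are exempt from deletion; only
    follow-up assessments can go missing.
    """
    spec = spec or MissingnessSpec()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    patients = data.patients
    utilities = data.utilities.copy()
    resource_use = data.resource_use.copy()

    dims = ["mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression"]
    if spec.rate_utility > 0:
        cand = utilities["timepoint_day"] > 0
        idx = utilities.index[cand]
        pat = utilities.loc[idx, "patient_id"]
        if spec.mechanism == "MCAR":
            logits = np.zeros(len(idx))
        else:
            base = pd.Series(_mar_logits(patients, spec), index=patients["patient_id"])
            logits = pat.map(base).to_numpy()
            if spec.mechanism == "MNAR":
                lv = utilities.loc[idx, dims].to_numpy(dtype=float)
                score = 1.0 - 0.05 * (lv - 1).sum(axis=1)  # value on the additive scale
                logits = logits + spec.mnar_delta * (score - np.nanmean(score)) / max(np.nanstd(score), 1e-9)
        a = _solve_intercept(logits, spec.rate_utility)
        drop = rng.random(len(idx)) < 1.0 / (1.0 + np.exp(-(a + logits)))
        utilities.loc[idx[drop], dims] = np.nan

    if spec.rate_cost > 0:
        cells = pd.MultiIndex.from_product([patients["patient_id"], HEALTHCARE_CATEGORIES],
                                           names=["patient_id", "category"])
        cell_df = cells.to_frame(index=False)
        if spec.mechanism == "MCAR":
            logits = np.zeros(len(cell_df))
        else:
            base = pd.Series(_mar_logits(patients, spec), index=patients["patient_id"])
            logits = cell_df["patient_id"].map(base).to_numpy()
            if spec.mechanism == "MNAR":
                truth = data.truth.get("cost_chf")
                if truth is not None:
                    t = truth.set_index("patient_id")
                    vals = np.array([np.log1p(t.at[pid, cat])
                                     for pid, cat in cell_df.itertuples(index=False)])
                    logits = logits + spec.mnar_delta * (vals - vals.mean()) / max(vals.std(), 1e-9)
        a = _solve_intercept(logits, spec.rate_cost)
        drop = rng.random(len(cell_df)) < 1.0 / (1.0 + np.exp(-(a + logits)))
        dropped = cell_df[drop]
        key = resource_use.set_index(["patient_id", "category"]).index
        mask = key.isin(pd.MultiIndex.from_frame(dropped))
        resource_use.loc[mask, "quantity"] = np.nan
        # cells with no events at all: add an explicit missing marker row
        have = set(map(tuple, data.resource_use[["patient_id", "category"]].itertuples(index=False)))
        extra = [
            {"patient_id": pid, "category": cat, "item_code": "", "quantity": np.nan, "event_day": 0.0}
            for pid, cat in dropped.itertuples(index=False) if (pid, cat) not in have
        ]
        if extra:
            resource_use = pd.concat([resource_use, pd.DataFrame(extra)], ignore_index=True)

    return TrialData(patients=patients, utilities=utilities, resource_use=resource_use,
                     truth=data.truth)
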