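"""Deterministic and probabilistic sensitivity analysis.

Deterministic: each cost category's unit costs are scaled by 0.7 / 1.3 in
turn and the pooled CEA re-run (the QALY side is invariant by
construction).  Probabilistic: a nonparametric bootstrap (clusters
resampled with replacement, stratified by arm and country, by default)
combined with parameter uncertainty on the cost side — one multiplier per
cost category drawn from Normal(1, sd) in every replicate — refitting the
model and recording (incremental cost, incremental QALY).  The replicates
from all imputed datasets are pooled into one cost-effectiveness plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .costing import HEALTHCARE_CATEGORIES
from .pipeline import COST_COLS, recompute_totals

logger = logging.getLogger(__name__)

#: sd such that +-30% is roughly a 95% range of the multiplier distribution.
DEFAULT_MULTIPLIER_SD = 0.153


@dataclass(frozen=True)
class PSAConfig:
    b: int = 1000  # bootstrap replications per imputed dataset
    multiplier_sd: float | dict[str, float] = DEFAULT_MULTIPLIER_SD
    resample_unit: str = "cluster"  # cluster | patient | none
    resample: bool = True
    seed: int = 0
    max_failure_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError("need at least one bootstrap replication")
        sds = (self.multiplier_sd.values() if isinstance(self.multiplier_sd, dict)
               else [self.multiplier_sd])
        if any(s < 0 for s in sds):
            raise ValueError("multiplier sds must be non-negative")
        if self.resample_unit not in ("cluster", "patient"):
            raise ValueError("resample_unit must be 'cluster' or 'patient'")

    def sd_for(self, category: str) -> float:
        if isinstance(self.multiplier_sd, dict):
            return self.multiplier_sd.get(category, DEFAULT_MULTIPLIER_SD)
        return self.multiplier_sd


def scale_category(df: pd.DataFrame, category: str, factor: float) -> pd.DataFrame:
    """Rescale one category's costs and rebuild the totals."""
    if category not in HEALTHCARE_CATEGORIES and category not in ("informal_care",):
        raise ValueError(f"unknown cost category {category!r}")
    out = df.copy()
    out[COST_COLS[category]] = out[COST_COLS[category]] * factor
    return recompute_totals(out)


def deterministic_sa(datasets: list[pd.DataFrame], variant: str = "joint",
                     spec: models.CovariateSpec | None = None,
                     perspective: str = "healthcare",
                     factors: tuple[float, ...] = (0.7, 1.3),
                     categories: tuple[str, ...] = HEALTHCARE_CATEGORIES) -> pd.DataFrame:
    """One-at-a-time +-30% unit-cost scenarios; one row per scenario."""
    rows = []
    for cat in categories:
        for f in factors:
            scaled = [scale_category(d, cat, f) for d in datasets]
            res = models.run_cea(scaled, variant=variant, spec=spec, perspective=perspective)
            rows.append({"category": cat, "factor": f,
                         "delta_cost": res.delta_cost.estimate,
                         "cost_ci_low": res.delta_cost.ci_low,
                         "cost_ci_high": res.delta_cost.ci_high,
                         "delta_qaly": res.delta_qaly.estimate,
                         "qaly_ci_low": res.delta_qaly.ci_low,
                         "qaly_ci_high": res.delta_qaly.ci_high,
                         "label": res.verdict.label})
    return pd.DataFrame(rows)


def _resample(df: pd.DataFrame, unit: str, rng: np.random.Generator) -> pd.DataFrame:
    """Stratified resampling with replacement; clusters keep their integrity."""
    if unit == "patient":
        parts = []
        for _, grp in df.groupby(["arm", "country"], sort=True):
            idx = rng.integers(0, len(grp), len(grp))
            parts.append(grp.iloc[idx])
        return pd.concat(parts, ignore_index=True)
    parts = []
    copy_counter = 0
    for _, grp in df.groupby(["arm", "country"], sort=True):
        clusters = np.sort(grp["cluster_id"].unique())
        chosen = rng.choice(clusters, size=len(clusters), replace=True)
        for c in chosen:
            block = grp[grp["cluster_id"] == c].copy()
            block["cluster_id"] = f"{c}~{copy_counter}"  # repeated draws are distinct clusters
            copy_counter += 1
            parts.append(block)
    return pd.concat(parts, ignore_index=True)


@dataclass
class BootstrapCloud:
    points: pd.DataFrame  # columns: imputation, replicate, delta_cost, delta_qaly
    n_failures: int = 0
    config: PSAConfig | None = None


def bootstrap_psa(datasets: list[pd.DataFrame], variant: str = "joint",
                  psa: PSAConfig | None = None, spec: models.CovariateSpec | None = None,
                  perspective: str = "healthcare") -> BootstrapCloud:
    """Combined bootstrap + cost-parameter PSA over all imputed datasets."""
    psa = psa or PSAConfig()
    spec = spec or models.CovariateSpec()
    if perspective == "societal":
        from dataclasses import replace
        spec = replace(spec, outcome_cost="total_societal")
    fitter = models.VARIANTS[variant]
    ss = np.random.SeedSequence(psa.seed)
    rngs = [np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(len(datasets))]
    rows = []
    failures = 0
    max_failures = max(1, int(np.ceil(psa.max_failure_fraction * psa.b * len(datasets))))
    for imp, (d, rng) in enumerate(zip(datasets, rngs)):
        if variant == "joint":  # warm-start refits from the point fit
            point = models.fit_joint_model(d, spec)
            theta0 = point.extra["theta"]
            fitter = lambda frame, sp: models.fit_joint_model(frame, sp, theta0=theta0)
        b_done = 0
        while b_done < psa.b:
            sample = _resample(d, psa.resample_unit, rng) if psa.resample else d.copy()
            for cat in HEALTHCARE_CATEGORIES:
                mult = max(rng.normal(1.0, psa.sd_for(cat)), 0.0)
                sample[COST_COLS[cat]] = sample[COST_COLS[cat]] * mult
            sample = recompute_totals(sample)
            try:
                fit = fitter(sample, spec)
                if not (np.isfinite(fit.incremental_cost) and np.isfinite(fit.incremental_qaly)):
                    raise RuntimeError("non-finite bootstrap estimate")
            except Exception as exc:  # noqa: BLE001 - replicate is redrawn
                failures += 1
                logger.debug("bootstrap replicate failed: %s", exc)
                if failures > max_failures:
                    raise RuntimeError(
                        f"more than {psa.max_failure_fraction:.0%} of bootstrap replicates "
                        f"failed ({failures})") from exc
                continue
            rows.append({"imputation": imp, "replicate": b_done,
                         "delta_cost": fit.incremental_cost, "delta_qaly": fit.incremental_qaly})
            b_done += 1
    cloud = BootstrapCloud(points=pd.DataFrame(rows), n_failures=failures, config=psa)
    if failures:
        logger.info("bootstrap finished with %d redrawn replicate(s)", failures)
    return cloud


def quadrant_fractions(cloud: BootstrapCloud | pd.DataFrame) -> dict:
    """Fractions of replicates per CE-plane quadrant (sum to exactly 1).

    Quadrants by (sign of delta_qaly, sign of delta_cost):
    lower-right = dominant (QALY gain, cost saving), upper-left = dominated.
    Exact zeros are assigned to the favourable (dominant) quadrant and
    counted separately under ``ties``.
    """
    pts = cloud.points if isinstance(cloud, BootstrapCloud) else cloud
    if len(pts) == 0:
        raise ValueError("empty bootstrap cloud")
    dq = pts["delta_qaly"].to_numpy()
    dc = pts["delta_cost"].to_numpy()
    ties = int(((dq == 0) | (dc == 0)).sum())
    lower_right = (dq >= 0) & (dc <= 0)
    upper_right = (dq >= 0) & (dc > 0)
    lower_left = (dq < 0) & (dc < 0)
    upper_left = (dq < 0) & (dc >= 0)
    n = len(pts)
    out = {
        "dominant_lower_right": lower_right.sum() / n,
        "trade_off_upper_right": upper_right.sum() / n,
        "saving_per_qaly_lost_lower_left": lower_left.sum() / n,
        "dominated_upper_left": upper_left.sum() / n,
        "ties": ties,
        "n": n,
    }
    assert abs(sum(v for k, v in out.items() if k.endswith(("right", "left"))) - 1.0) < 1e-12
    return out


def ce_plane_export(cloud: BootstrapCloud | pd.DataFrame, csv_path=None, plot_path=None,
                    point_estimate: tuple[float, float] | None = None) -> pd.DataFrame:
    """Write the (delta_qaly, delta_cost) points and an annotated scatter.

    QALY gains sit on the right-hand side of the plane, cost increases in
    the upper half.
    """
    pts = cloud.points if isinstance(cloud, BootstrapCloud) else cloud
    if len(pts) == 0:
        raise ValueError("empty bootstrap cloud")
    out = pts[["delta_qaly", "delta_cost"]].copy()
    if csv_path is not None:
        out.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frac = quadrant_fractions(pts)
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(out["delta_qaly"], out["delta_cost"], s=6, alpha=0.35, edgecolors="none")
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        if point_estimate is not None:
            ax.scatter([point_estimate[1]], [point_estimate[0]], color="red", marker="x", s=60,
                       label="point estimate")
            ax.legend(loc="upper left", fontsize=8)
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (CHF)")
        ax.set_title(f"Cost-effectiveness plane "
                     f"({frac['dominant_lower_right']:.1%} dominant)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return out
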