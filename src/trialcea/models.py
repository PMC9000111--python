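"""Simultaneous cost/QALY regression with cluster random effects.

The main model is a bivariate linear mixed model: a cost equation and a
QALY equation that share the cluster grouping, with correlated
cluster-level random intercepts (2x2 covariance S_u) and correlated
patient-level residuals (2x2 covariance S_e), estimated by maximum
likelihood.  The arm coefficients of the two equations are the incremental
cost and incremental QALY.  Robustness variants: seemingly unrelated
regression (no random effects), separate univariate mixed models, and a
gamma/log-link cost model with the incremental cost recovered as an
average marginal effect.

The marginal covariance of a cluster with n_j patients is
I (x) S_e + J (x) S_u, whose inverse and determinant are available in
closed form through the eigenstructure of J = 1 1'; the fixed effects are
profiled out by GLS, leaving a 6-parameter (two Cholesky factors)
quasi-Newton optimization with fixed starting values, so fits are
deterministic given the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .impute import rubin_pool, PooledEstimate
from .reporting import IcerVerdict, compute_icer

logger = logging.getLogger(__name__)

BASE_COVARIATES = (
    "arm_intervention", "age", "female", "utility_minus6m", "utility_baseline",
    "n_drugs_baseline", "n_comorbidities_baseline", "housebound", "smoker",
    "edu_high_school", "edu_university", "nursing_home_baseline", "dementia",
    "n_hosp_prior_year", "medical_ward", "index_duration",
    "country_IE", "country_BE", "country_NL",
)


@dataclass(frozen=True)
class CovariateSpec:
    """Regressors per equation; observation time enters the cost side only.

    Reference levels: Switzerland, less-than-high-school education, male,
    control arm (arm coded 0/1).
    """

    cost_covariates: tuple[str, ...] = BASE_COVARIATES + ("observation_time",)
    qaly_covariates: tuple[str, ...] = BASE_COVARIATES
    outcome_cost: str = "total_healthcare"
    outcome_qaly: str = "qaly"

    def drop(self, names) -> "CovariateSpec":
        names = set(names)
        return replace(self,
                       cost_covariates=tuple(c for c in self.cost_covariates if c not in names),
                       qaly_covariates=tuple(c for c in self.qaly_covariates if c not in names))

    def add(self, names) -> "CovariateSpec":
        extra = tuple(names)
        return replace(self, cost_covariates=self.cost_covariates + extra,
                       qaly_covariates=self.qaly_covariates + extra)


def add_design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Engineer the dummy/derived regressors from the raw patient columns."""
    out = df.copy()
    out["arm_intervention"] = (out["arm"] == "intervention").astype(float)
    out["edu_high_school"] = (out["education"] == "high-school").astype(float)
    out["edu_university"] = (out["education"] == "university").astype(float)
    out["medical_ward"] = (out["index_ward"] == "medical").astype(float)
    for c in ("IE", "BE", "NL"):
        out[f"country_{c}"] = (out["country"] == c).astype(float)
    out["observation_time"] = out["followup_days"].astype(float)
    out["died"] = out["death_day"].notna().astype(float)
    return out


@dataclass
class ModelFit:
    variant: str
    coef_cost: pd.Series
    se_cost: pd.Series
    coef_qaly: pd.Series
    se_qaly: pd.Series
    incremental_cost: float
    incremental_cost_se: float
    incremental_qaly: float
    incremental_qaly_se: float
    sigma_e: np.ndarray | None
    sigma_u: np.ndarray | None
    loglike: float
    converged: bool
    n: int
    extra: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for eq, coef, se in (("cost", self.coef_cost, self.se_cost),
                             ("qaly", self.coef_qaly, self.se_qaly)):
            for term in coef.index:
                z = stats.norm.ppf(0.975)
                rows.append({"equation": eq, "term": term, "estimate": coef[term],
                             "se": se[term], "ci_low": coef[term] - z * se[term],
                             "ci_high": coef[term] + z * se[term]})
        return pd.DataFrame(rows)


def _design(df: pd.DataFrame, spec: CovariateSpec):
    xc = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float)
                                               for c in spec.cost_covariates])
    xq = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float)
                                               for c in spec.qaly_covariates])
    yc = df[spec.outcome_cost].to_numpy(dtype=float)
    yq = df[spec.outcome_qaly].to_numpy(dtype=float)
    if np.isnan(xc).any() or np.isnan(xq).any() or np.isnan(yc).any() or np.isnan(yq).any():
        raise ValueError("model input contains missing values; impute first")
    names_c = ["const"] + list(spec.cost_covariates)
    names_q = ["const"] + list(spec.qaly_covariates)
    return xc, xq, yc, yq, names_c, names_q


def _chol2(a: float, b: float, c: float) -> np.ndarray:
    l = np.array([[np.exp(a), 0.0], [c, np.exp(b)]])
    return l @ l.T


class _JointLikelihood:
    """Profiled bivariate mixed-model likelihood with precomputed cross-products."""

    def __init__(self, xc, xq, yc, yq, cluster_codes):
        n = len(yc)
        self.n = n
        self.kc, self.kq = xc.shape[1], xq.shape[1]
        k = self.kc + self.kq
        self.k = k
        w = np.zeros((n, 2, k))
        w[:, 0, :self.kc] = xc
        w[:, 1, self.kc:] = xq
        y2 = np.column_stack([yc, yq])
        self.sc = yc.std() or 1.0
        self.sq = yq.std() or 1.0
        y2 = y2 / np.array([self.sc, self.sq])
        self.w, self.y2 = w, y2

        # global cross-products (independent of the variance parameters)
        self.g = np.einsum("nak,nbl->abkl", w, w)
        self.h = np.einsum("nak,nb->abk", w, y2)
        self.q = y2.T @ y2

        # per-cluster sums
        j = cluster_codes
        self.nj = np.bincount(j).astype(float)
        nclus = len(self.nj)
        t = np.zeros((nclus, 2, k))
        ty = np.zeros((nclus, 2))
        np.add.at(t, j, w)
        np.add.at(ty, j, y2)
        self.t, self.ty = t, ty
        self.gt = np.einsum("jak,jbl->jabkl", t, t)
        self.hty = np.einsum("jak,jb->jabk", t, ty)
        self.qty = np.einsum("ja,jb->jab", ty, ty)

    def gls(self, sigma_e, sigma_u):
        ainv = np.linalg.inv(sigma_e)
        s = np.einsum("ab,abkl->kl", ainv, self.g)
        r = np.einsum("ab,abk->k", ainv, self.h)
        quad = float(np.einsum("ab,ab->", ainv, self.q))
        logdet = 0.0
        sign, ld_a = np.linalg.slogdet(sigma_e)
        for njv in np.unique(self.nj):
            mask = self.nj == njv
            m_full = np.linalg.inv(sigma_e + njv * sigma_u)
            sign2, ld_f = np.linalg.slogdet(sigma_e + njv * sigma_u)
            logdet += mask.sum() * (ld_f + (njv - 1) * ld_a)
            d = (m_full - ainv) / njv
            s = s + np.einsum("ab,abkl->kl", d, self.gt[mask].sum(axis=0))
            r = r + np.einsum("ab,abk->k", d, self.hty[mask].sum(axis=0))
            quad += float(np.einsum("ab,ab->", d, self.qty[mask].sum(axis=0)))
        beta = np.linalg.solve(s, r)
        quadform = quad - float(r @ beta)
        nll = 0.5 * (logdet + quadform + 2 * self.n * np.log(2 * np.pi))
        return nll, beta, s

    def neg_loglike(self, theta) -> float:
        sigma_e = _chol2(*theta[:3])
        sigma_u = _chol2(*theta[3:])
        try:
            nll, _, _ = self.gls(sigma_e, sigma_u)
        except np.linalg.LinAlgError:
            return 1e12
        return nll if np.isfinite(nll) else 1e12


def fit_joint_model(df: pd.DataFrame, spec: CovariateSpec | None = None,
                    diagonal_ranef: bool = False,
                    theta0: np.ndarray | None = None) -> ModelFit:
    """ML fit of the bivariate cost/QALY mixed model.

    ``df`` must be a completed (post-imputation) analysis table with a
    ``cluster_id`` column.  A near-singular random-effects covariance
    (|correlation| > 0.999) triggers a deterministic refit with a diagonal
    random-effects structure, flagged in ``extra``.
    """
    spec = spec or CovariateSpec()
    if df.groupby(["arm"])["cluster_id"].nunique().min() < 2:
        raise ValueError("need at least 2 clusters per arm")
    xc, xq, yc, yq, names_c, names_q = _design(df, spec)
    codes, _ = pd.factorize(df["cluster_id"], sort=True)
    lik = _JointLikelihood(xc, xq, yc, yq, codes)

    x0 = np.array([np.log(0.9), np.log(0.9), 0.0, np.log(0.3), np.log(0.3), 0.0])
    if theta0 is not None:  # warm start (e.g. bootstrap refits around a point fit)
        x0 = np.clip(np.asarray(theta0, dtype=float), -11.9, 5.9)
    if diagonal_ranef:
        def obj(th5):
            th = np.array([th5[0], th5[1], th5[2], th5[3], th5[4], 0.0])
            return lik.neg_loglike(th)
        res = optimize.minimize(obj, x0[:5], method="L-BFGS-B",
                                bounds=[(-12.0, 6.0), (-12.0, 6.0), (-20.0, 20.0),
                                        (-12.0, 6.0), (-12.0, 6.0)],
                                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        theta = np.array([*res.x, 0.0])
    else:
        res = optimize.minimize(lik.neg_loglike, x0, method="L-BFGS-B",
                                bounds=[(-12.0, 6.0), (-12.0, 6.0), (-20.0, 20.0),
                                        (-12.0, 6.0), (-12.0, 6.0), (-20.0, 20.0)],
                                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        theta = res.x

    sigma_e = _chol2(*theta[:3])
    sigma_u = _chol2(*theta[3:])
    corr_u = sigma_u[0, 1] / np.sqrt(max(sigma_u[0, 0] * sigma_u[1, 1], 1e-300))
    refit_diagonal = (not diagonal_ranef) and abs(corr_u) > 0.999 and sigma_u[0, 0] > 1e-10
    if refit_diagonal:
        logger.info("near-singular random-effects covariance; refitting diagonal structure")
        fit = fit_joint_model(df, spec, diagonal_ranef=True)
        fit.extra["refit_diagonal"] = True
        return fit

    nll, beta, s = lik.gls(sigma_e, sigma_u)
    cov_beta = np.linalg.inv(s)
    se = np.sqrt(np.diag(cov_beta))
    scale = np.concatenate([np.full(lik.kc, lik.sc), np.full(lik.kq, lik.sq)])
    beta_o = beta * scale
    se_o = se * scale
    coef_cost = pd.Series(beta_o[:lik.kc], index=names_c)
    se_cost = pd.Series(se_o[:lik.kc], index=names_c)
    coef_qaly = pd.Series(beta_o[lik.kc:], index=names_q)
    se_qaly = pd.Series(se_o[lik.kc:], index=names_q)
    rescale = np.diag([lik.sc, lik.sq])
    loglike = -nll - lik.n * (np.log(lik.sc) + np.log(lik.sq))
    return ModelFit(
        variant="joint",
        coef_cost=coef_cost, se_cost=se_cost, coef_qaly=coef_qaly, se_qaly=se_qaly,
        incremental_cost=float(coef_cost.get("arm_intervention", np.nan)),
        incremental_cost_se=float(se_cost.get("arm_intervention", np.nan)),
        incremental_qaly=float(coef_qaly.get("arm_intervention", np.nan)),
        incremental_qaly_se=float(se_qaly.get("arm_intervention", np.nan)),
        sigma_e=rescale @ sigma_e @ rescale, sigma_u=rescale @ sigma_u @ rescale,
        loglike=float(loglike), converged=bool(res.success), n=lik.n,
        extra={"theta": theta, "diagonal_ranef": diagonal_ranef},
    )


def fit_sur(df: pd.DataFrame, spec: CovariateSpec | None = None, n_gls_steps: int = 2) -> ModelFit:
    """Seemingly unrelated regression: correlated residuals, no random effects.

    With identical regressors in both equations, GLS collapses to
    equation-by-equation least squares for any residual covariance — the
    classical SUR identity, used as an internal oracle in the tests.
    """
    spec = spec or CovariateSpec()
    xc, xq, yc, yq, names_c, names_q = _design(df, spec)
    n = len(yc)
    sc = yc.std() or 1.0
    sq = yq.std() or 1.0
    yc = yc / sc
    yq = yq / sq
    beta_c = np.linalg.lstsq(xc, yc, rcond=None)[0]
    beta_q = np.linalg.lstsq(xq, yq, rcond=None)[0]
    for _ in range(n_gls_steps):
        resid = np.column_stack([yc - xc @ beta_c, yq - xq @ beta_q])
        sigma = resid.T @ resid / n
        ainv = np.linalg.inv(sigma)
        kc, kq = xc.shape[1], xq.shape[1]
        s = np.zeros((kc + kq, kc + kq))
        s[:kc, :kc] = ainv[0, 0] * (xc.T @ xc)
        s[:kc, kc:] = ainv[0, 1] * (xc.T @ xq)
        s[kc:, :kc] = ainv[1, 0] * (xq.T @ xc)
        s[kc:, kc:] = ainv[1, 1] * (xq.T @ xq)
        r = np.concatenate([ainv[0, 0] * xc.T @ yc + ainv[0, 1] * xc.T @ yq,
                            ainv[1, 0] * xq.T @ yc + ainv[1, 1] * xq.T @ yq])
        beta = np.linalg.solve(s, r)
        beta_c, beta_q = beta[:kc], beta[kc:]
    cov_beta = np.linalg.inv(s)
    se = np.sqrt(np.diag(cov_beta))
    resid = np.column_stack([yc - xc @ beta_c, yq - xq @ beta_q])
    sigma = resid.T @ resid / n
    sign, ld = np.linalg.slogdet(sigma)
    quad = float(np.einsum("ab,na,nb->", np.linalg.inv(sigma), resid, resid))
    loglike = -0.5 * (n * ld + quad + 2 * n * np.log(2 * np.pi)) - n * (np.log(sc) + np.log(sq))
    coef_cost = pd.Series(beta_c * sc, index=names_c)
    se_cost = pd.Series(se[:kc] * sc, index=names_c)
    coef_qaly = pd.Series(beta_q * sq, index=names_q)
    se_qaly = pd.Series(se[kc:] * sq, index=names_q)
    rescale = np.diag([sc, sq])
    return ModelFit(
        variant="sur",
        coef_cost=coef_cost, se_cost=se_cost, coef_qaly=coef_qaly, se_qaly=se_qaly,
        incremental_cost=float(coef_cost.get("arm_intervention", np.nan)),
        incremental_cost_se=float(se_cost.get("arm_intervention", np.nan)),
        incremental_qaly=float(coef_qaly.get("arm_intervention", np.nan)),
        incremental_qaly_se=float(se_qaly.get("arm_intervention", np.nan)),
        sigma_e=rescale @ sigma @ rescale, sigma_u=None, loglike=float(loglike),
        converged=True, n=n,
    )


def fit_separate_lmm(df: pd.DataFrame, spec: CovariateSpec | None = None) -> ModelFit:
    """Two independent univariate mixed models (random cluster intercepts)."""
    import statsmodels.api as sm

    spec = spec or CovariateSpec()
    xc, xq, yc, yq, names_c, names_q = _design(df, spec)
    groups = df["cluster_id"].to_numpy()
    out = {}
    ll = 0.0
    converged = True
    for label, x, y, names in (("cost", xc, yc, names_c), ("qaly", xq, yq, names_q)):
        scale = y.std() or 1.0
        mod = sm.MixedLM(y / scale, x, groups=groups)
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):  # statsmodels can hit singular Hessians
            try:
                fit = mod.fit(reml=False, method=method, maxiter=200, disp=False)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
        if fit is None:
            raise np.linalg.LinAlgError(f"mixed model for {label} failed to fit")
        out[label] = (pd.Series(fit.fe_params * scale, index=names),
                      pd.Series(fit.bse_fe * scale, index=names))
        ll += fit.llf - len(y) * np.log(scale)
        converged = converged and bool(fit.converged)
    coef_cost, se_cost = out["cost"]
    coef_qaly, se_qaly = out["qaly"]
    return ModelFit(
        variant="lmm",
        coef_cost=coef_cost, se_cost=se_cost, coef_qaly=coef_qaly, se_qaly=se_qaly,
        incremental_cost=float(coef_cost["arm_intervention"]),
        incremental_cost_se=float(se_cost["arm_intervention"]),
        incremental_qaly=float(coef_qaly["arm_intervention"]),
        incremental_qaly_se=float(se_qaly["arm_intervention"]),
        sigma_e=None, sigma_u=None, loglike=float(ll), converged=converged, n=len(df),
    )


def fit_gamma_cost(df: pd.DataFrame, spec: CovariateSpec | None = None) -> ModelFit:
    """Gamma / log-link cost equation (cluster-robust GEE), Gaussian QALYs.

    The incremental cost is recovered on the CHF scale as the average
    marginal effect of the arm indicator, with a delta-method standard
    error from the robust coefficient covariance.  Non-positive costs are
    floored at 1 CHF (the gamma family requires positive outcomes).
    A degenerate outcome (no variation) yields a flagged, unconverged fit.
    """
    import statsmodels.api as sm

    spec = spec or CovariateSpec()
    xc, _, yc, _, names_c, _ = _design(df, spec)
    try:
        lmm = fit_separate_lmm(df, spec)
    except np.linalg.LinAlgError:
        lmm = None
    y = np.maximum(yc, 1.0)
    if np.ptp(y) < 1e-9 or lmm is None:
        return replace_degenerate(lmm, names_c, df)
    groups = df["cluster_id"].to_numpy()
    try:
        mod = sm.GEE(y, xc, groups=groups, family=sm.families.Gamma(sm.families.links.Log()),
                     cov_struct=sm.cov_struct.Exchangeable())
        fit = mod.fit(maxiter=100)
        params = np.asarray(fit.params)
        cov = np.asarray(fit.cov_params())
    except Exception:  # noqa: BLE001 - degenerate designs raise various numerics errors
        return replace_degenerate(lmm, names_c, df)

    arm_ix = names_c.index("arm_intervention")
    x1 = xc.copy(); x1[:, arm_ix] = 1.0
    x0 = xc.copy(); x0[:, arm_ix] = 0.0
    mu1 = np.exp(x1 @ params)
    mu0 = np.exp(x0 @ params)
    ame = float(np.mean(mu1 - mu0))
    grad = (mu1[:, None] * x1 - mu0[:, None] * x0).mean(axis=0)
    ame_se = float(np.sqrt(grad @ cov @ grad))

    fitres = ModelFit(
        variant="gamma",
        coef_cost=pd.Series(params, index=names_c),
        se_cost=pd.Series(np.sqrt(np.diag(cov)), index=names_c),
        coef_qaly=lmm.coef_qaly, se_qaly=lmm.se_qaly,
        incremental_cost=ame, incremental_cost_se=ame_se,
        incremental_qaly=lmm.incremental_qaly, incremental_qaly_se=lmm.incremental_qaly_se,
        sigma_e=None, sigma_u=None, loglike=np.nan, converged=True, n=len(df),
        extra={"cost_scale": "log-link; incremental cost is an average marginal effect"},
    )
    return fitres


def replace_degenerate(lmm: ModelFit | None, names_c, df) -> ModelFit:
    """Flagged, unconverged gamma fit for degenerate cost outcomes."""
    nanser = pd.Series(np.nan, index=names_c)
    return ModelFit(
        variant="gamma",
        coef_cost=nanser, se_cost=nanser.copy(),
        coef_qaly=lmm.coef_qaly if lmm else nanser.copy(),
        se_qaly=lmm.se_qaly if lmm else nanser.copy(),
        incremental_cost=np.nan, incremental_cost_se=np.nan,
        incremental_qaly=lmm.incremental_qaly if lmm else np.nan,
        incremental_qaly_se=lmm.incremental_qaly_se if lmm else np.nan,
        sigma_e=None, sigma_u=None, loglike=np.nan, converged=False, n=len(df),
        extra={"degenerate": True},
    )


VARIANTS = {
    "joint": fit_joint_model,
    "sur": fit_sur,
    "lmm": fit_separate_lmm,
    "gamma": fit_gamma_cost,
}


def lr_test_arm_country_interaction(df: pd.DataFrame, spec: CovariateSpec | None = None):
    """Likelihood-ratio test for arm x country interactions in both equations."""
    spec = spec or CovariateSpec()
    work = df.copy()
    added = []
    for c in ("IE", "BE", "NL"):
        col = f"arm_x_country_{c}"
        work[col] = work["arm_intervention"] * work[f"country_{c}"]
        added.append(col)
    full_spec = spec.add(added)
    reduced = fit_joint_model(work, spec)
    full = fit_joint_model(work, full_spec)
    stat = max(2.0 * (full.loglike - reduced.loglike), 0.0)
    dof = 2 * len(added)  # interactions enter the cost and the QALY equation
    p = float(stats.chi2.sf(stat, dof))
    return {"statistic": float(stat), "df": dof, "p_value": p,
            "loglike_full": full.loglike, "loglike_reduced": reduced.loglike}


@dataclass
class CEAResult:
    delta_cost: PooledEstimate
    delta_qaly: PooledEstimate
    verdict: IcerVerdict
    perspective: str
    variant: str
    n: int
    m: int
    fits: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "incremental_cost": self.delta_cost.estimate,
            "cost_ci": [self.delta_cost.ci_low, self.delta_cost.ci_high],
            "incremental_qaly": self.delta_qaly.estimate,
            "qaly_ci": [self.delta_qaly.ci_low, self.delta_qaly.ci_high],
            "icer": self.verdict.icer,
            "label": self.verdict.label,
            "perspective": self.perspective,
            "variant": self.variant,
            "n": self.n,
            "m": self.m,
        }


def run_cea(datasets: list[pd.DataFrame], variant: str = "joint",
            spec: CovariateSpec | None = None, perspective: str = "healthcare",
            keep_fits: bool = False) -> CEAResult:
    """Fit the chosen variant on each imputed dataset and pool by Rubin's rules."""
    spec = spec or CovariateSpec()
    if perspective not in ("healthcare", "societal"):
        raise ValueError("perspective must be 'healthcare' or 'societal'")
    if perspective == "societal":
        spec = replace(spec, outcome_cost="total_societal")
    fitter = VARIANTS[variant]
    costs, cost_vars, qalys, qaly_vars, fits = [], [], [], [], []
    for d in datasets:
        fit = fitter(d, spec)
        costs.append(fit.incremental_cost)
        cost_vars.append(fit.incremental_cost_se ** 2)
        qalys.append(fit.incremental_qaly)
        qaly_vars.append(fit.incremental_qaly_se ** 2)
        if keep_fits:
            fits.append(fit)
    n = len(datasets[0])
    df_complete = n - len(spec.cost_covariates) - 1
    if len(datasets) == 1:  # single complete dataset: no between-imputation variance
        z = stats.norm.ppf(0.975)
        pc = PooledEstimate(costs[0], cost_vars[0], 0.0, cost_vars[0], df_complete,
                            costs[0] - z * np.sqrt(cost_vars[0]), costs[0] + z * np.sqrt(cost_vars[0]), 1)
        pq = PooledEstimate(qalys[0], qaly_vars[0], 0.0, qaly_vars[0], df_complete,
                            qalys[0] - z * np.sqrt(qaly_vars[0]), qalys[0] + z * np.sqrt(qaly_vars[0]), 1)
    else:
        pc = rubin_pool(costs, cost_vars, df_complete=df_complete)
        pq = rubin_pool(qalys, qaly_vars, df_complete=df_complete)
    verdict = compute_icer(pc.estimate, pq.estimate)
    return CEAResult(delta_cost=pc, delta_qaly=pq, verdict=verdict, perspective=perspective,
                     variant=variant, n=n, m=len(datasets), fits=fits)
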