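"""Bivariate mixed model, SUR, robustness variants and pooling."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import trialcea as tc
from trialcea import models


@pytest.fixture(scope="module")
def tiny_spec():
    """A compact covariate spec for constructed datasets."""
    return models.CovariateSpec(
        cost_covariates=("arm_intervention", "age", "observation_time"),
        qaly_covariates=("arm_intervention", "age"),
    )


def _constructed(n_pairs=120, n_clusters=8, seed=0, delta_cost=0.0, delta_qaly=0.0,
                 cluster_sd=(0.0, 0.0)):
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    cluster = rng.integers(0, n_clusters, n)
    arm_of_cluster = {c: ("intervention" if c % 2 == 0 else "control") for c in range(n_clusters)}
    arm = np.array([arm_of_cluster[c] for c in cluster])
    age = rng.uniform(70, 95, n)
    obs_time = rng.uniform(250.0, 365.0, n)
    uc = rng.normal(0, cluster_sd[0], n_clusters)
    uq = rng.normal(0, cluster_sd[1], n_clusters)
    is_i = (arm == "intervention").astype(float)
    cost = 40000 + 300 * (age - 80) + delta_cost * is_i + uc[cluster] + rng.normal(0, 8000, n)
    qaly = 0.7 - 0.004 * (age - 80) + delta_qaly * is_i + uq[cluster] + rng.normal(0, 0.25, n)
    return pd.DataFrame({
        "cluster_id": [f"c{c}" for c in cluster], "arm": arm,
        "arm_intervention": is_i, "age": age,
        "observation_time": obs_time,
        "total_healthcare": cost, "qaly": qaly,
    })


def _mirrored(seed=1):
    """Intervention rows are exact copies of control rows: zero signal."""
    rng = np.random.default_rng(seed)
    half = pd.DataFrame({
        "cluster_id": [f"c{i % 4}" for i in range(100)],
        "age": rng.uniform(70, 95, 100),
        "observation_time": rng.uniform(250, 365, 100),
        "total_healthcare": rng.normal(40000, 9000, 100),
        "qaly": rng.normal(0.7, 0.2, 100),
    })
    a = half.copy(); a["arm"] = "control"; a["arm_intervention"] = 0.0
    b = half.copy(); b["arm"] = "intervention"; b["arm_intervention"] = 1.0
    b["cluster_id"] = b["cluster_id"] + "i"
    return pd.concat([a, b], ignore_index=True)


class TestSur:
    def test_identical_regressors_equal_ols(self, tiny_spec):
        """Classical SUR identity: same regressors -> per-equation OLS."""
        df = _constructed(seed=2)
        spec = replace(tiny_spec, qaly_covariates=tiny_spec.cost_covariates)
        fit = models.fit_sur(df, spec)
        for outcome, coefs in (("total_healthcare", fit.coef_cost), ("qaly", fit.coef_qaly)):
            x = np.column_stack([np.ones(len(df))] +
                                [df[c].to_numpy() for c in spec.cost_covariates])
            ols = np.linalg.lstsq(x, df[outcome].to_numpy(), rcond=None)[0]
            assert np.allclose(coefs.to_numpy(), ols, atol=1e-8)

    def test_no_signal_construction(self, tiny_spec):
        fit = models.fit_sur(_mirrored(), tiny_spec)
        assert fit.incremental_cost == pytest.approx(0.0, abs=1e-6)
        assert fit.incremental_qaly == pytest.approx(0.0, abs=1e-9)


class TestJoint:
    def test_no_signal_construction(self, tiny_spec):
        fit = models.fit_joint_model(_mirrored(), tiny_spec)
        assert fit.incremental_cost == pytest.approx(0.0, abs=1e-4)
        assert fit.incremental_qaly == pytest.approx(0.0, abs=1e-8)

    def test_matches_sur_in_zero_cluster_variance_limit(self, tiny_spec):
        df = _constructed(n_pairs=800, n_clusters=40, seed=3, delta_cost=-3000,
                          delta_qaly=0.03, cluster_sd=(0.0, 0.0))
        joint = models.fit_joint_model(df, tiny_spec)
        sur = models.fit_sur(df, tiny_spec)
        assert joint.sigma_u[0, 0] < 0.05 * joint.sigma_e[0, 0]
        assert joint.incremental_cost == pytest.approx(sur.incremental_cost,
                                                       abs=0.25 * abs(sur.incremental_cost_se))
        assert joint.incremental_qaly == pytest.approx(sur.incremental_qaly,
                                                       abs=0.25 * sur.incremental_qaly_se)

    def test_recovers_cluster_variance(self, tiny_spec):
        df = _constructed(n_pairs=1500, n_clusters=60, seed=4, cluster_sd=(4000.0, 0.0))
        fit = models.fit_joint_model(df, tiny_spec)
        assert np.sqrt(fit.sigma_u[0, 0]) == pytest.approx(4000.0, rel=0.5)

    def test_equivariance_constant_cost_shift(self, tiny_spec):
        """Adding a constant to every cost moves only the intercept.

        At fixed variance parameters GLS is exactly equivariant; the full
        refit (variance parameters re-optimized numerically) agrees to
        optimizer precision.
        """
        df = _constructed(seed=5, cluster_sd=(2000.0, 0.02))
        shifted = df.copy()
        shifted["total_healthcare"] = shifted["total_healthcare"] + 10000.0
        base = models.fit_joint_model(df, tiny_spec)

        # exact statement: same variance parameters, shifted data
        import pandas as pd
        theta = base.extra["theta"]
        sig_e = models._chol2(*theta[:3])
        sig_u = models._chol2(*theta[3:])
        betas = []
        for frame in (df, shifted):
            xc, xq, yc, yq, *_ = models._design(frame, tiny_spec)
            codes, _ = pd.factorize(frame["cluster_id"], sort=True)
            lik = models._JointLikelihood(xc, xq, yc, yq, codes)
            _, beta, _ = lik.gls(sig_e, sig_u)
            betas.append(beta * lik.sc)  # cost-equation scale
        arm_ix = 1  # const, arm_intervention, ...
        assert betas[1][arm_ix] == pytest.approx(betas[0][arm_ix], abs=1e-8 * abs(betas[0][arm_ix]) + 1e-8)

        fit2 = models.fit_joint_model(shifted, tiny_spec)
        assert fit2.incremental_cost == pytest.approx(base.incremental_cost, abs=3.0)
        assert (fit2.coef_cost["const"] - base.coef_cost["const"]) == pytest.approx(10000.0, rel=1e-3)

    def test_needs_two_clusters_per_arm(self, tiny_spec):
        df = _constructed(n_clusters=2, seed=6)
        with pytest.raises(ValueError):
            models.fit_joint_model(df, tiny_spec)

    def test_coefficient_direction_sanity(self, complete_analysis):
        """Nursing-home residence raises cost; baseline utility raises QALYs."""
        fit = models.fit_sur(complete_analysis)
        assert fit.coef_cost["nursing_home_baseline"] > 0
        assert fit.coef_qaly["utility_baseline"] > 0

    def test_joint_and_separate_fits_agree_within_one_se(self, complete_analysis):
        joint = models.fit_joint_model(complete_analysis)
        lmm = models.fit_separate_lmm(complete_analysis)
        sur = models.fit_sur(complete_analysis)
        for other in (lmm, sur):
            assert abs(joint.incremental_cost - other.incremental_cost) \
                <= max(joint.incremental_cost_se, other.incremental_cost_se)
            assert abs(joint.incremental_qaly - other.incremental_qaly) \
                <= max(joint.incremental_qaly_se, other.incremental_qaly_se)


class TestGamma:
    def test_marginal_effect_near_generating_delta(self, tiny_spec):
        rng = np.random.default_rng(7)
        df = _constructed(n_pairs=1500, n_clusters=40, seed=7)
        is_i = df["arm_intervention"].to_numpy()
        df["total_healthcare"] = np.exp(rng.normal(10, 0.8, len(df))) * (1 - 0.15 * is_i)
        fit = models.fit_gamma_cost(df, tiny_spec)
        true_delta = -0.15 * np.exp(10 + 0.32)
        assert fit.converged
        assert abs(fit.incremental_cost - true_delta) <= 2.0 * fit.incremental_cost_se

    def test_zero_arm_coefficient_zero_marginal_effect(self, tiny_spec):
        """Mirrored arms force the arm coefficient, hence the AME, to zero."""
        df = _mirrored(seed=8)
        df["total_healthcare"] = np.abs(df["total_healthcare"])
        fit = models.fit_gamma_cost(df, tiny_spec)
        assert fit.incremental_cost == pytest.approx(0.0, abs=1e-3)

    def test_degenerate_costs_flagged(self, tiny_spec):
        df = _constructed(seed=9)
        df["total_healthcare"] = 1000.0
        fit = models.fit_gamma_cost(df, tiny_spec)
        assert not fit.converged
        assert fit.extra.get("degenerate")


class TestLrTest:
    def test_nesting_orders_loglik(self, complete_analysis):
        out = models.lr_test_arm_country_interaction(complete_analysis)
        assert out["loglike_full"] >= out["loglike_reduced"] - 1e-6
        assert out["statistic"] >= 0.0
        assert 0.0 <= out["p_value"] <= 1.0
        assert out["df"] == 6


class TestRunCea:
    def test_identical_datasets_pool_to_single_fit(self, tiny_spec):
        df = _constructed(seed=10, delta_cost=-2000, delta_qaly=0.02)
        res = models.run_cea([df, df, df], variant="sur", spec=tiny_spec)
        single = models.fit_sur(df, tiny_spec)
        assert res.delta_cost.estimate == pytest.approx(single.incremental_cost)
        assert res.delta_cost.between_variance == pytest.approx(0.0, abs=1e-12)

    def test_societal_perspective_changes_only_cost_outcome(self, small_imputed):
        hc = models.run_cea(small_imputed, variant="sur")
        soc = models.run_cea(small_imputed, variant="sur", perspective="societal")
        assert soc.delta_qaly.estimate == pytest.approx(hc.delta_qaly.estimate)
        assert soc.delta_cost.estimate != hc.delta_cost.estimate

    def test_verdict_consistent_with_signs(self, small_imputed):
        res = models.run_cea(small_imputed, variant="sur")
        dc, dq = res.delta_cost.estimate, res.delta_qaly.estimate
        if dc < 0 and dq > 0:
            assert res.verdict.label == "dominant"

    def test_unknown_perspective_rejected(self, small_imputed):
        with pytest.raises(ValueError):
            models.run_cea(small_imputed, perspective="galactic")
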