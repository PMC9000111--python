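"""Multilevel joint-model imputation and Rubin's rules."""

import numpy as np
import pandas as pd
import pytest

import trialcea as tc
from trialcea import impute


def _toy_frame(n=300, n_clusters=10, miss_rate=0.2, seed=0, shift_by_arm=0.0):
    """Two correlated normal targets with cluster structure and MCAR holes."""
    rng = np.random.default_rng(seed)
    cluster = rng.integers(0, n_clusters, n)
    arm = np.where(cluster % 2 == 0, "control", "intervention")
    u = rng.normal(0, 1, n_clusters)
    x = rng.normal(0, 1, n)
    base = 5.0 + 0.8 * x + u[cluster]
    y1 = base + rng.normal(0, 1, n) + shift_by_arm * (arm == "intervention")
    y2 = 0.5 * base + rng.normal(0, 1, n)
    df = pd.DataFrame({"cluster_id": [f"c{c}" for c in cluster], "arm": arm,
                       "x": x, "y1": y1, "y2": y2})
    holes = rng.random(n) < miss_rate
    df.loc[holes, "y1"] = np.nan
    return df, holes


def _spec(**kw):
    defaults = dict(targets=("y1", "y2"), predictors=("x",), m=3, n_iterations=20, seed=1)
    defaults.update(kw)
    return impute.ImputationSpec(**defaults)


class TestSpecValidation:
    def test_m_and_iterations_floors(self):
        with pytest.raises(ValueError):
            _spec(m=1)
        with pytest.raises(ValueError):
            _spec(n_iterations=0)

    def test_slopes_need_covariate(self):
        with pytest.raises(ValueError):
            _spec(random_structure="intercepts_and_slopes")


class TestImputation:
    def test_no_missing_returns_identical_copies(self):
        df, _ = _toy_frame(miss_rate=0.0)
        out = impute.fit_and_impute(df, _spec())
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c[df.columns], df)

    def test_observed_cells_never_altered(self):
        df, holes = _toy_frame()
        out = impute.fit_and_impute(df, _spec())
        for c in out:
            assert np.allclose(c.loc[~holes, "y1"], df.loc[~holes, "y1"])
            assert np.allclose(c["y2"], df["y2"])

    def test_imputations_vary_only_in_missing_cells(self):
        df, holes = _toy_frame()
        a, b, _ = impute.fit_and_impute(df, _spec())
        assert not np.allclose(a.loc[holes, "y1"], b.loc[holes, "y1"])

    def test_seed_reproducibility(self):
        df, _ = _toy_frame()
        a = impute.fit_and_impute(df, _spec())
        b = impute.fit_and_impute(df, _spec())
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_mcar_mean_recovery(self):
        """Imputed-cell means track the generating mean within 3 SE."""
        devs = []
        for seed in range(6):
            df, holes = _toy_frame(n=600, miss_rate=0.2, seed=seed)
            full, _ = _toy_frame(n=600, miss_rate=0.2, seed=seed)
            out = impute.fit_and_impute(df, _spec(seed=seed))
            imputed = np.mean([c.loc[holes, "y1"].mean() for c in out])
            truth = 5.0 + 0.8 * df.loc[holes, "x"].mean()
            devs.append(imputed - truth)
        se = np.std(devs, ddof=1) / np.sqrt(len(devs))
        assert np.mean(devs) == pytest.approx(0.0, abs=3.5 * se + 0.05)

    def test_by_arm_separation(self):
        """Imputing one arm never borrows strength from the other arm's rows."""
        df, holes = _toy_frame(n=800, miss_rate=0.25, seed=3, shift_by_arm=50.0)
        out = impute.fit_and_impute(df, _spec(seed=3, by_arm=True))
        interv = df["arm"] == "intervention"
        imp_interv = np.mean([c.loc[holes & interv, "y1"].mean() for c in out])
        imp_ctrl = np.mean([c.loc[holes & ~interv, "y1"].mean() for c in out])
        assert imp_interv - imp_ctrl == pytest.approx(50.0, abs=5.0)

    def test_zero_observed_target_raises(self):
        df, _ = _toy_frame()
        df["y1"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            impute.fit_and_impute(df, _spec())

    def test_structural_zeros_written_back_as_zero(self):
        df, holes = _toy_frame()
        struct = pd.DataFrame(False, index=df.index, columns=["y1", "y2"])
        struct.loc[df.index[:20], "y1"] = True
        out = impute.fit_and_impute(df, _spec(), structural_zeros=struct)
        for c in out:
            assert (c.loc[df.index[:20], "y1"] == 0.0).all()

    def test_clip_respected(self):
        df, holes = _toy_frame(miss_rate=0.3)
        out = impute.fit_and_impute(df, _spec(clip={"y1": (4.0, 6.0)}))
        for c in out:
            assert c.loc[holes, "y1"].between(4.0, 6.0).all()

    def test_random_slopes_structure_runs(self):
        df, holes = _toy_frame()
        spec = _spec(random_structure="intercepts_and_slopes", slope_covariate="x")
        out = impute.fit_and_impute(df, spec)
        assert len(out) == 3
        assert not out[0].loc[holes, "y1"].isna().any()


class TestRubin:
    def test_hand_example(self):
        p = impute.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        assert p.estimate == 2.0
        assert p.within_variance == 1.0
        assert p.between_variance == 1.0
        assert p.total_variance == pytest.approx(1.0 + (4.0 / 3.0))

    def test_degenerate_between_variance(self):
        p = impute.rubin_pool([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert p.estimate == 2.0 and p.between_variance == 0.0
        assert p.total_variance == pytest.approx(1.0)

    def test_total_at_least_within(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            est = rng.normal(0, 1, 5)
            var = rng.uniform(0.1, 2.0, 5)
            p = impute.rubin_pool(est, var)
            assert p.total_variance >= p.within_variance
            assert p.ci_low <= p.estimate <= p.ci_high

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            impute.rubin_pool([1.0], [1.0])

    def test_barnard_rubin_df_smaller_than_classical(self):
        classical = impute.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        small_sample = impute.rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], df_complete=20)
        assert small_sample.df < classical.df


class TestMnar:
    def test_delta_zero_reproduces_mar(self):
        df, holes = _toy_frame()
        base = impute.fit_and_impute(df, _spec())
        shifted = impute.mnar_offset(base, df, ["y1"], 0.0)
        for a, b in zip(base, shifted):
            pd.testing.assert_frame_equal(a, b)

    def test_offset_moves_only_imputed_cells(self):
        df, holes = _toy_frame()
        base = impute.fit_and_impute(df, _spec())
        shifted = impute.mnar_offset(base, df, ["y1"], -0.5)
        for a, b in zip(base, shifted):
            assert np.allclose(b.loc[holes, "y1"], a.loc[holes, "y1"] - 0.5)
            assert np.allclose(b.loc[~holes, "y1"], a.loc[~holes, "y1"])

    def test_sensitivity_table_monotone_in_delta(self):
        df, holes = _toy_frame(n=500, miss_rate=0.3, seed=9)
        spec = _spec(seed=9)

        def analysis(datasets):
            return {"mean_y1": np.mean([d["y1"].mean() for d in datasets])}

        table = impute.mnar_sensitivity(lambda: impute.fit_and_impute(df, spec),
                                        analysis, [-0.5, 0.0, 0.5], ["y1"], df)
        assert table["mean_y1"].is_monotonic_increasing
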