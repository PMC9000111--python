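"""Statistical structure of the synthetic trial generator."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

import trialcea as tc
from trialcea import costing, eq5d


class TestConfigValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            tc.TrialConfig(country_weights={"CH": 0.5, "IE": 0.4})

    def test_more_clusters_than_patients_infeasible(self):
        with pytest.raises(ValueError):
            tc.TrialConfig(n_patients=50, n_clusters_intervention=30, n_clusters_control=30)

    def test_minimum_two_clusters_per_arm(self):
        with pytest.raises(ValueError):
            tc.TrialConfig(n_clusters_intervention=1)

    def test_rates_in_unit_interval(self):
        with pytest.raises(ValueError):
            tc.TrialConfig(death_hazard=1.2)
        with pytest.raises(ValueError):
            tc.MissingnessSpec(rate_utility=-0.1)
        with pytest.raises(ValueError):
            tc.MissingnessSpec(mechanism="banana")


class TestStructure:
    def test_same_seed_same_tables(self, small_config, unit_costs, ppp):
        a = tc.generate_trial(small_config, unit_costs, ppp)
        b = tc.generate_trial(small_config, unit_costs, ppp)
        pdt.assert_frame_equal(a.patients, b.patients)
        pdt.assert_frame_equal(a.utilities, b.utilities)
        pdt.assert_frame_equal(a.resource_use, b.resource_use)

    def test_different_seed_differs(self, small_config, small_trial, unit_costs, ppp):
        from dataclasses import replace
        other = tc.generate_trial(replace(small_config, seed=99), unit_costs, ppp)
        assert not other.patients["age"].equals(small_trial.patients["age"])

    def test_arm_constant_within_cluster(self, small_trial):
        assert (small_trial.patients.groupby("cluster_id")["arm"].nunique() == 1).all()

    def test_cluster_counts_per_arm(self, small_trial):
        counts = small_trial.patients.drop_duplicates("cluster_id").groupby("arm")["cluster_id"].count()
        assert counts["intervention"] == 10 and counts["control"] == 10

    def test_followup_and_death_consistency(self, small_trial):
        p = small_trial.patients
        assert p["followup_days"].between(0, 366).all()
        dead = p["death_day"].notna()
        assert (p.loc[dead, "death_day"] <= p.loc[dead, "followup_days"]).all()

    def test_no_death_no_withdrawal_full_followup(self, unit_costs, ppp):
        cfg = tc.TrialConfig(n_patients=150, n_clusters_intervention=4, n_clusters_control=4,
                             death_hazard=0.0, withdrawal_prob=0.0, seed=5)
        data = tc.generate_trial(cfg, unit_costs, ppp)
        assert (data.patients["followup_days"] == 365.0).all()
        assert data.patients["death_day"].isna().all()

    def test_eligibility_floors(self, small_trial):
        p = small_trial.patients
        assert (p["age"] >= 70).all()
        assert (p["n_drugs_baseline"] >= 5).all()
        assert (p["n_comorbidities_baseline"] >= 3).all()

    def test_assessments_stop_at_death(self, small_trial):
        p = small_trial.patients.set_index("patient_id")
        u = small_trial.utilities
        death = u["patient_id"].map(p["death_day"])
        post = u["timepoint_day"] > 0
        assert not ((post) & (u["timepoint_day"] >= death)).any()


class TestCalibration:
    def test_death_rate_and_cost_shape_near_targets(self, unit_costs, ppp):
        """Default config reproduces its calibration targets over seeds."""
        deaths, ratios, means = [], [], []
        for seed in range(3):
            cfg = tc.TrialConfig(n_patients=1200, n_clusters_intervention=27,
                                 n_clusters_control=28, seed=seed)
            d = tc.generate_trial(cfg, unit_costs, ppp)
            deaths.append(d.patients["death_day"].notna().mean())
            tot = d.truth["cost_chf"][list(costing.HEALTHCARE_CATEGORIES)].sum(axis=1)
            ratios.append(tot.mean() / tot.median())
            means.append(tot.mean())
        assert np.mean(deaths) == pytest.approx(0.191, abs=0.03)
        assert np.mean(ratios) == pytest.approx(1.8, abs=0.35)
        assert np.mean(means) == pytest.approx(44000, rel=0.12)

    def test_null_effects_give_exchangeable_arms(self, unit_costs, ppp):
        """With zero true effects, arm means differ only by sampling noise."""
        diffs_c, diffs_q = [], []
        for seed in range(6):
            cfg = tc.TrialConfig(n_patients=900, n_clusters_intervention=20,
                                 n_clusters_control=20, seed=200 + seed)
            d = tc.generate_trial(cfg, unit_costs, ppp)
            p = d.patients.set_index("patient_id")
            tot = d.truth["cost_chf"].set_index("patient_id")[
                list(costing.HEALTHCARE_CATEGORIES)].sum(axis=1)
            arm = p["arm"]
            diffs_c.append(tot[arm == "intervention"].mean() - tot[arm == "control"].mean())
            lat = d.truth["latent_utilities"]["day_183"]
            diffs_q.append(lat[arm == "intervention"].mean() - lat[arm == "control"].mean())
        # standardized mean over seeds within 3 standard errors of zero
        for diffs in (diffs_c, diffs_q):
            t = np.mean(diffs) / (np.std(diffs, ddof=1) / np.sqrt(len(diffs)))
            assert abs(t) < 3.0

    def test_cluster_level_cost_variation_matches_config(self, unit_costs, ppp):
        """Between-cluster SD of mean costs tracks cluster_sd_cost."""
        cfg = tc.TrialConfig(n_patients=6000, n_clusters_intervention=30, n_clusters_control=30,
                             cluster_sd_cost=9000.0, cost_sigma_patient=0.3, seed=17)
        d = tc.generate_trial(cfg, unit_costs, ppp)
        tot = d.truth["cost_chf"].set_index("patient_id")[
            list(costing.HEALTHCARE_CATEGORIES)].sum(axis=1)
        cl = d.patients.set_index("patient_id")["cluster_id"]
        cluster_means = tot.groupby(cl).mean()
        n_per = tot.groupby(cl).size().mean()
        within_var = tot.groupby(cl).var().mean()
        between_sd = np.sqrt(max(cluster_means.var() - within_var / n_per, 0.0))
        assert between_sd == pytest.approx(9000.0, rel=0.45)

    def test_configured_cost_effect_realized(self, unit_costs, ppp):
        """Expected arm difference in total healthcare cost hits the target."""
        diffs = []
        for seed in range(8):
            cfg = tc.TrialConfig(n_patients=2500, true_delta_cost=-8000.0, cluster_sd_cost=500.0,
                                 cost_sigma_patient=0.4, seed=300 + seed)
            d = tc.generate_trial(cfg, unit_costs, ppp)
            local = costing.price_resource_use(d.resource_use, unit_costs, d.patients)
            chf = costing.total_costs(costing.convert_ppp(local, d.patients, ppp), d.patients)
            arm = chf["patient_id"].map(d.patients.set_index("patient_id")["arm"])
            diffs.append(chf.loc[arm == "intervention", "total_healthcare"].mean()
                         - chf.loc[arm == "control", "total_healthcare"].mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(-8000.0, abs=3 * se + 500)


class TestMissingness:
    def test_zero_rates_identity(self, small_trial):
        spec = tc.MissingnessSpec(mechanism="MCAR", rate_utility=0.0, rate_cost=0.0)
        out = tc.apply_missingness(small_trial, spec, seed=1)
        pdt.assert_frame_equal(out.utilities, small_trial.utilities)
        pdt.assert_frame_equal(out.resource_use, small_trial.resource_use)

    def test_mcar_patient_level_rate(self, unit_costs, ppp):
        """Per-element MCAR at 26% yields ~26% of assessments missing."""
        cfg = tc.TrialConfig(n_patients=2000, seed=8)
        data = tc.generate_trial(cfg, unit_costs, ppp)
        spec = tc.MissingnessSpec(mechanism="MCAR", rate_utility=0.26, rate_cost=0.0)
        out = tc.apply_missingness(data, spec, seed=9)
        post = out.utilities["timepoint_day"] > 0
        frac = out.utilities.loc[post, "mobility"].isna().mean()
        assert frac == pytest.approx(0.26, abs=0.02)

    def test_mar_targets_dementia(self, unit_costs, ppp):
        """MAR deletion hits dementia patients more, across seeds."""
        gaps = []
        for seed in range(5):
            cfg = tc.TrialConfig(n_patients=1500, n_clusters_intervention=20,
                                 n_clusters_control=20, seed=400 + seed)
            data = tc.generate_trial(cfg, unit_costs, ppp)
            spec = tc.MissingnessSpec(mechanism="MAR", rate_utility=0.2, rate_cost=0.0)
            out = tc.apply_missingness(data, spec, seed=seed)
            dem = out.utilities["patient_id"].map(
                data.patients.set_index("patient_id")["dementia"])
            post = out.utilities["timepoint_day"] > 0
            miss = out.utilities["mobility"].isna()
            gaps.append(miss[post & (dem == 1)].mean() - miss[post & (dem == 0)].mean())
        t = np.mean(gaps) / (np.std(gaps, ddof=1) / np.sqrt(len(gaps)))
        assert t > 3.0  # one-sided: dementia missingness strictly higher

    def test_realized_rate_matches_request(self, small_trial):
        spec = tc.MissingnessSpec(mechanism="MAR", rate_utility=0.15, rate_cost=0.1)
        out = tc.apply_missingness(small_trial, spec, seed=3)
        post = out.utilities["timepoint_day"] > 0
        assert out.utilities.loc[post, "mobility"].isna().mean() == pytest.approx(0.15, abs=0.04)

    def test_deaths_never_deleted(self, small_trial_missing, small_trial):
        pdt.assert_series_equal(small_trial_missing.patients["death_day"],
                                small_trial.patients["death_day"])

    def test_baseline_assessments_exempt(self, small_trial_missing):
        base = small_trial_missing.utilities["timepoint_day"] <= 0
        assert small_trial_missing.utilities.loc[base, "mobility"].notna().all()

    def test_mnar_depends_on_value(self, unit_costs, ppp):
        """With a large negative MNAR offset, low utilities go missing more."""
        cfg = tc.TrialConfig(n_patients=1500, n_clusters_intervention=20,
                             n_clusters_control=20, seed=12)
        data = tc.generate_trial(cfg, unit_costs, ppp)
        spec = tc.MissingnessSpec(mechanism="MNAR", rate_utility=0.3, rate_cost=0.0,
                                  mar_weights={}, mnar_delta=-2.0)
        out = tc.apply_missingness(data, spec, seed=13)
        lv = data.utilities[["mobility", "self_care", "usual_activities",
                             "pain_discomfort", "anxiety_depression"]].to_numpy()
        score = 1 - 0.05 * (lv - 1).sum(axis=1)
        miss = out.utilities["mobility"].isna().to_numpy()
        post = (data.utilities["timepoint_day"] > 0).to_numpy()
        assert score[post & miss].mean() < score[post & ~miss].mean()
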