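import numpy as np
import pandas as pd
import pytest

import trialcea as tc
from trialcea import costing, eq5d, pipeline


@pytest.fixture(scope="session")
def toy_vs():
    return eq5d.toy_value_set()


@pytest.fixture(scope="session")
def unit_costs():
    return costing.example_unit_costs()


@pytest.fixture(scope="session")
def ppp():
    return costing.example_ppp()


@pytest.fixture(scope="session")
def small_config():
    """A reduced trial: fast enough for per-test use, same structure."""
    return tc.TrialConfig(n_patients=400, n_clusters_intervention=10, n_clusters_control=10,
                          true_delta_cost=-3500.0, true_delta_qaly=0.025, seed=7)


@pytest.fixture(scope="session")
def small_trial(small_config, unit_costs, ppp):
    return tc.generate_trial(small_config, unit_costs, ppp)


@pytest.fixture(scope="session")
def small_trial_missing(small_trial, small_config):
    return tc.apply_missingness(small_trial, small_config.missingness, seed=11)


@pytest.fixture(scope="session")
def complete_analysis(small_trial, toy_vs, unit_costs, ppp):
    """Analysis table from the complete (no-missingness) small trial."""
    wide, struct = pipeline.build_wide_table(small_trial, toy_vs, unit_costs, ppp)
    for c in pipeline.UTILITY_COLS.values():
        wide.loc[struct[c], c] = 0.0
    # withdrawal-censored assessments remain missing even in a "complete"
    # trial; fill them from the generating latent truth for oracle fits
    latent = small_trial.truth["latent_utilities"]
    for day, col in pipeline.UTILITY_COLS.items():
        holes = wide[col].isna()
        if holes.any():
            pid = wide.loc[holes, "patient_id"]
            wide.loc[holes, col] = latent.loc[pid, f"day_{day}"].to_numpy()
    return pipeline.completed_to_analysis(wide)


@pytest.fixture(scope="session")
def small_imputed(small_trial_missing, toy_vs, unit_costs, ppp):
    """m=3 imputed analysis datasets from the small trial (fast settings)."""
    wide, struct = pipeline.build_wide_table(small_trial_missing, toy_vs, unit_costs, ppp)
    spec = pipeline.default_imputation_spec(toy_vs, m=3, n_iterations=25, seed=13)
    return pipeline.impute_and_analyze(wide, struct, spec)
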