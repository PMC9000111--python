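# trialcea

Within-trial cost-effectiveness analysis (CEA) for multi-country
**cluster-randomized trials**, built for health economists analyzing
trial-collected EQ-5D-5L utilities and resource use under three
simultaneous complications: within-cluster correlation, between-country
heterogeneity, and missing data.

The package covers the whole chain:

1. **QALYs** — EQ-5D-5L profiles scored against a (pluggable) value set;
   per-patient QALYs over one year by the trapezium rule, with utility set
   to zero from the date of death.
2. **Costs** — resource-use events priced with 2018-style local unit
   costs, converted to CHF with purchasing-power parities (PPP);
   healthcare-system and societal (adds informal care) perspectives;
   intervention delivery cost on the intervention arm only.
3. **Multiple imputation** — missing per-timepoint utility scores and
   per-category costs imputed from a multivariate-normal joint model with
   cluster random effects, Gibbs-sampled separately by arm; estimates
   pooled by Rubin's rules, T = W + (1 + 1/m)·B.
4. **The main model** — a bivariate linear mixed model fitted by maximum
   likelihood: cost and QALY equations with correlated cluster random
   intercepts and correlated residuals,

       cost_i = x_i'β_c + u_{j(i),c} + e_{i,c}
       qaly_i = z_i'β_q + u_{j(i),q} + e_{i,q},   (u_c,u_q) ~ N(0,Σ_u), (e_c,e_q) ~ N(0,Σ_e)

   whose arm coefficients are the incremental cost Δ*C* and incremental
   QALY Δ*E*. Robustness variants: SUR, separate mixed models, gamma/log
   GEE for costs, arm×country likelihood-ratio test.
5. **Uncertainty** — deterministic ±30% unit-cost scenarios, and a
   combined cluster-bootstrap + probabilistic sensitivity analysis
   (Normal(1, 0.153) multipliers per cost category) pooled across imputed
   datasets into a cost-effectiveness plane with quadrant fractions.
6. **Heterogeneity & subgroups** — country-specific CEAs with local value
   sets, qualitative (chi-bar-squared, Gail–Simon form) and quantitative
   (Cochran Q) interaction tests, protocol subgroup analyses.
7. **ICER verdicts** — Δ*C*/Δ*E* with dominance labels: *dominant*
   (cheaper, more effective), *dominated*, CHF-per-QALY-gained (NE
   quadrant) or CHF-saved-per-QALY-lost (SW quadrant).

Because patient-level trial data of this kind are confidential, the
package includes a first-class **synthetic trial generator**
(`trialcea.synthetic`) whose defaults emulate the target study: 2,008
patients in 110 clusters across four countries (CH/IE/BE/NL), median age
79, 19.1% one-year mortality, right-skewed annual costs (mean ≈ 44,000,
median ≈ 24,000 CHF) in six categories, AR(1) utility trajectories at
−6/0/2/6/12 months, configurable true incremental effects, and
MCAR/MAR/MNAR missingness. Every downstream stage is validated against
it. See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
import trialcea as tc

cfg = tc.TrialConfig(n_patients=600, n_clusters_intervention=15, n_clusters_control=15,
                     true_delta_cost=-3500, true_delta_qaly=0.025, seed=1)
data = tc.generate_trial(cfg)                              # complete trial tables
miss = tc.apply_missingness(data, cfg.missingness, seed=2) # MAR holes
out = tc.run_full_cea(miss, m=3, n_iterations=50, seed=3)  # score→cost→MI→fit→pool
res = out["result"]
print(f"incremental cost: {res.delta_cost.estimate:.0f} CHF "
      f"[{res.delta_cost.ci_low:.0f}, {res.delta_cost.ci_high:.0f}]")
print(f"incremental QALY: {res.delta_qaly.estimate:.3f} "
      f"[{res.delta_qaly.ci_low:.3f}, {res.delta_qaly.ci_high:.3f}]")
print("verdict:", res.verdict.label)
```

prints

```
incremental cost: -6336 CHF [-15470, 2799]
incremental QALY: 0.044 [-0.002, 0.089]
verdict: dominant
```

The intervention arm of this 600-patient synthetic trial is estimated to
save about CHF 6,300 per patient and gain 0.044 QALYs — both intervals
cross the configured truths (−3,500 and 0.025); the wide intervals
reflect the small sample and the cluster design. The point estimate lies
in the lower-right (dominant) quadrant of the cost-effectiveness plane,
so no finite ICER is reported.

The same chain runs from the shell (`trialcea` console script), reading
and writing plain CSV/JSON:

```bash
trialcea simulate --seed 1 --out trial/                 # patients/utilities/resource_use CSVs
trialcea fit --trial-dir trial/ --variant joint --m 5 --seed 1 --out result.json
trialcea bootstrap --trial-dir trial/ --b 1000 --m 5 --seed 1 --out-dir psa/
trialcea subgroups --trial-dir trial/ --seed 1 --out subgroups.csv
```

`bootstrap` writes `ce_plane.csv`, `ce_plane.png`, `quadrants.json` and
the ±30% `sa_table.csv`. Subcommands accept `--perspective
{healthcare,societal}` and `--variant {joint,sur,lmm,gamma}` where
applicable; `simulate --config config.yaml` takes generator overrides
under a top-level `trial:` key (field names as in `TrialConfig`, with a
nested `missingness:` block).

## Data interfaces

- `patients.csv` — one row per patient: `patient_id, cluster_id, country,
  arm, age, female, education, smoker, alcohol_units_week,
  n_drugs_baseline, n_comorbidities_baseline, n_hosp_prior_year,
  housebound, nursing_home_baseline, dementia, index_ward,
  index_duration, followup_days, death_day`.
- `utilities.csv` — long format: `patient_id, timepoint_day` (−183 … 365)
  and the five EQ-5D-5L dimension levels (1–5, blank when missing).
- `resource_use.csv` — long format: `patient_id, category, item_code,
  quantity, event_day`; a blank quantity marks that patient's category as
  missing.
- Value sets: CSV with `state` (5-digit profile) and `utility`. Licensed
  crosswalk tariffs are not redistributable; a deterministic additive toy
  set (utility = 1 − 0.05·Σ(level−1)) ships for tests.
- Pricing: `unit_costs.csv` (`country, category, item_code, unit_cost,
  currency`; staff wages appear as `intervention_delivery` item codes,
  informal-care hourly rates as the `informal_care` category) and
  `ppp.csv` (`country, factor`, CH = 1). A self-consistent fictitious
  pack is built in (`example_unit_costs()`, `example_ppp()`).

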