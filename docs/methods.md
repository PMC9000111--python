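# Methods

`trialcea` implements a within-trial cost-effectiveness analysis (CEA) for
multi-country cluster-randomized trials, together with a synthetic trial
generator that reproduces the statistical structure such an analysis must
handle: cluster-level correlation, between-country heterogeneity, heavy
right-skew in annual costs, one-year mortality around 19%, and incomplete
utility and cost records. This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic validation does
and does not establish.

## Outcomes

**QALYs.** Health status is measured with the EQ-5D-5L instrument (five
dimensions, five levels; a health state is the 5-digit profile). A value
set maps each of the 3,125 profiles to a utility in [floor, 1], where the
floor may be negative; utilities below 0 are retained, not truncated. The
per-patient QALY over the one-year horizon is the area under the
piecewise-linear utility curve through the scheduled assessments (baseline
and months 2, 6, 12), divided by 365.25 days/year. For patients who die,
utility is set to zero from the date of death: the curve descends linearly
from the last pre-death assessment to zero at the death day and stays at
zero to the horizon. The 6-months-before-baseline recall assessment is
never integrated; it enters only as a regression covariate. For patients
censored alive before the horizon the area runs to the end of follow-up
(configurable); after multiple imputation this case disappears because all
scheduled assessments are completed.

Licensed national crosswalk tariffs cannot be redistributed, so value sets
load from user CSVs (`state,utility`); a deterministic additive toy set,
utility = 1 − 0.05·Σ(level−1), ships for tests and synthetic runs.

**Costs.** Resource-use events in six medical categories
(hospitalization, rehabilitation, medical visits, nursing visits at home,
nursing-home care, drugs) are priced with 2018-style local unit costs and
converted to Swiss francs with purchasing-power-parity (PPP) factors
anchored at CH = 1. The healthcare-system perspective sums the six
categories plus the intervention delivery cost (trial-observed staff
minutes priced at role wages plus a per-patient software amortization,
intervention arm only); the societal perspective adds informal care hours
valued at the country's average wage. Unit costs, wages and PPP factors
are configuration data, never hard-coded; a self-consistent fictitious
pack ships for tests (clearly synthetic). Events dated after a patient's
follow-up end are excluded (within-trial horizon); discounting is not
applied over a one-year horizon.

## The main model

Costs and QALYs are analyzed simultaneously with a bivariate linear mixed
model: per patient i in cluster j,

    cost_i = x_i' β_c + u_{j,c} + e_{i,c}
    qaly_i = z_i' β_q + u_{j,q} + e_{i,q}

with correlated cluster random intercepts (u_c, u_q) ~ N(0, Σ_u) and
correlated residuals (e_c, e_q) ~ N(0, Σ_e), estimated by maximum
likelihood. The arm coefficients are the incremental cost and incremental
QALY. Covariates: arm, age, sex, utility at −6 months and baseline,
numbers of drugs and comorbidities, housebound, smoking, education
dummies, nursing-home residence, dementia, prior-year hospitalizations,
ward type, index-hospitalization duration, country dummies (CH reference)
— and observation time in the cost equation only (costs accrue with
exposure; QALYs already normalize to the horizon).

The marginal covariance of a cluster of size n_j is
I⊗Σ_e + J⊗Σ_u, whose inverse and log-determinant follow in closed form
from the eigenstructure of J = 11'. Fixed effects are profiled out by
GLS, leaving a 6-parameter optimization over the two Cholesky factors
(log-diagonal parameterization, so both covariances stay PSD), run with
L-BFGS-B from fixed starting values and fixed tolerances — fits are
deterministic given the data. Standard errors come from the GLS
information matrix at the optimum. A near-singular Σ_u (|corr| > 0.999)
triggers a logged refit with diagonal random-effects structure.

Robustness variants mirror the main fit: seemingly unrelated regression
(correlated residuals, no random effects; with identical regressors it
provably equals per-equation least squares, which the tests exploit as an
oracle), two separate univariate mixed models (statsmodels `MixedLM`,
ML), and a gamma/log-link cost model. The gamma variant is fitted as a
GEE with exchangeable within-cluster correlation and cluster-robust
errors — a marginal rather than mixed formulation, chosen because the
incremental cost is recovered on the CHF scale as the average marginal
effect of the arm indicator (delta-method SE), which is a marginal
quantity. An arm×country interaction is assessed with a likelihood-ratio
test against χ² with df = 6 (three dummies in each equation).

## Missing data

Missing per-timepoint utility scores and per-category costs (never
aggregates) are multiply imputed from a multivariate normal joint model
with cluster random intercepts, fitted by Gibbs sampling separately
within each arm. Targets: the five utility scores and the six cost
categories, costs log1p-transformed. Predictors are the complete baseline
covariates plus follow-up duration and death. Conjugate updates: matrix
normal for the coefficient block, per-cluster Gaussian draws for the
random effects, inverse-Wishart (df p+2, scale 0.01·I, on standardized
data) for both covariances, and conditional-normal draws for the missing
cells grouped by missingness pattern. Defaults: m = 5 completed datasets
(m = 3 in the reduced validation runs), 100-sweep burn-in and 100 sweeps
between saved datasets — whether the stated iteration count includes
burn-in is genuinely ambiguous in practice, so both are configurable.
An optional random-slope structure (cluster slopes on centered follow-up
time, independent of the intercepts a priori) is available;
intercepts-only is the default used everywhere.

Three practical rules matter:

- Observed cells are never altered, and utility assessments scheduled on
  or after death are *structural zeros*: excluded from the imputation
  model and written back as 0, never imputed.
- Imputed utilities are clipped to the value-set range. Imputed costs are
  back-transformed with expm1 and clipped to the per-arm observed range
  of their category: a Gaussian model on the log scale of a zero-inflated,
  heavy-tailed variable occasionally produces draws whose exponential is
  orders of magnitude beyond anything observed, and a handful of such
  cells dominates Rubin's between-imputation variance. Range-restriction
  is the standard pragmatic remedy and is on by default.
- Downstream estimates are pooled by Rubin's rules, T = W + (1+1/m)B,
  with Barnard–Rubin small-sample degrees of freedom when the
  complete-data df is known.

MNAR sensitivity re-uses the MAR draws and shifts only the imputed cells
of chosen targets by a grid of offsets δ, so δ = 0 reproduces the main
analysis bit-for-bit under the same seed.

## Uncertainty

Deterministic sensitivity scales each category's costs by 0.7/1.3 in turn
and re-runs the pooled analysis (QALY side invariant by construction).
The probabilistic analysis combines a nonparametric bootstrap with
parameter uncertainty on unit costs: per replicate, clusters are resampled
with replacement stratified by arm and country (patient-level resampling
available; cluster-level is the default because randomization was at
cluster level and resampling must respect the exchangeability unit), one
multiplier per category is drawn from Normal(1, 0.153) — an sd chosen so
±30% is roughly a 95% range, linking the PSA to the deterministic
scenarios — costs are rescaled, the model refitted (warm-started from the
point fit), and (Δcost, ΔQALY) recorded. Replicates from all imputed
datasets are pooled into the cost-effectiveness plane (QALY gains to the
right, cost increases upward); failed refits are redrawn and counted, and
more than 5% failures aborts. Quadrant fractions sum to exactly 1; exact
zeros are assigned to the favourable quadrant and reported as ties.

## Heterogeneity and subgroups

Country-specific CEAs restrict to one country, re-score with the locally
relevant value set, re-impute within the subset (imputations drawn under
one valuation algorithm are not consistent with analysis under another,
which is why trial-wide imputations are not reused), and drop the country
dummies. Heterogeneity of the per-country incremental estimates is tested
two ways: a qualitative (sign-crossing) test — Q⁺ the sum of squared
standardized positive effects, Q⁻ the negative analogue, statistic
min(Q⁺,Q⁻) referred to the chi-bar-squared mixture
Σ_h C(g−1,h)(½)^{g−1} P(χ²_h > q) — and a quantitative Cochran-Q
homogeneity test against χ²(g−1). Protocol subgroups (sex, residence,
ward, age bands, drug and comorbidity counts) re-run the pooled analysis
per stratum with the axis covariate dropped from its own fit (it is
constant there); strata with fewer than two clusters per arm, or singular
designs, are flagged rather than fitted.

ICER reporting: Δcost/ΔQALY is only displayed in the two trade-off
quadrants (truncated toward zero to whole CHF for tables, full precision
in JSON); cheaper-and-more-effective is *dominant*,
costlier-and-less-effective *dominated*, and a |ΔQALY| below a
configurable epsilon suppresses the ratio.

## The synthetic generator

The generator's defaults are the emulated study conditions: 2,008
patients in 54 intervention and 56 control clusters across four countries
(weights 822/346/388/452 out of 2,008 for CH/IE/BE/NL), median age 79,
44.7% female, 19.1% one-year mortality (death day uniform over the year),
6.4% censoring by withdrawal or loss to follow-up, and annual medical
costs calibrated to mean ≈ 44,000 and median ≈ 24,000 CHF (mean/median
≈ 1.8).

Costs are built from a shared patient-level lognormal frailty (σ = 0.85,
which produces the target skew), a multiplicative cluster shift whose
CHF-scale sd is `cluster_sd_cost` (default 4,000), a covariate profile
(nursing-home residence, comorbidities, prior admissions, age, …)
normalized to mean 1, and per-category occurrence indicators and
lognormal noise (gamma selectable). Category CHF targets are converted to
event quantities through the local unit cost and PPP factor, so the
pricing chain reproduces them exactly and every generated pair is priced.
Utilities follow a latent AR(1) (stationary sd 0.30, lag correlation 0.75
between successive assessments) around a covariate- and cluster-shifted
mean, clipped to [0,1], and are emitted as EQ-5D-5L profiles by
stochastically rounding the implied additive decrement (mean-preserving)
and spreading it uniformly over the five dimensions. A configurable
frailty loading (default −0.3) makes high-cost patients less healthy.

True effects are injected so the *marginal* one-year contrasts equal the
configured values: the intervention multiplies category means by a common
factor chosen so the expected total healthcare difference (including the
delivery cost it must offset) is `true_delta_cost`; post-baseline latent
utilities are shifted by `true_delta_qaly` divided by a transfer factor
that accounts for the trapezium weights of the assessment schedule, death
and withdrawal truncation, and the clipping attenuation (interior
probability mass, evaluated at the shift midpoint by a short fixed-point
iteration). Empirically the realized contrasts match the configured ones
within Monte-Carlo error (e.g. 0.0230 ± 0.0012 for a configured 0.025).

Missingness is applied in a separate pass. Element-wise rates (default
0.046 per utility assessment, 0.0138 per cost category) are calibrated so
that, with censoring, ~26% of patients lack a QALY element and ~8% a cost
element. MCAR deletes uniformly; MAR passes covariates (dementia 1.2,
housebound 0.6, +0.3 per decade of age, on the logit scale) through a
logistic model whose intercept is solved so the realized rate matches the
request; MNAR adds δ times the standardized to-be-deleted value. Deaths
and follow-up are never deleted, and baseline/pre-baseline assessments
(collected in person at enrollment) are exempt.

**What the generator does not emulate:** clinical endpoints (the trial's
drug-related admissions are out of scope), per-drug pharmacology,
seasonal or policy-driven cost drift, country-specific utility
trajectories, and informal-care arm effects (informal care is
arm-neutral by default, so the societal and healthcare incremental costs
coincide in expectation). Costs accrue at an annualized rate independent
of survival time — terminal-care intensity is taken to offset shorter
exposure — so passing tests say nothing about cost–survival dependence.
Within-patient cost/utility correlation is a single frailty loading, not
estimated from any real dataset.

## Validation and problem sizes

The acceptance suite checks, at sizes chosen to keep the full run within
minutes on one CPU: (i) ICER verdicts reproduce the printed worked
examples exactly; (ii) over 25 synthetic trials at full scale (n = 2,008,
110 clusters, MAR missingness, m = 3), the Rubin-pooled 95% intervals
cover the true −3,500 CHF and 0.025 QALY effects between 90% and 99% of
the time; (iii) the trapezium QALY equals dense numerical integration to
1e-9, SUR with identical regressors equals per-equation least squares to
1e-8, the joint model collapses to SUR when cluster variance is absent,
and quadrant fractions match analytic Gaussian orthant probabilities
within two Monte-Carlo SEs; (iv) under the generator's MAR mechanism the
complete-case mean is at least twice as biased as the MI estimate, and
MNAR with δ = 0 reproduces the MAR analysis bit-identically; (v) the
qualitative and quantitative interaction tests hold their type-I error at
or below nominal over 500 null replicates; (vi) the full pipeline is
byte-identical across repeated runs with one seed (one top-level seed
spawns per-stage substreams).

## Known limitations

- The joint imputation model is Gaussian on (log-transformed) targets;
  zero-inflated categories are approximated, not modelled, and the
  observed-range clip introduces a small shrinkage toward the observed
  support.
- The gamma robustness fit is marginal (GEE), not a mixed model; its SE
  is cluster-robust rather than likelihood-based.
- Bootstrap refits use the point fit's variance parameters as starting
  values; with very small B the optimizer occasionally stops at a nearby
  local mode, which the redraw-and-count failure logic does not detect.
- Country-level and subgroup analyses at realistic sizes have few
  clusters per stratum; their SEs rely on the normal approximation and
  should be read qualitatively, as the flagging logic (min clusters,
  singular designs) enforces only hard failures.
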