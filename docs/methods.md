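# Methods

This note records the statistical model behind `qitrend`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Outcome model and standardization

The outcome model is a single ML logistic regression over all regions and
years with one free intercept per region×year cell and covariate effects
assumed constant across regions and years. Design rules are data-driven:

* **Age** enters as a restricted cubic (natural) spline of mean-centered
  age. The number of knots is k = ceil((P99 − P1)/10) clamped to [2, 4]
  (k=2 degenerates to a linear term); knots sit at the 10/50/90th
  percentiles for k=3 and the 5/35/65/95th for k=4. Percentiles are
  linear-interpolation sample quantiles, pooled over regions and years
  (the pooling level is a choice; it is recorded in `ModelDesign`).
* **Comorbidity** (Charlson index at study entry, deliberately frozen at
  entry so that intervention-induced changes in comorbidity or its
  documentation cannot bias the adjustment) uses L dummies for the values
  0..L−1 plus a linear tail max(x−L, 0), with L the floored gender-specific
  90th percentile capped at the second-largest observed value; L=0 (pure
  linear) when only two distinct values occur; the term is dropped when
  constant. The coding has no own intercept (identifiability next to the
  cell intercepts and the gender main effect).
* **Gender-specific effects** are used only when both genders have at
  least 100 events and 100 non-events, evaluated on the pooled analysis
  population.
* Cells whose records are all events or all non-events have no finite
  intercept; they are flagged non-estimable, their rows are excluded, and
  the trend model simply treats them as missing observations.

Coefficient covariance is the cluster-robust sandwich with clusters =
subjects across years (a practice-level option exists for sensitivity
analyses). No small-sample correction is applied, so with singleton
clusters the matrix equals HC0 exactly; at realistic cluster counts the
correction factor is negligible.

Standardized prevalences average each cell's predicted probability over all
reference-sample members present in that year. Variances follow the delta
method; because the pair term is quadratic in the reference-sample size,
both averages are Monte-Carlo approximated: v̄ on a without-replacement
subject subsample, c̄ on ordered subject pairs sampled without replacement
among all n(n−1) pairs. Defaults follow the size rules n1 = min(n, 10000)
and n2 = min(floor(n/2), 20000); explicitly requested sizes cap at the
population, and when they cover it the computation is the exact
full-enumeration delta method (this is how the exactness tests work). The
variance is floored at zero before the square root, since the pair term can
push the estimate marginally negative; the event is logged.

## Trend model

The meta-regression p̂_rt = α_t + β_r + θ̃_r t + γ_rt + ε_rt uses
sum-to-zero (deviation) coding for the year effects and the region slopes,
with the last level reconstructed by the linear transform and its
covariance propagated accordingly. Within-cell variances σ̂²_rt are plugged
in; a single additive heterogeneity τ² is estimated by REML (bounded scalar
optimization; ties at the boundary resolve to τ²=0), with a
method-of-moments alternative behind `tau_method="mom"`. Region-specific
γ variances and cross-cell correlations of the p̂_rt are deliberately not
modeled. All fitted regions — intervention, controls and the reference
region — enter the Σ_r θ̃_r = 0 side condition.

The overall linear trend is the OLS slope of the α̂_t on the year index,
with the closed form θ̂ = Σ t α̂_t / Σ(t−t̄)² (valid because Σα̂_t = 0; the
weights use the years actually present). Five-year trends are
θ̂_r = 5(θ̃̂_r + θ̂) × 100 percentage points, with
Var(θ̂_r) = 25[Var(θ̃̂_r) + c'Var(α̂)c + 2c'Cov(α̂, θ̃̂_r)].

The acceleration analysis keeps the model but adds, for the intervention
region only, a hinge term (t − m)₊ with the knot m exactly at the middle of
the observation period (fractional values allowed, e.g. 4.5 for years
0..9). The hinge coefficient is the slope change Δ_KT = θ̃^L − θ̃^E, with a
Wald interval and p-value.

## Pooling, key figures, grading

Control trends are pooled by DerSimonian–Laird: fixed weights give
Cochran's Q, the moment estimator τ̂² (truncated at 0), random-effects
weights give μ̂_C, and σ̂_C = √τ̂². The z-score's Fieller set needs a
sampling variance for σ̂_C, which the moment estimator does not come with;
we use the large-sample variance of Q under the random-effects model
(Var(Q) = 2(k−1) + 4τ²(S1−S2/S1) + 2τ⁴(S2 − 2S3/S1 + S2²/S1²) with
S_m = Σw^m), giving Var(τ̂²) = Var(Q)/(S1−S2/S1)² and, by the delta method,
Var(σ̂_C) ≈ Var(τ̂²)/(4τ̂²) with τ̂² floored at 1e−8. The rule is isolated
in one function so alternatives can be swapped in.

Wald intervals for Δ̂_C and Δ̂_BW assume independence of the two estimates;
the Fieller set {ρ : (Δ̂ − ρσ̂)² ≤ 1.96²(Var Δ̂ + ρ²Var σ̂)} assumes
independence of Δ̂_C and σ̂_C (fixed effects vs. variance components). When
the quadratic's leading coefficient σ̂² − 1.96²Var(σ̂) is non-positive the
set is unbounded or a complement and is flagged degenerate; grading then
skips the z-conditions. With ~13 control regions this happens routinely —
σ̂_C is simply not precise with k=13 — and is the intended behaviour, not a
failure mode.

The verbal grading reads its table sequentially: each row's full
conjunction (trend AND z conditions) is tested in order
strong → regular → weak; a strong row failing only its z-condition does
not fall through with relaxed trend conditions. When z-conditions are
skipped (σ̂_C ≤ 0.001 or degenerate Fieller set), the trend conditions of
each row still apply in order. All inequalities are strict, as printed. A
directed difference of exactly zero grades inconclusive. Relevance limits
use the crude reference-sample prevalence of the indicator's first year;
for desired decreases the potential improvement is the distance to 0%.

## Evidence summaries and region-swap inference

S_hint averages hint points (±5/±3/±1/0) over directed indicators; S_diff
averages directed log odds ratios log[((π+Δ)/(1−π−Δ))/(π/(1−π))] on the
fraction scale, with π+Δ clamped to [1e−6, 1−1e−6] (logged) to keep
boundary indicators finite; S_|z| averages |ẑ| over all indicators with a
defined z (σ̂_C > 0), undirected ones included, undefined ones excluded and
counted.

Swap semantics are a full role exchange: the focal control is compared
against the remaining 12 controls plus the true intervention region (a
drop-the-intervention variant exists behind `swap_mode="drop"`). Relevance
limits are not recomputed per scenario — they depend only on the reference
baseline. The normal approximation is fitted to the 13 scenario values
only (observed excluded), two-sided for S_hint/S_diff and upper-tailed for
S_|z|. No multiplicity adjustment is applied for subgroup summaries.

## Synthetic-data generator

The generator emulates an insurance claims panel: ~15 regions (1
intervention, 13 controls, 1 reference pool), ten annual cross-sections,
per-subject covariates (age advancing one year per year, fixed gender and
entry comorbidity, an area-level deprivation score shared by blocks of
subjects), annual exit churn with replacement entrants, movers between
analysis regions, and an optional family-doctor-contract flag.

Ground truth is defined on the estimand scale: the target standardized
prevalence trajectory is p*_rt = b_r + g_t + s_r(t − t̄) with region
baselines b_r, a common profile g_t of arbitrary shape (linear,
change-point, structural break presets) and per-year on-top slopes s_r
drawn N(0, (σ_C/500)²), the intervention optionally shifted. The
region×year intercept is then solved numerically so that the
reference-standardized prevalence equals p*_rt exactly; the true five-year
trend 500(s_r + slope_OLS(g)) pp is therefore exact rather than a
first-order logit approximation, and recovery tests are limited only by
sampling noise. Regions receive different age distributions by
construction, creating exactly the confounding the standardization step
must remove.

Defaults are desk-scale: 2,000 subjects per region and a 4,000-subject
reference pool (the study regions hold tens of thousands of insurees), and
deprivation areas of 500 subjects — at these region sizes the study-scale
block of ~4,500 would make the score region-constant and collinear with
the cell intercepts. σ_C defaults to 1 pp per five years, a mid-range
value for the between-region spread the method is designed around. The
generator does not emulate ICD-coded morbidity, realistic insurance churn,
overlap between reference sample and control regions, or correlated
indicators; passing tests therefore demonstrate correctness of the
estimators under the assumed data-generating structure, not robustness to
coding artefacts in real claims data.

Evidence-stage calibration studies use `simulate_trend_estimates`, which
draws exchangeable true trends N(μ_C, σ_C²) plus estimation noise directly
at the trend stage. Since all upstream stages treat regions symmetrically,
exchangeability there is precisely the null hypothesis of the region-swap
test; this makes hundreds of calibration replicates affordable.

## Numerical choices and problem sizes

* REML optimization: bounded Brent on τ² ∈ [0, 10·scale], xatol 1e−14.
* GLM: statsmodels IRLS, max 200 iterations, tol 1e−8; coefficients with
  |β̂| > 30 are treated as separation.
* Negative variances arising from MC noise or covariance round-off are
  floored at zero and logged.
* Recovery tests run one full pipeline at 15 regions × 2,000 subjects ×
  10 years (≈320k records, ~165 parameters); calibration studies use 200+
  replicates at the trend stage. These sizes were chosen to make the whole
  suite runnable on a laptop in minutes while leaving the statistical
  conclusions stable.

## Known limitations

* Var(σ̂_C) is a large-sample approximation evaluated at the estimates;
  with 13 regions the Fieller set is often degenerate (see above).
* The p-value of the region-swap test relies on a normal approximation to
  13 placebo values; its calibration is approximate (verified by
  simulation at KS-test coarseness, not exact).
* Cross-indicator correlation is not modeled anywhere; evidence p-values
  treat the indicator set as given.
* Family-contract exclusions remove flagged record-years, not whole
  subjects; the alternative reading (remove the subject entirely) would
  shrink denominators further but is not implemented.
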