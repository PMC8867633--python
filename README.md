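# qitrend

Evaluating a region-based integrated-care model is hard because nothing is
randomized: one intervention region must be compared with a handful of
structurally similar control regions, populations differ and drift, global
time trends and administrative rule changes move every region at once, and
regional prevalence trends vary even without any intervention. `qitrend`
implements a complete statistical pipeline for this setting, aimed at
biostatisticians and health-services researchers who evaluate claims-based
quality indicators (binary events in annual denominator populations) across
an intervention region, ~13 control regions, and a population reference
sample.

## The method

For one indicator with subject-year outcomes Y_it the pipeline runs five
steps:

1. **Standardized prevalences.** One logistic regression over all regions
   and years,

   logit P(Y_it = 1) = α_{r(i,t),t} + β_gender·1{gender_i=1}
   + β^g_gisd·gisd_it + f^g_age(age_it) + f^g_comorb(comorb_i),

   with a free intercept per region×year cell, restricted-cubic-spline age
   effects (2–4 knots, data-driven), a dummy-plus-linear-tail comorbidity
   coding, and gender-specific covariate effects where both genders have
   ≥100 events and non-events. Each cell's prediction rule is averaged over
   the reference sample of that year: p̂_rt = |S_t|⁻¹ Σ_{i∈S_t} Λ(α̂_rt + x_i'β̂).
   Standard errors use the delta method with the subject-clustered sandwich
   covariance, Monte-Carlo approximated over subject and subject-pair
   subsamples (exact when the subsamples cover the population).

2. **On-top trends.** A weighted meta-regression
   p̂_rt = α_t + β_r + θ̃_r·t + γ_rt + ε_rt with Σ_t α_t = 0, Σ_r θ̃_r = 0,
   known within-cell variances σ̂²_rt and REML heterogeneity τ², separates
   each region's linear trend θ̃_r from the common (possibly nonlinear)
   profile α_t. Five-year trends θ̂_r = 5(θ̃̂_r + θ̂) add back the overall
   OLS slope θ̂ of α_t and are reported in percentage points.

3. **Pooling.** DerSimonian–Laird random-effects pooling of the control
   trends yields the mean μ̂_C and between-region SD σ̂_C of true control
   trends.

4. **Key figures.** Δ̂_C = θ̂_KT − μ̂_C (Wald CI), ẑ = Δ̂_C/σ̂_C (Fieller CI,
   treating numerator and denominator as independent) and
   Δ̂_BW = θ̂_KT − θ̂_BW.

5. **Verbal grading.** The directed difference is compared with a relevance
   limit (10% of the potential improvement from the reference-sample
   baseline prevalence, min 0.1 pp) and graded sequentially into
   strong/regular/weak positive or negative hints or "inconclusive";
   z-conditions apply only when σ̂_C > 0.001 and the Fieller set is proper.

Across indicators, summary statistics (hint points, mean directed log odds
ratio, mean |z|) are compared against 13 placebo configurations in which
each control region in turn takes over the focal role ("region swap"); a
normal approximation to the 13 scenario values yields a p-value.

A synthetic-data generator produces panels with this exact structure —
entry/exit churn, movers, confounders including an area-level deprivation
score, arbitrary common time profiles (change points, structural breaks) —
with known ground-truth trends for recovery tests.

## Worked example

```python
import qitrend as q

cfg = q.scenario_presets(
    "intervention_effect", seed=3,
    subjects_per_region=400, reference_subjects=1000,
    base_prevalence=0.8, delta_intervention=6.0, sigma_C_true=0.5,
)
panel, truth = q.generate_panel(cfg)
res = q.run_indicator(panel)
```

prints (via the summary fields of `res`):

```
baseline prevalence (reference sample, year 0): 79.3%
relevance limit l_rel:                          2.07 pp
theta_KT  (five-year trend, intervention):      7.47 pp
mu_C      (pooled control mean):                0.82 pp
sigma_C   (between-region SD of control trends): 0.30 pp
Delta_C = theta_KT - mu_C:                      6.66 (95% CI 4.56 to 8.75, p=4.7e-10)
z = Delta_C / sigma_C:                          22.49
Delta_BW = theta_KT - theta_BW:                 5.93
verbal grade:                                   strong_positive
(injected true excess five-year trend:          5.64 pp)
```

The intervention region gains 7.47 percentage points per five years while
the controls average 0.82; the excess of 6.66 pp clears the 2.07 pp
relevance limit with a lower confidence bound above half the limit, and the
z-score shows the trend is far outside the natural variation of control
trends — a strong positive hint, consistent with the injected true excess
of 5.64 pp.

The same chain is available from the shell:

```
qitrend simulate --preset intervention_effect --seed 3 --out panel.csv --truth truth.json
qitrend analyze  --panel panel.csv --out-dir run/
qitrend plot     --run-dir run/
```

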