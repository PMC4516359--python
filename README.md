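# miproj

Two-scenario projection of first myocardial infarction (MI) incidence for a
regional population, separating the effect of demographic ageing from the
effect of changing risk-factor prevalences.

Morbidity forecasts often apply today's age- and sex-specific incidence to
tomorrow's population pyramid, implicitly freezing every other determinant of
risk. For strongly risk-factor-driven diseases such as MI that assumption can
reverse the sign of the forecast: falling hypertension, smoking and lipid
levels can more than offset the extra cases an older population generates.
`miproj` implements this comparison for epidemiologists working with repeated
population-based cohort waves (e.g. two examination waves roughly a decade
apart) and statistical-office population data.

## Model

For participant *i* with covariate vector
*x*ᵢ = (sex, age, hypertension, diabetes, current smoking, waist
circumference, TG, HDL, LDL) and follow-up time *t*ᵢ (5 years by design),
incident first-MI counts follow a Poisson rate model with log link:

    y_i ~ Poisson(t_i · exp(β₀ + βᵀ x_i))

fitted by Newton–Raphson (IRLS) with the inverse Fisher information as the
coefficient covariance. Incident cases are self-reported MI between waves or
death with a qualifying ICD-10 primary cause (I21.9, I24.9, I25.0, I25.1,
I25.9, I28.8; I25.9 is treated as an imprecisely coded MI). The measured
factors can enter continuously (default) or as the conventional 0/1 flags
(WC ≥ 94/80 cm m/f, TG > 1.7, HDL < 1.0/1.3 m/f, LDL > 3.0 mmol/l).

Projection: per sex × 5-year age band *g* (twelve bands, 20–79), the annual
incidence is the plug-in rate exp(β̂₀ + β̂ᵀx̄_g) at the band's mean covariate
vector (age at the band midpoint). Expected cases in year *Y* are
Σ_g N_g(Y) · λ̂_g with N_g(Y) the population pyramid. Two scenarios are
compared against the base year:

* **constant prevalence** — wave-1 covariates on both pyramids (pure
  demographic effect);
* **trend prevalence** — wave-2 covariates on the horizon-year pyramid
  (demography + observed prevalence trends).

Delta-method confidence intervals propagate the coefficient covariance
through the totals on the log scale; a parametric bootstrap is available as
a sensitivity check. Between-wave prevalence changes are reported after
direct age-sex standardization to the base-year pyramid.

Because real two-wave cohort data are not redistributable, the package ships
a first-class synthetic generator (`miproj.synthetic`) that emulates the
study conditions: stratified waves of 3,377 / 4,010 participants, published
per-sex prevalences and coefficient values as generating truth, events drawn
from the log-linear intensity, and an ageing population pyramid.

## Worked example

```sh
cat > config.yaml <<'YAML'
inputs:
  wave1: {synthetic: default}
  wave2: {synthetic: default}
  pyramid_base: {synthetic: default}
  pyramid_horizon: {synthetic: default}
seed: 1
cutoffs: {hdl_female: 1.3}
YAML
miproj run --config config.yaml --out out
```

prints (and writes to `out/summary.txt`):

```
Projected incident first-MI cases
==================================
constant_prevalence  2006  male      1205.3  (95% CI 791.6-1835.2)
constant_prevalence  2006  female     615.6  (95% CI 349.1-1085.7)
constant_prevalence  2017  male      1348.5  (95% CI 895.2-2031.2)
constant_prevalence  2017  female     698.4  (95% CI 402.4-1212.2)
trend_prevalence     2017  male       870.4  (95% CI 489.9-1546.4)
trend_prevalence     2017  female     611.0  (95% CI 328.4-1136.8)

Relative change vs base year (%)
constant_prevalence  male   +11.9%
constant_prevalence  female +13.4%
trend_prevalence     male   -27.8%
trend_prevalence     female -0.7%

Model: n=3377, events=55
```

Reading: with prevalences frozen at wave-1 levels, the older 2017 pyramid
alone would raise male incident cases by ~12%; plugging in the lower wave-2
prevalences instead turns the male projection into a 28% decline — the
prevalence trend more than offsets the demographic effect. (Numbers are for
the synthetic cohort drawn with seed 1; the model is fitted on 3,377
eligible participants with 55 incident events, so scenario contrasts carry
substantial sampling noise at this cohort size, visible in the wide CIs.)
`out/` also contains the full coefficient table (`model_summary.csv`),
per-band incidences and projections, the exclusion cascade tally, the
standardized prevalence changes and a provenance block.

The same flow is scriptable: see `miproj.pipeline.run_pipeline`, or use the
estimator classes directly (`RiskFactorCoder` → `PoissonGLM` →
`group_incidence` → `project_cases`).

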