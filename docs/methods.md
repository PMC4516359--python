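# Methods

## The estimation and projection procedure

The package chains five steps.

1. **Cohort preparation.** Participants are excluded in a fixed order —
   prior or unknown MI history, any missing model covariate (complete-case
   analysis, no imputation of covariates), age above 80, no usable follow-up
   (lost, and optionally deaths without a certified cause) — with one tally
   counter per rule so the cascade is auditable. Incident first MI is a
   between-wave self-report or a death whose primary ICD-10 cause is one of
   I21.9, I24.9, I25.0, I25.1, I25.9, I28.8. Treating I25.9 (chronic
   ischaemic heart disease) as MI is a deliberate imputation of an
   imprecisely certified cause; it is logged whenever it fires, and the code
   set is configurable. Deaths with a known non-MI cause are kept as
   observed non-cases over the full interval; no person-time censoring
   adjustment is made. This mirrors the cohort design the package targets
   and slightly understates rates when deaths occur early in the interval —
   a documented simplification.

2. **Covariate coding.** Nine terms in fixed order: sex (female = 1), age in
   years (continuous), hypertension, diabetes and current-smoker indicators
   (former and never smokers both code 0), and WC/TG/HDL/LDL either as raw
   measurements (`continuous`, default) or as cutoff flags (`binary`). The
   cutoff conventions are WC ≥ 94 cm (m) / ≥ 80 cm (f), TG > 1.7 mmol/l,
   HDL < 1.0 (m) / < 1.3 (f) mmol/l, LDL > 3.0 mmol/l, with the inequality
   directions exactly as stated. The female HDL threshold is genuinely
   ambiguous in the source descriptives (1.2 vs 1.3 mmol/l); both are
   supported, 1.3 is the default, and building cutoffs from a config without
   an explicit choice warns rather than silently resolving. Whether the
   measured factors entered the original analysis continuously or as flags
   is not documented; the small published WC coefficient (0.007) is only
   consistent with per-unit coding, hence the continuous default.

3. **Poisson fit.** Newton–Raphson on the Poisson log-likelihood with a
   log-exposure offset (all participants contribute t = 5 years; handling
   exposure as an offset was chosen for generality — rescaling exposure
   shifts only the intercept). Starting values are the closed-form
   intercept-only solution with zero slopes; iterations are damped by step
   halving and stop when every score coordinate is below 1e−8 or the
   relative log-likelihood change is below 1e−10, capped at 100 iterations
   (non-convergence raises, with the likelihood trace attached). The
   covariance is the inverse Fisher information at the optimum; Wald SEs,
   95% intervals and p-values follow. Rank-deficient designs and separation
   (a binary covariate level with zero events) are rejected up front with
   the covariate named. The intercept is always estimated and reported even
   though coefficient tables in this literature often omit it — without it
   absolute rates cannot be reconstructed.

4. **Group incidence and projection.** The default prediction is the
   plug-in at the group mean: annual incidence per sex × band =
   exp(β̂₀ + β̂ᵀx̄_g), with age represented by the band midpoint (how age
   entered the original group step is undocumented; the midpoint is the
   neutral choice) and the annual number of incident cases treated as
   constant across ages within a band (the 5-year expected count is divided
   by 5; no within-interval hazard refinement). Because the exponential is
   convex, the plug-in underestimates the exact group-average rate (Jensen
   gap); the exact `individual_average` mode is provided when records are
   available, and the gap is asserted (plug-in < individual average) in the
   tests rather than hidden. Empty bands borrow the nearest band's
   covariates with a warning. Projected cases are linear in the pyramid;
   pyramid cells above age 79 are dropped with a warning, so all projections
   deliberately understate the 80+ burden.

5. **Uncertainty and comparison.** The original description says only
   "asymptotic confidence intervals"; the package's decision is the delta
   method on the log of each projected total (gradient Σ_g N_g λ_g d_g
   through the coefficient covariance, interval exponentiated so bounds stay
   positive), with pyramids and prevalences treated as fixed. A parametric
   bootstrap (coefficients resampled from their asymptotic normal) is
   available behind `--ci-method bootstrap` as a sensitivity check. One
   published female interval in this literature is not centred on its point
   estimate and cannot be reverse-engineered; it is not imitated. Scenario
   changes are 100·(alt − ref)/ref, held at full precision and rounded to
   one decimal only in rendered summaries. For the constant-prevalence
   scenario the wave-1 prevalences are pushed through the model onto both
   pyramids (rather than applying observed crude incidences directly), so
   both scenarios differ only in the covariate vector — the cleaner
   counterfactual contrast.

## Synthetic study conditions

The generator emulates a two-wave stratified cohort design with no external
data. Defaults (all overridable through `WaveSpec`/`TrueModel` or YAML):

* **Waves.** n = 3,377 and 4,010 (the analysed sizes of the cohorts the
  design emulates), ages 20–79, equal sampling weight per 5-year band
  within sex, male share 1632/3377, follow-up 5 years.
* **Factor levels.** Per-sex published descriptives serve as band-averaged
  anchors (e.g. male hypertension 63.60%, male WC 95.86 ± 11.5 cm). Since
  age-specific prevalences are unpublished, each binary factor gets a
  logistic age gradient (log-odds per band: hypertension +0.45, diabetes
  +0.55, smoking −0.30) and each measurement a linear mean gradient (WC
  +1.2 cm, TG +0.04, HDL 0, LDL +0.08 mmol/l per band), calibrated by root
  finding so the band average reproduces the anchor exactly. Measurements
  are independent truncated-at-zero normals given (sex, band); an arbitrary
  joint distribution is not modelled.
* **Truth.** The published nine-coefficient column is the generating truth;
  the intercept (unpublished) is calibrated analytically — using exact
  truncated-normal moment-generating functions — so the population-average
  5-year event rate equals the observed 67/3377.
* **Events.** P(event) = 1 − exp(−e^η·t/5) with η the 5-year log-rate: the
  exponential-probability bridge that makes the generator exactly
  consistent with the fitted Poisson rate model at low rates. At the oldest
  bands 5-year risks reach ~0.15–0.25, where the bridge mildly attenuates
  fitted slopes (a warning fires if any stratum's event probability exceeds
  0.5). Event records split into certified deaths (fraction 33/67, cause
  sampled from the six qualifying codes with acute-MI codes dominating) and
  self-reports.
* **Trend wave.** Wave 2 = wave 1 with per-sex multipliers equal to the
  published second-to-first-wave ratios (e.g. male hypertension ×0.766);
  prevalences are clipped to [0,1] with a warning if a multiplier overshoots.
* **Pyramids.** Gaussian band-shape over band indices; base year: total
  1.2 M, peak at band 5, spread 3.4, male share 0.49. Horizon year: total
  −5%, peak shifted +0.6 bands. The shift was chosen by analytic plug-in
  arithmetic under the true model so the pure-demography scenario yields
  ≈ +11%, matching the direction and size of the regional demographic
  effect the package is designed to study. Under these defaults the female
  trend scenario comes out near zero rather than clearly negative: the
  published female decline depends on age-specific prevalence shifts that
  are not public, so per-sex uniform multipliers cannot reproduce it — a
  known limitation of the emulation, not of the method.
* **Randomness.** Everything flows from one seeded `numpy` generator with a
  fixed draw order, so identical (spec, model, seed) give identical tables.

What passing tests on these conditions show: the estimator recovers known
coefficients with correct Wald coverage, the projection arithmetic is exact
and monotone where it must be, and the full pipeline recovers analytically
known scenario changes within Monte-Carlo tolerance. What they do not show:
robustness to covariate measurement error, informative loss to follow-up,
non-response, correlated risk factors, or real secular demographic detail —
none of which the generator emulates.

## Problem sizes and numerical choices

The test suite uses a single n = 200,000 cohort for large-sample recovery,
100 replicates at n = 20,000 for CI coverage, 200 fixed-design Poisson
replicates for bias/coverage of the fitter, 30 pipeline replicates at
n = 8,000 per wave for end-to-end recovery, and dense 2-D likelihood grids
(step 1e−4 after coarse centring) as the independent oracle for the
optimiser; `statsmodels` serves as a second, independent cross-check of
coefficients and covariance. Apportionment of pyramid totals to cells uses
largest-remainder rounding so cell counts are integers and totals exact.
Ties and degenerate inputs: empty cohorts, all-excluded cohorts, zero-event
fits, collinear or separated designs, zero reference populations and
mismatched coding modes all raise typed validation errors naming the
offending field.

## Known limitations

* Absolute projected counts for the real region are out of scope: they
  would require the official pyramids, unpublished age-specific
  prevalences, and the unreported intercept.
* The plug-in group prediction carries Jensen bias relative to the exact
  individual average; both are implemented so the gap can be measured.
* No overdispersion correction, robust errors, or model selection — the
  nine-term specification is fixed by design.
* Prevalences and pyramids enter the CIs as fixed constants; forecast
  uncertainty in either is not modelled.
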