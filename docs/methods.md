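# Methods

## The problem

Self-reported dietary assessment (24-h recalls, FFQs) measures habitual
intake with error that is neither purely random nor independent of the truth:
people under- or over-report systematically (person-specific bias) and
flatten the intake–report relationship (intake-related bias).  In a cohort
study this error attenuates diet–disease log relative risks by a
multiplicative factor λ and reduces power through the imperfect correlation
ρ between the instrument and true usual intake.  A validation study
quantifies λ and ρ by comparing repeated self-reports against reference
measures whose errors are independent of self-report errors: recovery
biomarkers (24-h urinary nitrogen, potassium, sodium), a predictive biomarker
(urinary sucrose + fructose for total sugars), energy expenditure as a
surrogate for energy intake, and plasma concentration biomarkers for ranking
checks.

`dietval` implements this analysis end to end for a two-tool design (an
online self-administered 24-h recall and an interviewer-administered
multiple-pass recall), driven by a synthetic-data generator so that every
stage is testable without access to participant-level study data.

## Measurement-error model

All modelling is on the natural-log scale (chosen so the back-transform of a
mean log difference is a geometric-mean ratio).  For participant *i*,
occasion *j* and nutrient:

* latent usual intake: `T_i ~ N(mu_T, sigma2_T)`;
* reference: `R_ij = T_i + u_ij`, `u_ij ~ N(0, sigma2_u)`;
* tool *m* ∈ {online, interviewer}:
  `Q_ijm = beta0_m + beta1_m T_i + r_im + eps_ijm`,
  with `r_im ~ N(0, sigma2_r_m)` constant over occasions,
  `cov(r_iA, r_iB) = sigma_rAB`, and `eps_ijm ~ N(0, sigma2_eps_m)` independent.

The reference is anchored as unbiased for `T` (intercept 0, slope 1) — the
recovery-biomarker convention; without an anchor the scale of `T` is not
identified.  The anchor applies equally to the TEE reference and the sugar
predictive biomarker (their calibration to intake happens upstream, in the
derivation step); their reference error variances are estimated, not assumed
equal across nutrients.

Estimation is maximum likelihood.  Each participant's observed sub-vector of
(up to) 3 reference + 3 online + 3 interviewer log values is multivariate
normal with a structured mean and covariance; participants contribute the
marginal density of what they were observed to provide, which is the correct
treatment under missing at random and involves no imputation.  The optimizer
(L-BFGS-B with analytic gradients) works on an unconstrained
reparameterization — log variances, arctanh-scaled bias correlation — so the
implied covariance stays admissible.  Starting values come from a
method-of-moments map of orbit-averaged sample moments; on complete balanced
data this moment estimator is itself the exact MLE (the structured
covariance spans a quadratic subspace, so the likelihood equations are
linear in the pattern-averaged sample covariance), which the test suite
exploits as an independent oracle.

Degenerate (noiseless) data make the Gaussian likelihood singular; the fit
then returns the closed-form moment solution, flagged `method="moments"`.
Non-convergence is flagged on the result and never silently replaced.

Derived quantities for the mean of *k* administrations of tool *m*:

    lambda(k) = beta1 * sigma2_T / (beta1^2 sigma2_T + sigma2_r + sigma2_eps / k)
    rho(k)    = beta1 * sqrt(sigma2_T) / sqrt(beta1^2 sigma2_T + sigma2_r + sigma2_eps / k)

λ(k) increases in *k* toward `beta1 sigma2_T / (beta1^2 sigma2_T + sigma2_r)`:
repeat administration removes within-person error but not person-specific
bias.  The reported ρ is the model-implied correlation between a single
administration and `T` (a "partial" correlation in the sense that constant
biases are removed by the model); this interpretation is a documented choice.

Mean % difference: per participant, the mean of log tool values minus the
mean of log reference values over available replicates; the grand mean and
its t-based 95% CI are back-transformed as `(exp(d) − 1)·100`.

Confidence intervals for λ and ρ use the delta method on the inverse
observed information (Hessian by central differences of the analytic
gradient) by default; a participant-resampling percentile bootstrap
(seedable, default 1000 replicates) is available, and is the automatic
fallback when the information matrix is singular.  Simulation at n = 200
puts the delta CI's empirical coverage at ≈ 95% (the acceptance suite checks
91–98% over 500 replicates).

Nutrient densities (g/MJ) are formed first — self-report nutrient over
self-report energy, biomarker nutrient over TEE — and the identical model is
run on the density values.  Stratified analyses (sex, age tertiles,
BMI < 25 vs ≥ 25) are independent re-fits per stratum with a configurable
minimum stratum size (default 30).

## Biomarker derivation

* Protein = urinary nitrogen / 0.81 × nitrogen→protein ratio (default 6.25,
  overridable per record via a `nitrogen_to_protein_ratio` column, since
  food-source-specific ratios exist).
* Potassium = urinary K / 0.80; sodium = urinary Na / 0.86.
* Total sugars = `exp(a + b·ln(sucrose+fructose) + c·age + d·I[female])`.
  The published calibration's coefficients are not reproducible from public
  sources; the defaults (a = 2.26, b = 0.5, c = 0.005, d = −0.05) are
  synthetic placeholders on a realistic scale and are configuration, not a
  claim about any study.
* REE by the Weir equation, `(3.941·VO2 + 1.106·VCO2) kcal/min`, on the mean
  of the last 10 of 15 one-minute gas measurements (earlier minutes are
  equilibration); protein correction omitted; kcal→MJ at 4.184 kJ/kcal.
  TEE = (REE + AEE) / (1 − 0.10), treating the thermic effect of food as 10%
  of TEE.
* Plasma antioxidant concentrations are never converted to intakes; they
  feed the ranking (ICC) analyses only.

PABA completeness of the 24-h urine: recovery 85–110% complete, 50–<85%
adjustable, otherwise excluded; boundaries inclusive at 50, 85, 110.  The
adjustment multiplies urinary N, K and Na by `93 / recovery` ("adjust to 93%
recovery"); the exact arithmetic behind that phrase is an interpretation and
is isolated in one function.  The sugar biomarker is subject to the
50–110% exclusion but not the rescale, because its calibration is log-linear
(an analyte rescale by f changes the prediction by f^b, not f).

Exclusion conventions: "two or more missed voids" is ≥ 2; ">5% weight
change from the first appointment" is strict and excludes TEE at the
deviating visits; armband wear-time bounds are strict (< 23 h, > 25 h);
"recall within 24 h of a biomarker" is a calendar-day difference ≤ 1.

## Agreement statistics

Between-tool and plasma-vs-intake agreement use occasion-level (not
participant-averaged) values.  The two-way mixed model
`y_smo = mu + tau_m + b_s + g_sm + e_smo` has the method as a fixed effect,
a subject-by-method interaction with method-specific variance and
method-specific residual variances; it is fitted by the same structured-ML
machinery.  The absolute-agreement ICC for M fixed methods is

    ICC = sigma2_subject / (sigma2_subject + mean_m sigma2_int_m
          + mean_m sigma2_e_m + sum_m tau_m^2 / (M − 1)),

so systematic offsets between methods reduce agreement; heterogeneous
variances are combined by arithmetic mean.  For method pairs in different
units (plasma µM vs dietary mg), log values are z-standardized within method
before fitting — without a common scale, absolute agreement is undefined.
This standardization is a documented interpretation, flagged prominently:
the resulting ICC measures agreement in ranking.

Bland–Altman agreement is computed on log differences and back-transformed:
% difference `(exp(mean d) − 1)·100`, limits `exp(mean d ± 1.96·sd(d)) − 1`
with the sample SD and the conventional 1.96 multiplier (not a t quantile).
The limits therefore describe ratios of geometric means.

## Synthetic-data generator

The generator emulates the study conditions: 212 participants (60% female,
ages 18–65, weights/BMIs by sex), 3 occasions ~2 weeks apart (14 ± 2 days),
recalls 1–3 days after each biomarker collection with the second tool 2–4
days later in randomized order, and per-instrument missing-completely-at-
random record deletion (2% online, 7% interviewer, 9% biomarker — matching
first-visit cell sizes of 208/197/192).

Default truth parameters per nutrient are solved from target (λ, ρ) pairs
via `beta1 = rho^2 / lambda` and total single-day variance
`V = beta1·sigma2_T / lambda`, with `sigma2_T = 0.09` (0.04 for energy) and
intercepts matching realistic geometric means.  The protein defaults give
single-administration attenuation 0.30 (online) and 0.38 (interviewer) —
the protein-like scenario used throughout the tests.  Between-person
variances of usual log intake are not published at this granularity; the
chosen values are plausible for adult populations and are simulation
configuration, not estimates.

Raw biomarker panels are generated by inverting the derivation equations,
so derivation reproduces the intended reference intakes exactly (relative
error < 1e-9) wherever the PABA recovery is complete; collections with
recovery < 85% have their analytes scaled by `recovery/93` to emulate
under-collection.  Calorimetry series carry settling noise only in the first
5 minutes (the discarded ones), keeping the last-10-minute mean exact.  All
raw-signal noise is multiplicative, preserving positivity.

What the generator does **not** emulate: correlation of usual intakes across
nutrients (each nutrient's latent intake is drawn independently, so density
analyses exercise the code path but not a realistic nutrient–energy
correlation structure); day-of-week and seasonal effects; laboratory assay
error; informative (non-MAR) missingness; food-level composition.  Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to violations of it.

## Numerical choices and problem sizes

* Optimizer: L-BFGS-B, `ftol 1e-13`, `gtol 1e-8`, analytic gradients; rows
  grouped by missingness pattern so cost scales with distinct patterns.
* Variance floors at 1e-8 × data scale keep log-parameterized components
  finite; the degenerate (singular-likelihood) path described above handles
  exact zeros.
* Bootstrap and simulation seeds all derive from a single configured seed
  via `numpy.random.SeedSequence`; identical seeds give byte-identical
  datasets and output files.
* Test problem sizes are chosen to balance Monte-Carlo precision against
  runtime: moment-convergence checks at n = 50,000 draws, estimator
  equivalence at n = 2,000, parameter recovery over 100 studies of n = 200,
  CI calibration over 500 such studies, ICC recovery at 2,000 subjects and
  Bland–Altman calibration at 5,000 pairs.

## Known limitations

* The ρ reported here is the model-implied instrument–truth correlation;
  other definitions of "partial correlation" exist and could differ.
* The unequal-units ICC depends on the z-standardization choice; alternative
  conventions (e.g. regression-calibrated scaling) would give different
  absolute values while preserving ranking behaviour.
* The PABA adjustment arithmetic and the sugar-calibration coefficients are
  interpretations/placeholders as noted above.
* No multivariate (joint multi-nutrient) fitting, no regression calibration
  of external cohorts, and no relative-risk modelling.
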