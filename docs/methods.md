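# Methods

`loadresponse` implements a two-stage framework for deciding whether a
blood biomarker is mechanosensitive — whether its serum concentration
responds to a standardized walking stress test — and whether the size of
that response depends on the magnitude of ambulatory load. The intended
design is a crossover loading experiment: each participant walks 30
minutes under each of three load conditions (80, 100 and 120% of body
weight) on separate days, with serum sampled twice before the test (t-1,
t0) and three times after (t1, t2, t3), each sample assayed in duplicate.

## Change transforms

All inference is on changes from the same-day baseline t0. Two scales are
provided because neither absolute nor relative concentration changes are
a priori the right physiological quantity:

* **Normalized absolute change**: `(y_t - y_0) / m * 100`, where `m` is the
  marker's median t0 concentration pooled over subjects and load
  conditions. A five-point change is a change worth 5% of the typical
  resting level, which makes markers with different native units
  comparable.
* **Shifted relative change**: `(y_t - y_0) / (y_0 + c) * 100`. With
  `c = 0` this is ordinary percent change; the shift constant `c` is the
  smallest nonnegative value that caps the maximal relative change at the
  early post-test timepoints (t1, t2) at 75%, protecting against the
  instability of percent changes when a subject's baseline approaches
  zero. The closed form is `c = max(0, max{(y_t - y_0) * 100/cap - y_0})`
  over records with `y_t > y_0`.

Choices the formulas leave open, fixed as follows: the cap constrains only
increases (the responses of interest are concentration rises; decreases
are bounded below by -100% anyway); `c` is selected per marker, pooled over
subjects and loads; both the cap value and the capped timepoint set are
configurable. Duplicate wells are averaged before any transform; the
duplicate CV uses the two-point sample SD `|x1 - x2| / sqrt(2)` (divisor
n-1). Medians of even counts are midpoints. Strongly right-skewed markers
(ADAMTS-4 by default) are `log10(1+x)`-transformed before the
absolute-change transform; the relative scale always works on raw values.
The synthesis/degradation ratio CPII/C2C is computed from
duplicate-averaged values. t-1 samples are carried through descriptively
but never enter change computation.

## The individual-response model

For one marker, timepoint and scale, the change `delta_il` of subject `i`
at load code `l` (80/100/120 %BW coded -1/0/+1) is modeled as

    delta_il = alpha_i + beta_i * l + eps_il,

with `(alpha_i, beta_i)` drawn from a bivariate normal with means
`(mu_alpha, mu_beta)`, SDs `(sd_alpha, sd_beta)` and correlation `rho`,
and `eps` i.i.d. normal with SD `sd_error`. `mu_alpha`/`sd_alpha` are the
average response at 100% body weight and its inter-individual variation;
`mu_beta`/`sd_beta` the average per-load-level dose-response slope and its
variation.

Fitting is by REML, implemented in `reml.py`:

* Fixed effects are profiled out by GLS, so the optimization runs over at
  most four covariance parameters: the residual SD and the lower Cholesky
  factor of the random-effect covariance.
* Parameters are optimized on the **direct Cholesky scale** with
  nonnegativity bounds on the diagonal (L-BFGS-B), rather than a
  log-Cholesky scale: boundary solutions then land exactly at 0, which is
  what the boundary flags, the `0.0 [0.0; inf]`-style intervals, and the
  clipped likelihood-ratio statistics require. Estimates below 1e-6 of
  the data scale are reported as 0 with a boundary flag.
* The residual SD is floored at 1e-6 of the data scale, which caps the
  covariance condition number near 1e12; noise-free data that the fixed
  effects interpolate exactly are detected beforehand and returned as an
  exact boundary fit. When the residual SD collapses to its floor the
  criterion's numerical noise defeats gradient-based line searches, so
  the fit is polished with a bounded Nelder-Mead simplex; up to 5
  restarts from jittered starts guard against local optima.
* Subjects sharing a load pattern share one covariance factorization, so
  a balanced 24-subject fit costs a few milliseconds — the property that
  makes the 1000-replicate power simulations cheap.

The engine's restricted log-likelihoods and LRT statistics were verified
against lme4 (agreement to 4 decimals) and statsmodels MixedLM; the test
suite keeps both a dense-matrix brute-force REML oracle and the
statsmodels cross-check.

### Inference

* **Means**: two-sided Wald tests and symmetric CIs with a normal
  reference. At n=24 the normal reference makes the test's true size
  about 6% rather than 5% (a t reference with ~23 df would be closer to
  nominal); the normal version is kept because the framework's published
  presentation uses symmetric normal-style intervals. The null-calibration
  test asserts the [3%, 7%] band.
* **SDs**: removing a correlated random effect removes one variance *and*
  one covariance, so the boundary LRT is referenced against the 50:50
  mixture of chi-square(1) and chi-square(2) (Self–Liang-type boundary
  asymptotics); a sole random effect uses the chi-square(0):chi-square(1)
  mixture. REML likelihoods are compared only between models with
  identical fixed effects, which keeps the REML LRT valid. Statistics are
  clipped at 0.
* **SD confidence intervals** invert the same mixture test along the
  profile restricted likelihood: the interval is all SD values whose
  profile deviance stays under the mixture's 95% quantile, so 0 is inside
  exactly when the boundary test is non-significant. The upper bound is
  reported as infinity when the profile stays below the threshold over
  the searched range (200x the data scale) — "the data place no practical
  upper limit".

## Criteria gating

Criterion I passes a marker/timepoint combination when the mean response
(Ia) or the response SD (Ib) is significant at the 5% level on the
relative-change scale (the absolute scale is run as a sensitivity
analysis). Explicit overrides can remove a passing combination with a
recorded reason — the bundled worked example removes PRG-4 at t2, whose
significant *negative* mean contradicts the marker's other timepoints; a
helper flags such sign-inconsistent candidates but never applies them
automatically. Criterion II then asks, for the survivors, whether the mean
slope (IIa) or the slope SD (IIb) is significant; a marker is "suitable"
for dose-response assessment if any surviving combination passes. No
multiple-testing adjustment is applied: the framework is a screening
device and each criterion is a per-marker question; this is deliberate and
should be kept in mind when reading the gating report.

On the bundled published tables the mechanical rule admits six markers
(COMP, MMP-3, MMP-9, ADAMTS-4, IL-6, CPII — the last through an isolated
significant slope-SD); a substantive reading that discounts that isolated
variance signal lists five. Both outputs are reported.

## Marker association

Change correlations are Spearman correlations computed within each load
level and then averaged, so between-day pooling never manufactures rank
agreement; ties get midranks. Inference resamples **subjects** (keeping
each subject's full load profile intact, respecting within-subject
dependence), applies Fisher's z to the averaged correlation, and uses a
normal approximation on the z scale for the CI (back-transformed) and the
two-sided p-value; the default is 2000 bootstrap replicates with a
required seed. Slope correlations are plain Spearman correlations of the
per-subject OLS slopes of change on load code — with complete, equally
spaced loads the slope is exactly `(delta(+1) - delta(-1)) / 2`.

## Power study

`run_power_study` simulates the design (default 24 subjects, loads
-1/0/+1, 1000 replicates) from the response model, fits each replicate by
REML, and records rejections at 5%: Wald for the means, mixture-chi-square
LRT for the SDs — the same tests the analysis pipeline applies. The
reference scenario sets all four response parameters to 5 change points
with residual SD 5 or 7; the generating intercept–slope correlation is 0.
Replicates with non-converged fits are dropped and counted (a warning
fires above 5%; in practice convergence failures are absent at these
sizes).

Under this procedure the mean-response powers reproduce the published
figures closely, and so does the intercept-SD power; the slope-SD power
comes out 6–9 percentage points below the published 78%/44%. The
discrepancy is procedural, not numerical: the engine's likelihoods match
lme4 to 4 decimals, both tests are correctly sized under their nulls, and
no standard variant of the boundary test (ML instead of REML likelihoods,
independent instead of correlated random effects,
chi-square(0):chi-square(1) instead of chi-square(1):chi-square(2)
reference) reproduces both published SD powers simultaneously. The
composition used here is the one consistent with the fitted model and is
documented rather than tuned.

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions
everything else is validated against. `simulate_change_values` draws
directly from the response model. `simulate_concentration_panel` emulates
the raw data layer: per-subject baselines are lognormal with marker
defaults at realistic resting medians (e.g. COMP ~800 ng/ml, IL-6
~1.8 pg/ml) and the duplicate CVs reported for this assay battery (COMP
2.2%, MMP-3 2.6%, MMP-9 1.2%, ADAMTS-4 1.3%, PRG-4 4.8%, IL-6 2.4%, C2C
8.1%, CPII 3.0%); the response is injected multiplicatively on the
relative scale, `y = b * (1 + w_t * delta / 100)`, so the relative-change
transform recovers the intended delta structure (exactly, absent assay
noise, at the timepoint with weight 1); the default response profile
decays over the post-test timepoints (weights 1.0/0.5/0.2 at t1/t2/t3),
a simple stand-in for post-exercise kinetics. Duplicate noise is
lognormal-multiplicative with mean one, keeping concentrations positive;
values beyond the detection limits are clipped to the limit and flagged.
The RNG is split per subject, so adding subjects never perturbs earlier
subjects' draws.

What the generator does **not** emulate: circadian drift, day effects or
carry-over between test days, assay plate/batch structure, missing visits,
inter-marker correlation beyond what a shared design induces (markers are
generated independently), and any nonlinearity in the dose-response.
Passing tests therefore validate the statistical machinery under the
model's own assumptions; they do not certify behavior under real-data
violations of those assumptions.

## Problem sizes and numerical defaults

Defaults chosen for the package's own test and reproduction runs: REML
convergence tolerance 1e-8 on the criterion, at most 5 jittered restarts,
profile-CI bracketing by bisection with tolerance 1e-4 of the SD scale.
The bundled acceptance reproduction uses the full 1000 replicates per
scenario; the test suite's power checks use 300 replicates with
correspondingly wider Monte-Carlo tolerances, null-calibration checks use
1000 replicates, parameter recovery uses 500 subjects, and profile-CI
coverage is spot-checked at 40 replicates of 60 subjects. Bootstrap
defaults: 2000 replicates for reported analyses, smaller counts inside
calibration loops.

## Known limitations

* Exactly one grouping level (subjects) and homoscedastic residuals; no
  Bayesian fitting.
* The Wald normal reference is mildly anti-conservative at n=24 (true
  size ~6%).
* Profile SD intervals use the same mixture threshold as the boundary
  test; intervals for well-identified SDs are therefore slightly wider
  than plain chi-square(1) profile intervals.
* The shift-constant rule caps only positive changes; markers whose
  response of interest is a *decrease* would need the cap applied to
  |change|.
* Detection-limit handling is flag-and-exclude (per the subject-exclusion
  rule); no censored-likelihood imputation.
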