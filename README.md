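# loadresponse

Is a blood biomarker **mechanosensitive**, and does its response to a
walking stress test scale with ambulatory load? `loadresponse` implements
a two-stage experimental-analytical framework for answering both
questions in crossover loading experiments: participants walk 30 minutes
at 80, 100 and 120% of body weight on separate days, serum markers of
articular-cartilage turnover (COMP, MMP-3, MMP-9, ADAMTS-4, PRG-4, IL-6,
C2C, CPII and the CPII/C2C ratio) are sampled before and after each test,
and the analysis decides which marker/timepoint combinations respond to
the test (criterion I) and which markers track load magnitude
(criterion II).

The statistical core is the individual-response model

    delta_il = alpha_i + beta_i * l + eps_il,        l in {-1, 0, +1}

where `delta_il` is the change from the same-day baseline of subject `i`
under load condition `l`, `(alpha_i, beta_i)` are bivariate-normal random
intercepts and slopes, and `eps` is residual noise. The four quantities of
interest are `mu_alpha` (average response at normal load), `sd_alpha`
(inter-individual variation in response), `mu_beta` (average dose-response
slope per load level) and `sd_beta` (variation in that slope). The package
fits this model by REML with its own engine (cross-validated against lme4
and statsmodels), tests the means with Wald tests and the SDs with
boundary likelihood-ratio tests against 50:50 chi-square mixtures, inverts
the same test for profile SD intervals, computes the change transforms
(normalized absolute change and shifted relative change with a 75% cap
rule), averaged-Spearman/bootstrap and slope correlations among markers,
a Monte-Carlo power study, and a synthetic-data generator that emulates
the whole study design. See `docs/methods.md` for the full model account.

## Worked example

Fit the response model to one synthetic 24-subject dataset generated at
the clinically interesting parameter point (all four parameters = 5,
residual SD 5) — `examples/03_fit_response_model.py`:

```text
n_subjects = 24, converged = True
mu_alpha  =   4.9  [2.6; 7.2]  p = 0.0000
sd_alpha  =   5.1  [3.1; 7.9]  p = 0.0007
mu_beta   =   6.1  [3.5; 8.7]  p = 0.0000
sd_beta   =   5.7  [3.3; 9.0]  p = 0.0020
sd_error  =   4.5
```

Each line is an estimate, 95% CI and p-value: the cohort responds on
average (`mu_alpha` ~ 5 change points), individuals differ in their
response (`sd_alpha` > 0), the response grows with load (`mu_beta` > 0),
and the load dependence itself varies between individuals (`sd_beta` > 0).
This combination passes criteria Ia/Ib and IIa/IIb, i.e. the marker would
be declared suitable for dose-response assessment.

The other examples each cover one capability: simulating a raw
concentration panel with duplicate wells (`01`), the two change scales and
the shift-constant rule (`02`), criteria gating on the bundled published
summary tables, reproducing the selection of 13 marker/timepoint
combinations (`04`), marker correlations (`05`) and the power study
(`06`). A thin CLI mirrors the stages:

```bash
loadresponse simulate --seed 1 --out panel.csv
loadresponse transform panel.csv --scale relative --out changes.csv
loadresponse run-all --seed 1 --out-dir results/
loadresponse power --n-reps 1000 --seed 1 --out power.csv
```

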