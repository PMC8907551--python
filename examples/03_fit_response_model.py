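"""Fit the individual-response model to one marker/timepoint slice.

The model is delta_il = alpha_i + beta_i * l + eps_il with bivariate-normal
random (alpha_i, beta_i): mu_alpha/sd_alpha describe the average response
and its inter-individual variation; mu_beta/sd_beta the average
dose-response slope and its variation.  Means get Wald tests; SDs get
boundary likelihood-ratio tests against a 50:50 chi-square mixture and
profile-likelihood intervals.
"""

from loadresponse import (SimulationConfig, fit_response_model,
                          simulate_change_values)

# generate at the clinical-interest parameter point
table = simulate_change_values(SimulationConfig(seed=7))
fit = fit_response_model(table, marker="synthetic", timepoint="t1",
                         scale="relative")

print(f"n_subjects = {fit.n_subjects}, converged = {fit.converged}")
print(f"mu_alpha  = {fit.mu_alpha_hat:5.1f}  "
      f"[{fit.ci_mu_alpha[0]:.1f}; {fit.ci_mu_alpha[1]:.1f}]  "
      f"p = {fit.p_mu_alpha:.4f}")
print(f"sd_alpha  = {fit.sd_alpha_hat:5.1f}  "
      f"[{fit.ci_sd_alpha[0]:.1f}; {fit.ci_sd_alpha[1]:.1f}]  "
      f"p = {fit.p_sd_alpha:.4f}")
print(f"mu_beta   = {fit.mu_beta_hat:5.1f}  "
      f"[{fit.ci_mu_beta[0]:.1f}; {fit.ci_mu_beta[1]:.1f}]  "
      f"p = {fit.p_mu_beta:.4f}")
print(f"sd_beta   = {fit.sd_beta_hat:5.1f}  "
      f"[{fit.ci_sd_beta[0]:.1f}; {fit.ci_sd_beta[1]:.1f}]  "
      f"p = {fit.p_sd_beta:.4f}")
print(f"sd_error  = {fit.sd_error_hat:5.1f}")
print("\nAll four generating parameters are 5; estimates should be near 5 "
      "with small p-values for the means and (usually) for the SDs — the "
      "SD tests have less power at n=24, which is exactly what the power "
      "study quantifies.")
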