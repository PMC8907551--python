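"""Monte-Carlo power for the four response-model parameters.

Under the clinical-interest scenario (all four parameters equal to 5,
24 subjects), how often do the Wald tests of the means and the boundary
LRTs of the SDs reject at the 5% level, and how much power is lost when
the residual SD grows from 5 to 7?  A reduced replicate count keeps this
example fast; the acceptance script runs the full 1000 replicates.
"""

from loadresponse import PowerScenario, run_power_grid

grid = run_power_grid(PowerScenario(n_reps=300), sd_errors=(5.0, 7.0),
                      seed=0)
for sd_e, sub in grid.groupby("scenario_sd_error"):
    print(f"\nresidual SD = {sd_e:g}:")
    for row in sub.itertuples():
        print(f"  {row.parameter:9s} power = {100 * row.power:5.1f}%  "
              f"(MC SE {100 * row.mc_se:.1f})")
print("\nMean responses stay detectable at either noise level; the "
      "variance components - inter-individual differences in response and "
      "in dose dependence - lose much of their detectability at the higher "
      "residual SD. That asymmetry is the design message of the power "
      "study: n=24 secures the averages, heterogeneity only if assay and "
      "biological noise stay moderate.")
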