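"""Change-from-baseline transforms on both analysis scales.

Builds the two change tables from a synthetic panel: normalized absolute
change (relative to the marker's pooled baseline median, so markers with
different units become comparable) and shifted relative change (percent
change from the same-day baseline, with the shift constant c capping the
maximal t1/t2 change at 75%).
"""

from loadresponse import (SimulationConfig, average_duplicates,
                          build_change_table, simulate_concentration_panel)

panel = average_duplicates(
    simulate_concentration_panel(SimulationConfig(seed=42)))

for scale in ("absolute", "relative"):
    table, constants = build_change_table(panel, scale)
    print(f"\n{scale} change table: {len(table)} values")
    print(constants.to_string(index=False))
    comp = table[(table["marker"] == "COMP") & (table["timepoint"] == "t1")]
    print(f"COMP at t1: mean {comp['delta'].mean():.1f}, "
          f"SD {comp['delta'].std():.1f} change points")

print("\nThe 'constant' column is the baseline median m (absolute scale) "
      "or the shift constant c (relative scale); c=0 means no change "
      "exceeded the 75% cap.  A COMP mean near the generator's mu_alpha=5 "
      "shows the transform recovers the injected response.")
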