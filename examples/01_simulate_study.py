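"""Simulate a synthetic walking-stress-test study.

Generates a raw concentration panel for 24 subjects under the default
marker panel: three ambulatory-load conditions (80/100/120 %BW), five
sampling timepoints, duplicate ELISA wells with marker-specific intra-assay
CV.  Prints the panel layout and the duplicate-precision summary.
"""

from loadresponse import (SimulationConfig, intra_assay_cv,
                          simulate_concentration_panel)

config = SimulationConfig(seed=42)
panel = simulate_concentration_panel(config)

print(f"panel: {len(panel)} records "
      f"({panel['subject_id'].nunique()} subjects x "
      f"{panel['marker'].nunique()} markers x 3 loads x 5 timepoints x "
      f"2 replicates)")
print(panel.head(6).to_string(index=False))

cv = intra_assay_cv(panel)
print("\nintra-assay CV per marker (mean +- SD, %):")
for _, row in cv.iterrows():
    print(f"  {row['marker']:9s} {row['mean_cv']:.1f} +- {row['sd_cv']:.1f}")
print("\nEach CV is the duplicate-pair coefficient of variation; values in "
      "the low single digits mean assay noise is small relative to the "
      "biological response the study wants to detect.")
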