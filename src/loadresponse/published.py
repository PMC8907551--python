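"""Published summary tables from the 24-participant ambulatory-load study
of nine serum cartilage markers, bundled as the package's worked example.

Two response tables (average response and inter-individual variation per
marker and post-test timepoint, relative and absolute change scales) and
two slope tables (mean and SD of the per-subject dose-response slopes, for
the combinations that passed criterion I).  P-values printed as "<.001"
are stored numerically as 0.0005 together with their display string; they
are only ever compared against significance thresholds of 0.05 or larger,
so the exact stand-in value is immaterial.
"""

from __future__ import annotations

import pandas as pd

P_BELOW_001 = 0.0005

#: The documented plausibility override: PRG-4 at t2 has a significant but
#: *negative* mean response inconsistent with its other timepoints, and is
#: excluded from the criterion-I selection as a spurious finding.
PRG4_T2_OVERRIDE = ("PRG-4", "t2",
                    "significant negative mean response, inconsistent with "
                    "the marker's other timepoints")


def _table(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=[
        "marker", "timepoint", "est_mean", "p_mean_display",
        "est_sd", "p_sd_display"])

    def parse(p):
        return P_BELOW_001 if p == "<.001" else float(p)

    df["p_mean"] = df["p_mean_display"].map(parse)
    df["p_sd"] = df["p_sd_display"].map(parse)
    return df[["marker", "timepoint", "est_mean", "p_mean", "est_sd", "p_sd",
               "p_mean_display", "p_sd_display"]]


def stress_response_relative() -> pd.DataFrame:
    """Relative-change response table: mean and SD of the individual
    responses to the stress test, with their p-values."""
    return _table([
        ("COMP", "t1", 29.3, "<.001", 12.3, "<.001"),
        ("COMP", "t2", 5.5, "<.001", 5.9, "<.001"),
        ("COMP", "t3", -0.4, ".783", 4.9, ".023"),
        ("MMP-3", "t1", 26.7, "<.001", 9.5, "<.001"),
        ("MMP-3", "t2", 13.1, "<.001", 6.9, ".001"),
        ("MMP-3", "t3", 4.2, ".002", 5.0, ".010"),
        ("MMP-9", "t1", 1.1, ".597", 0.0, "1.000"),
        ("MMP-9", "t2", -0.1, ".977", 9.0, ".039"),
        ("MMP-9", "t3", 2.7, ".525", 16.3, ".006"),
        ("PRG-4", "t1", 2.1, ".544", 6.2, ".666"),
        ("PRG-4", "t2", -6.9, ".023", 0.0, "1.000"),
        ("PRG-4", "t3", 0.5, ".919", 0.0, "1.000"),
        ("ADAMTS-4", "t1", 3.2, ".014", 0.0, "1.000"),
        ("ADAMTS-4", "t2", -0.7, ".722", 0.0, "1.000"),
        ("ADAMTS-4", "t3", 1.0, ".563", 0.0, "1.000"),
        ("IL-6", "t1", 6.1, "<.001", 4.6, ".219"),
        ("IL-6", "t2", 9.5, "<.001", 10.9, ".003"),
        ("IL-6", "t3", 21.3, "<.001", 18.7, "<.001"),
        ("C2C", "t1", 1.6, ".406", 4.7, ".446"),
        ("C2C", "t2", 3.6, ".086", 0.0, "1.000"),
        ("C2C", "t3", 1.3, ".617", 0.0, "1.000"),
        ("CPII", "t1", 4.9, ".032", 0.0, "1.000"),
        ("CPII", "t2", 3.3, ".299", 0.0, "1.000"),
        ("CPII", "t3", 5.5, ".179", 0.0, "1.000"),
        ("CPII/C2C", "t1", 3.7, ".058", 0.0, "1.000"),
        ("CPII/C2C", "t2", 1.5, ".583", 0.0, "1.000"),
        ("CPII/C2C", "t3", 4.4, ".239", 0.0, "1.000"),
    ])


def stress_response_absolute() -> pd.DataFrame:
    """Absolute-change response table (sensitivity counterpart)."""
    return _table([
        ("COMP", "t1", 29.6, "<.001", 12.6, "<.001"),
        ("COMP", "t2", 4.2, ".021", 7.7, "<.001"),
        ("COMP", "t3", -2.0, ".230", 6.3, ".011"),
        ("MMP-3", "t1", 26.2, "<.001", 12.5, "<.001"),
        ("MMP-3", "t2", 12.4, "<.001", 9.3, "<.001"),
        ("MMP-3", "t3", 3.3, ".014", 4.9, ".019"),
        ("MMP-9", "t1", -0.2, ".925", 0.0, "1.000"),
        ("MMP-9", "t2", -1.4, ".565", 6.7, ".307"),
        ("MMP-9", "t3", -1.1, ".739", 8.7, ".293"),
        ("PRG-4", "t1", -2.3, ".594", 0.0, "1.000"),
        ("PRG-4", "t2", -13.3, ".003", 0.0, "1.000"),
        ("PRG-4", "t3", -4.6, ".397", 0.0, "1.000"),
        ("ADAMTS-4", "t1", 1.8, ".020", 0.0, "1.000"),
        ("ADAMTS-4", "t2", -1.2, ".306", 0.0, "1.000"),
        ("ADAMTS-4", "t3", -0.2, ".836", 0.0, "1.000"),
        ("IL-6", "t1", 5.8, ".002", 5.8, ".120"),
        ("IL-6", "t2", 8.6, ".010", 14.0, "<.001"),
        ("IL-6", "t3", 21.0, "<.001", 22.9, "<.001"),
        ("C2C", "t1", 0.7, ".740", 4.3, ".570"),
        ("C2C", "t2", 1.8, ".367", 0.0, "1.000"),
        ("C2C", "t3", -1.6, ".543", 0.0, "1.000"),
        ("CPII", "t1", 2.5, ".314", 0.0, "1.000"),
        ("CPII", "t2", -0.7, ".829", 0.0, "1.000"),
        ("CPII", "t3", 0.2, ".964", 0.0, "1.000"),
        ("CPII/C2C", "t1", 2.1, ".286", 0.0, "1.000"),
        ("CPII/C2C", "t2", -1.4, ".602", 0.0, "1.000"),
        ("CPII/C2C", "t3", 0.1, ".982", 0.0, "1.000"),
    ])


def load_slopes_relative() -> pd.DataFrame:
    """Relative-change slope table: mean and SD of the per-subject
    dose-response slopes for the criterion-I-passing combinations."""
    return _table([
        ("COMP", "t1", 4.9, ".003", 4.0, ".027"),
        ("COMP", "t2", 2.1, ".074", 3.9, ".075"),
        ("COMP", "t3", 0.6, ".645", 3.7, ".274"),
        ("MMP-3", "t1", 8.0, "<.001", 4.1, ".022"),
        ("MMP-3", "t2", 5.7, "<.001", 2.4, ".161"),
        ("MMP-3", "t3", 4.2, "<.001", 3.3, ".041"),
        ("MMP-9", "t2", -2.4, ".329", 6.1, ".042"),
        ("MMP-9", "t3", -0.5, ".894", 10.7, ".122"),
        ("ADAMTS-4", "t1", 1.0, ".630", 8.4, ".008"),
        ("IL-6", "t1", -2.3, ".189", 4.9, ".033"),
        ("IL-6", "t2", 1.1, ".607", 2.7, ".296"),
        ("IL-6", "t3", 0.8, ".826", 12.6, ".108"),
        ("CPII", "t1", 2.0, ".582", 14.0, ".010"),
    ])


def load_slopes_absolute() -> pd.DataFrame:
    """Absolute-change slope table (sensitivity counterpart)."""
    return _table([
        ("COMP", "t1", 4.2, ".004", 2.1, ".196"),
        ("COMP", "t2", 1.6, ".175", 3.4, ".222"),
        ("COMP", "t3", 0.4, ".804", 5.5, ".118"),
        ("MMP-3", "t1", 7.9, "<.001", 4.7, ".060"),
        ("MMP-3", "t2", 5.8, "<.001", 3.2, ".287"),
        ("MMP-3", "t3", 3.8, ".001", 2.2, ".144"),
        ("MMP-9", "t2", -3.0, ".301", 9.2, ".009"),
        ("MMP-9", "t3", -2.0, ".584", 10.0, ".319"),
        ("ADAMTS-4", "t1", 0.7, ".567", 4.8, ".020"),
        ("IL-6", "t1", -2.5, ".159", 3.0, ".237"),
        ("IL-6", "t2", 1.5, ".519", 4.2, ".116"),
        ("IL-6", "t3", 1.3, ".723", 10.6, ".270"),
        ("CPII", "t1", 0.9, ".820", 15.8, ".003"),
    ])
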