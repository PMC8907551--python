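"""CSV input/output and table formatting.

The interchange format is a long-format CSV with the documented panel
columns.  Numeric report formatting follows the published table style:
estimates to one decimal, p-values to three decimals with values below
0.001 printed as "<.001", and unbounded interval ends printed as "inf".
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import pandas as pd

from .config import LOAD_PCT_TO_CODE, MARKERS, RATIO_MARKER, TIMEPOINTS
from .errors import InputIntegrityError

log = logging.getLogger(__name__)

PANEL_KEY = ["subject_id", "marker", "load_pct", "load_code", "timepoint"]
KNOWN_MARKERS = set(MARKERS) | {RATIO_MARKER}


def read_panel(path) -> pd.DataFrame:
    """Read and validate a raw concentration panel.

    Enforces the panel invariants: the fixed load percent <-> code mapping,
    nonnegative unflagged concentrations, and at most one record per
    (subject, marker, load, timepoint, replicate).  Unknown columns are
    preserved; unknown marker names produce a warning only.
    """
    df = pd.read_csv(path)
    required = set(PANEL_KEY) - {"load_code"} | {"concentration"}
    missing = required - set(df.columns)
    if missing:
        raise InputIntegrityError(f"missing columns: {sorted(missing)}")
    if "out_of_range" not in df.columns:
        df["out_of_range"] = False
    df["out_of_range"] = df["out_of_range"].astype(bool)
    bad_load = ~df["load_pct"].isin(LOAD_PCT_TO_CODE)
    if bad_load.any():
        lines = (df.index[bad_load] + 2).tolist()[:10]
        raise InputIntegrityError(f"unknown load_pct at file lines {lines}")
    codes = df["load_pct"].map(LOAD_PCT_TO_CODE)
    if "load_code" in df.columns:
        mismatch = df["load_code"] != codes
        if mismatch.any():
            lines = (df.index[mismatch] + 2).tolist()[:10]
            raise InputIntegrityError(
                f"load_pct/load_code mismatch at file lines {lines}")
    df["load_code"] = codes
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        lines = (df.index[bad_tp] + 2).tolist()[:10]
        raise InputIntegrityError(f"unknown timepoint at file lines {lines}")
    neg = (df["concentration"] < 0) & ~df["out_of_range"]
    if neg.any():
        lines = (df.index[neg] + 2).tolist()[:10]
        raise InputIntegrityError(
            f"negative unflagged concentration at file lines {lines}")
    key = PANEL_KEY + (["replicate"] if "replicate" in df.columns else [])
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].to_dict()
        raise InputIntegrityError(f"duplicated record key {first}")
    unknown = set(df["marker"]) - KNOWN_MARKERS
    if unknown:
        log.warning("read_panel: unknown marker name(s) %s", sorted(unknown))
    return df


def format_p(p: float | None) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p < 0.001:
        return "<.001"
    text = f"{p:.3f}"
    return text[1:] if text.startswith("0.") else text  # 0.042 -> .042


def format_ci(lo: float, hi: float) -> str:
    hi_s = "inf" if math.isinf(hi) else f"{hi:.1f}"
    return f"[{lo:.1f};{hi_s}]"


def render_response_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Published-style response table: Estimate, 95% CI, P-value for the
    mean and the SD, estimates to one decimal."""
    out = pd.DataFrame({
        "Biomarker": frame["marker"],
        "Time point": frame["timepoint"].str.lstrip("t"),
        "Mean Estimate": frame["est_mean"].map(lambda v: f"{v:.1f}"),
        "Mean 95% CI": [format_ci(lo, hi) for lo, hi in
                        zip(frame["ci_mean_lo"], frame["ci_mean_hi"])],
        "Mean P-value": frame["p_mean"].map(format_p),
        "SD Estimate": frame["est_sd"].map(lambda v: f"{v:.1f}"),
        "SD 95% CI": [format_ci(lo, hi) if lo is not None else ""
                      for lo, hi in zip(frame["ci_sd_lo"], frame["ci_sd_hi"])],
        "SD P-value": frame["p_sd"].map(format_p),
    })
    return out


def write_manifest(path, config_dict: dict, seed: int) -> None:
    import hashlib
    import sys

    import numpy
    import pandas
    import scipy

    blob = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
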