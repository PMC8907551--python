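"""Raw-panel preprocessing: duplicate averaging, assay precision, the
synthesis/degradation ratio marker, transforms and exclusions.

All operations act on the long-format concentration panel (one row per
subject x marker x load x timepoint x replicate; see
``synthetic.PANEL_COLUMNS``) and return new frames — inputs are never
mutated.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import DomainError, InputIntegrityError

log = logging.getLogger(__name__)

KEY = ["subject_id", "marker", "load_pct", "load_code", "timepoint"]


def average_duplicates(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate wells to their arithmetic mean.

    The mean of the available replicates (1 or 2) per key is used for all
    further analysis; the ``out_of_range`` flag propagates if any replicate
    was flagged.  Idempotent: a panel without a ``replicate`` column is
    returned unchanged.
    """
    if "replicate" not in panel.columns:
        return panel.copy()
    counts = panel.groupby(KEY, sort=False)["replicate"].size()
    if (counts > 2).any():
        bad = counts[counts > 2].index[0]
        raise InputIntegrityError(f"more than 2 replicates for key {bad}")
    grouped = panel.groupby(KEY, as_index=False, sort=False).agg(
        concentration=("concentration", "mean"),
        out_of_range=("out_of_range", "any"),
    )
    return grouped


def intra_assay_cv(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-marker intra-assay precision from duplicate wells.

    For each duplicate pair the CV is the two-point sample SD,
    |x1 - x2| / sqrt(2), divided by the pair mean, in percent.  Returns one
    row per marker with the mean and SD of the record-level CVs, the number
    of pairs, and the number of pairs skipped for a zero mean.
    """
    if "replicate" not in panel.columns:
        raise InputIntegrityError("panel has no replicate column")
    wide = panel.pivot_table(index=KEY, columns="replicate",
                             values="concentration", aggfunc="first")
    if 2 not in wide.columns:
        raise InputIntegrityError("no duplicate records present")
    pairs = wide.dropna(subset=[1, 2]).reset_index()
    mean = (pairs[1] + pairs[2]) / 2.0
    zero = mean == 0
    n_skipped = pairs.loc[zero].groupby("marker").size()
    if zero.any():
        log.warning("intra_assay_cv: skipped %d duplicate pair(s) with zero mean",
                    int(zero.sum()))
    pairs = pairs.loc[~zero]
    mean = mean.loc[~zero]
    cv = (pairs[1] - pairs[2]).abs() / math.sqrt(2.0) / mean * 100.0
    out = (pd.DataFrame({"marker": pairs["marker"], "cv": cv})
           .groupby("marker", sort=False)
           .agg(mean_cv=("cv", "mean"), sd_cv=("cv", lambda s: s.std(ddof=1)),
                n_pairs=("cv", "size"))
           .reset_index())
    out["n_skipped"] = out["marker"].map(n_skipped).fillna(0).astype(int)
    return out


def add_ratio_marker(panel: pd.DataFrame, numerator: str = "CPII",
                     denominator: str = "C2C",
                     name: str = "CPII/C2C") -> pd.DataFrame:
    """Append the synthesis/degradation ratio marker (numerator / denominator
    concentration per key).  Expects a duplicate-averaged panel.  Keys whose
    denominator is 0 or missing are skipped with a warning."""
    if "replicate" in panel.columns:
        raise InputIntegrityError("average duplicates before building the ratio")
    keys = [c for c in KEY if c != "marker"]
    num = panel[panel["marker"] == numerator].set_index(keys)
    den = panel[panel["marker"] == denominator].set_index(keys)
    joined = num.join(den, how="inner", lsuffix="_num", rsuffix="_den")
    n_missing = len(num) - len(joined) + len(den) - len(joined)
    zero = joined["concentration_den"] == 0
    if zero.any() or n_missing > 0:
        log.warning("add_ratio_marker: skipped %d key(s) (zero or missing %s)",
                    int(zero.sum()) + max(n_missing, 0), denominator)
    joined = joined.loc[~zero]
    ratio = joined.reset_index()[keys].copy()
    ratio["marker"] = name
    ratio["concentration"] = (joined["concentration_num"]
                              / joined["concentration_den"]).to_numpy()
    ratio["out_of_range"] = (joined["out_of_range_num"]
                             | joined["out_of_range_den"]).to_numpy()
    return pd.concat([panel, ratio[panel.columns.tolist()]], ignore_index=True)


def log_transform_marker(panel: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Replace the named marker's concentrations by log10(1 + x)."""
    sel = panel["marker"] == marker
    x = panel.loc[sel, "concentration"]
    if (x < 0).any():
        raise DomainError(f"negative concentration for {marker}; "
                          "log10(1+x) undefined")
    out = panel.copy()
    out.loc[sel, "concentration"] = np.log10(1.0 + x)
    return out


def exclude_subjects(panel: pd.DataFrame, rules) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove (subject, marker) cells named by the rules.

    Each rule is either an explicit pair ``("pair", subject_id, marker)`` or
    a detection-limit criterion ``("detection_limit", marker, min_flagged)``
    removing every subject with at least ``min_flagged`` out-of-range
    records for that marker (the rule used for a subject whose values fell
    outside the assay's detection limits).  Returns the filtered panel and
    a report with one row per removed (subject, marker) cell.
    """
    drop = pd.Series(False, index=panel.index)
    report_rows = []
    for rule in rules:
        kind = rule[0]
        if kind == "pair":
            _, subject, marker = rule
            mask = (panel["subject_id"] == subject) & (panel["marker"] == marker)
            if mask.any():
                report_rows.append((subject, marker, f"pair:{subject}/{marker}",
                                    int(mask.sum())))
            drop |= mask
        elif kind == "detection_limit":
            _, marker, min_flagged = rule
            flagged = panel[(panel["marker"] == marker) & panel["out_of_range"]]
            counts = flagged.groupby("subject_id").size()
            for subject, n in counts[counts >= min_flagged].items():
                mask = ((panel["subject_id"] == subject)
                        & (panel["marker"] == marker))
                report_rows.append((subject, marker,
                                    f"detection_limit:>={min_flagged}",
                                    int(mask.sum())))
                drop |= mask
        else:
            raise DomainError(f"unknown exclusion rule kind {kind!r}")
    report = pd.DataFrame(report_rows,
                          columns=["subject_id", "marker", "rule", "n_records"])
    return panel.loc[~drop].copy(), report


def baseline_median(panel: pd.DataFrame, marker: str) -> float:
    """Median concentration at baseline t0, pooled over subjects and loads."""
    t0 = panel[(panel["marker"] == marker) & (panel["timepoint"] == "t0")]
    if t0.empty:
        raise InputIntegrityError(f"no t0 records for marker {marker}")
    return float(t0["concentration"].median())
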