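"""Change-from-baseline transforms.

Two scales make marker responses comparable across markers with very
different native units:

* **absolute** change, normalized by the marker's pooled baseline median m:
  ``(y_t - y_0) / m * 100`` — a five-point change is a change worth 5% of
  the typical resting level;
* **relative** change with a shift constant c: ``(y_t - y_0) / (y_0 + c) *
  100`` — percent change from the same-day baseline, stabilized against
  near-zero baselines by the smallest c that caps the maximal relative
  change at the early post-test timepoints (t1, t2) at 75%.

Changes are always taken against the same test day's t0 sample; the t-1
sample never enters change computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DomainError
from .preprocess import baseline_median, log_transform_marker

log = logging.getLogger(__name__)

CHANGE_COLUMNS = ["subject_id", "marker", "load_code", "timepoint",
                  "delta", "scale"]
DEFAULT_CAP = 75.0
CAP_TIMEPOINTS = ("t1", "t2")


def absolute_change(y_t, y_0, m):
    """Normalized absolute change ``(y_t - y_0) / m * 100`` in points."""
    if np.any(np.asarray(m) <= 0):
        raise DomainError("baseline median m must be > 0")
    return (np.asarray(y_t, dtype=float) - y_0) / m * 100.0


def relative_change(y_t, y_0, c):
    """Shifted relative change ``(y_t - y_0) / (y_0 + c) * 100`` in percent.

    With c = 0 this is the ordinary percent change from baseline.
    """
    denom = np.asarray(y_0, dtype=float) + c
    if np.any(denom <= 0):
        raise DomainError("y_0 + c must be > 0")
    return (np.asarray(y_t, dtype=float) - y_0) / denom * 100.0


def select_shift_constant(panel: pd.DataFrame, marker: str,
                          cap: float = DEFAULT_CAP,
                          timepoints=CAP_TIMEPOINTS) -> float:
    """Smallest c >= 0 capping all t1/t2 relative changes at ``cap`` percent.

    For each record with y_t > y_0 the cap binds at
    ``c = (y_t - y_0) * 100 / cap - y_0``; the selected constant is the
    maximum of these over all subjects, loads and capped timepoints
    (clipped at 0), pooled per marker.  Only increases are constrained: the
    responses of interest are concentration rises, and a decrease is
    bounded below anyway.
    """
    if cap <= 0:
        raise DomainError("cap must be > 0")
    sub = panel[panel["marker"] == marker]
    keys = ["subject_id", "load_code"]
    y0 = (sub[sub["timepoint"] == "t0"]
          .set_index(keys)["concentration"])
    post = sub[sub["timepoint"].isin(timepoints)]
    if y0.empty or post.empty:
        log.warning("select_shift_constant: no qualifying records for %s; c=0",
                    marker)
        return 0.0
    yt = post.set_index(keys)["concentration"]
    base = y0.reindex(yt.index)
    diff = yt - base
    rising = diff > 0
    if not rising.any():
        return 0.0
    c = (diff[rising] * 100.0 / cap - base[rising]).max()
    return float(max(c, 0.0))


def build_change_table(panel: pd.DataFrame, scale: str,
                       markers=None, cap: float = DEFAULT_CAP,
                       cap_timepoints=CAP_TIMEPOINTS,
                       log_markers=("ADAMTS-4",),
                       timepoints=("t1", "t2", "t3")):
    """Turn a duplicate-averaged panel into a change table.

    Returns ``(change_table, constants)`` where constants holds the
    per-marker baseline median m (absolute scale) or shift constant c
    (relative scale) for auditability.  Markers in ``log_markers`` are
    log10(1+x)-transformed before the absolute-change transform (used for
    right-skewed markers); the relative scale always works on raw values.
    (subject, load) cells with no t0 record are skipped and logged.
    """
    if scale not in ("absolute", "relative"):
        raise DomainError(f"unknown change scale {scale!r}")
    if markers is None:
        markers = list(dict.fromkeys(panel["marker"]))
    rows = []
    const_rows = []
    for marker in markers:
        work = panel
        constant = np.nan
        if scale == "absolute":
            if marker in log_markers:
                work = log_transform_marker(panel, marker)
            m = baseline_median(work, marker)
            constant = m
        else:
            c = select_shift_constant(panel, marker, cap=cap,
                                      timepoints=cap_timepoints)
            constant = c
        sub = work[work["marker"] == marker]
        keys = ["subject_id", "load_code"]
        y0 = sub[sub["timepoint"] == "t0"].set_index(keys)["concentration"]
        post = sub[sub["timepoint"].isin(timepoints)]
        base = y0.reindex(post.set_index(keys).index)
        missing = base.isna().to_numpy()
        if missing.any():
            skipped = post.loc[missing, keys].drop_duplicates()
            for _, r in skipped.iterrows():
                log.warning("build_change_table: no t0 for subject %s load %s "
                            "marker %s; skipped", r["subject_id"],
                            r["load_code"], marker)
        yt = post["concentration"].to_numpy()[~missing]
        y0v = base.to_numpy()[~missing]
        if scale == "absolute":
            delta = absolute_change(yt, y0v, m)
        else:
            delta = relative_change(yt, y0v, c)
        kept = post.loc[~missing]
        frame = pd.DataFrame({
            "subject_id": kept["subject_id"].to_numpy(),
            "marker": marker,
            "load_code": kept["load_code"].to_numpy(),
            "timepoint": kept["timepoint"].to_numpy(),
            "delta": delta,
            "scale": scale,
        })
        rows.append(frame)
        const_rows.append((marker, scale, constant))
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=CHANGE_COLUMNS))
    constants = pd.DataFrame(const_rows,
                             columns=["marker", "scale", "constant"])
    return table, constants
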