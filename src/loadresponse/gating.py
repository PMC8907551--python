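"""Two-stage criteria gating for marker suitability.

Criterion I asks whether a marker responds to the walking stress test at a
given post-test timepoint: (Ia) a significant average response, or (Ib)
significant inter-individual variation in the response.  Combinations
passing I (after any documented plausibility overrides) advance to
criterion II on the dose-response slopes: (IIa) a significant average
slope, or (IIb) significant inter-individual slope variation.  A marker is
"suitable" for assessing the dose-response relationship if any of its
passing combinations satisfies IIa or IIb.

Significance is assessed per test at the configured level (default 5%)
with no multiple-testing adjustment — deliberately, since the framework is
a screening device: each criterion is a yes/no question about one marker
at one timepoint, and controlling a family-wise rate across markers would
change the question being asked.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import GatingIncompleteError

POST_TIMEPOINTS = ("t1", "t2", "t3")


@dataclass
class GateDecision:
    marker: str
    timepoint: str
    scale: str = ""
    crit_Ia: bool = False
    crit_Ib: bool = False
    crit_I: bool = False
    overridden: bool = False
    override_reason: str = ""
    crit_IIa: bool | None = None
    crit_IIb: bool | None = None
    crit_II: bool | None = None
    alpha_level: float = 0.05


def _require_columns(table: pd.DataFrame, cols):
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise GatingIncompleteError([f"column:{c}" for c in missing])


def apply_criterion_one(fit_table: pd.DataFrame, alpha: float = 0.05,
                        overrides=(), scale: str = "",
                        timepoints=POST_TIMEPOINTS) -> list[GateDecision]:
    """Apply criterion I to a response-fit table.

    ``fit_table`` needs one row per marker x post-test timepoint with
    columns ``marker, timepoint, p_mean, p_sd`` (the layout produced by
    :func:`loadresponse.model.fits_to_frame` and by the bundled published
    tables).  ``overrides`` is a sequence of (marker, timepoint, reason)
    triples removing a passing combination for a recorded reason;
    overrides can only remove, never add.
    """
    _require_columns(fit_table, ["marker", "timepoint", "p_mean", "p_sd"])
    markers = list(dict.fromkeys(fit_table["marker"]))
    index = fit_table.set_index(["marker", "timepoint"])
    gaps = [(m, tp) for m in markers for tp in timepoints
            if (m, tp) not in index.index]
    if gaps:
        raise GatingIncompleteError(gaps)
    override_map = {(m, tp): reason for m, tp, reason in overrides}
    decisions = []
    for m in markers:
        for tp in timepoints:
            row = index.loc[(m, tp)]
            ia = bool(row["p_mean"] < alpha)
            ib = bool(row["p_sd"] < alpha)
            d = GateDecision(marker=m, timepoint=tp, scale=scale,
                             crit_Ia=ia, crit_Ib=ib, crit_I=ia or ib,
                             alpha_level=alpha)
            if d.crit_I and (m, tp) in override_map:
                d.overridden = True
                d.override_reason = override_map[(m, tp)]
                d.crit_I = False
            decisions.append(d)
    return decisions


def selected_combinations(decisions) -> list[tuple[str, str]]:
    """Marker/timepoint combinations passing criterion I (post-override)."""
    return [(d.marker, d.timepoint) for d in decisions if d.crit_I]


def flag_override_candidates(fit_table: pd.DataFrame,
                             alpha: float = 0.05) -> list[tuple[str, str, str]]:
    """Flag significant mean responses whose sign contradicts the same
    marker's other timepoints — candidates for a plausibility override,
    for human review (never applied automatically)."""
    _require_columns(fit_table, ["marker", "timepoint", "est_mean", "p_mean"])
    out = []
    for m, grp in fit_table.groupby("marker", sort=False):
        for _, row in grp.iterrows():
            if row["p_mean"] >= alpha:
                continue
            others = grp[grp["timepoint"] != row["timepoint"]]["est_mean"]
            if len(others) == 0:
                continue
            if row["est_mean"] < 0 and (others >= 0).all():
                out.append((m, row["timepoint"],
                            "significant negative mean, other timepoints "
                            "non-negative"))
            elif row["est_mean"] > 0 and (others <= 0).all():
                out.append((m, row["timepoint"],
                            "significant positive mean, other timepoints "
                            "non-positive"))
    return out


def apply_criterion_two(slope_table: pd.DataFrame, decisions,
                        alpha: float = 0.05):
    """Apply criterion II to the criterion-I survivors.

    ``slope_table`` holds the slope-model fits (columns ``marker,
    timepoint, p_mean, p_sd``, where mean/SD refer to mu_beta/sd_beta) and
    must cover every selected combination.  Returns the updated decisions
    and a per-marker suitability verdict (True if any passing combination
    satisfies IIa or IIb).
    """
    _require_columns(slope_table, ["marker", "timepoint", "p_mean", "p_sd"])
    index = slope_table.set_index(["marker", "timepoint"])
    selected = selected_combinations(decisions)
    gaps = [key for key in selected if key not in index.index]
    if gaps:
        raise GatingIncompleteError(gaps)
    verdicts: dict[str, bool] = {}
    for d in decisions:
        if not d.crit_I:
            continue
        row = index.loc[(d.marker, d.timepoint)]
        d.crit_IIa = bool(row["p_mean"] < alpha)
        d.crit_IIb = bool(row["p_sd"] < alpha)
        d.crit_II = d.crit_IIa or d.crit_IIb
        verdicts[d.marker] = verdicts.get(d.marker, False) or d.crit_II
    return decisions, verdicts


def decisions_to_frame(decisions) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in decisions])


def gating_report(decisions, verdicts=None) -> str:
    """Human-readable gating report mirroring the two-stage flow."""
    lines = ["# Marker suitability gating", "",
             "## Criterion I: response to the stress test", ""]
    for d in decisions:
        status = "PASS" if d.crit_I else "fail"
        note = ""
        if d.overridden:
            note = f"  [overridden: {d.override_reason}]"
        lines.append(f"- {d.marker} {d.timepoint}: Ia={d.crit_Ia} "
                     f"Ib={d.crit_Ib} -> {status}{note}")
    sel = selected_combinations(decisions)
    lines += ["", f"Selected combinations ({len(sel)}): "
              + ", ".join(f"{m} {tp}" for m, tp in sel)]
    if any(d.crit_II is not None for d in decisions):
        lines += ["", "## Criterion II: dose-response relationship", ""]
        for d in decisions:
            if d.crit_II is None:
                continue
            status = "PASS" if d.crit_II else "fail"
            lines.append(f"- {d.marker} {d.timepoint}: IIa={d.crit_IIa} "
                         f"IIb={d.crit_IIb} -> {status}")
    if verdicts:
        suitable = sorted(m for m, v in verdicts.items() if v)
        lines += ["", "Suitable markers (mechanical rule): "
                  + (", ".join(suitable) if suitable else "none")]
    return "\n".join(lines) + "\n"
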