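"""End-to-end orchestration of the two-stage analysis.

``run_pipeline`` executes preprocess -> change transforms -> response-model
fits (all markers x t1-t3 x both scales) -> criteria gating -> marker
association, and writes published-style response and slope tables, the
gating report, correlation matrices and a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import association, changes, gating, io, model, preprocess
from .config import PipelineConfig, RATIO_MARKER
from .errors import LoadResponseError
from .synthetic import simulate_concentration_panel

log = logging.getLogger(__name__)


class StageError(LoadResponseError):
    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {original}")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except LoadResponseError as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("preprocess")
def _preprocess(config: PipelineConfig):
    if config.input_csv is not None:
        panel = io.read_panel(config.input_csv)
    else:
        panel = simulate_concentration_panel(
            config.scenario.with_(seed=config.seed))
    cv = preprocess.intra_assay_cv(panel) if "replicate" in panel.columns \
        else pd.DataFrame()
    averaged = preprocess.average_duplicates(panel)
    if {"CPII", "C2C"} <= set(averaged["marker"]):
        averaged = preprocess.add_ratio_marker(averaged)
    averaged, exclusions = preprocess.exclude_subjects(
        averaged, [("detection_limit", m, 1)
                   for m in dict.fromkeys(averaged["marker"])])
    return averaged, cv, exclusions


@_stage("change_transforms")
def _transform(averaged, config: PipelineConfig):
    tables, constants = [], []
    for scale in config.scales:
        t, c = changes.build_change_table(averaged, scale, cap=config.cap)
        tables.append(t)
        constants.append(c)
    return pd.concat(tables, ignore_index=True), pd.concat(
        constants, ignore_index=True)


@_stage("mixed_model")
def _fit_all(change_table, config: PipelineConfig):
    fits = []
    for (marker, tp, scale), _ in change_table.groupby(
            ["marker", "timepoint", "scale"], sort=False):
        try:
            fits.append(model.fit_response_model(
                change_table, marker=marker, timepoint=tp, scale=scale,
                seed=config.seed))
        except LoadResponseError as exc:
            log.warning("fit failed for %s %s (%s): %s", marker, tp, scale,
                        exc)
    return fits


@_stage("criteria_gate")
def _gate(fits, config: PipelineConfig):
    scale = config.gating_scale
    resp = model.fits_to_frame([f for f in fits if f.scale == scale])
    slope = model.slope_fits_to_frame([f for f in fits if f.scale == scale])
    decisions = gating.apply_criterion_one(
        resp, alpha=config.alpha, overrides=config.overrides, scale=scale)
    decisions, verdicts = gating.apply_criterion_two(
        slope, decisions, alpha=config.alpha)
    return decisions, verdicts


@_stage("marker_association")
def _associate(change_table, decisions, config: PipelineConfig):
    selected = gating.selected_combinations(decisions)
    if len(selected) < 2:
        return None
    sub = change_table[change_table["scale"] == config.gating_scale]
    rho_change, _ = association.correlation_matrix(
        selected, sub, kind="change")
    rho_slope, p_slope = association.correlation_matrix(
        selected, sub, kind="slope")
    return {"rho_change": rho_change, "rho_slope": rho_slope,
            "p_slope": p_slope}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-stage analysis; returns the result bundle and
    writes all outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("loadresponse").addHandler(handler)
    try:
        averaged, cv, exclusions = _preprocess(config)
        change_table, constants = _transform(averaged, config)
        fits = _fit_all(change_table, config)
        decisions, verdicts = _gate(fits, config)
        correlations = (_associate(change_table, decisions, config)
                        if config.compute_correlations else None)
    finally:
        logging.getLogger("loadresponse").removeHandler(handler)
        handler.close()

    # --- write outputs (fixed column order, stable formatting) ---
    if not cv.empty:
        cv.to_csv(out / "intra_assay_cv.csv", index=False, float_format="%.4f")
    exclusions.to_csv(out / "exclusions.csv", index=False)
    change_table.to_csv(out / "change_table.csv", index=False,
                        float_format="%.6f")
    constants.to_csv(out / "change_constants.csv", index=False,
                     float_format="%.6f")
    for scale in config.scales:
        resp = model.fits_to_frame([f for f in fits if f.scale == scale])
        slope = model.slope_fits_to_frame([f for f in fits if f.scale == scale])
        io.render_response_table(resp).to_csv(
            out / f"response_{scale}.csv", index=False)
        io.render_response_table(slope).to_csv(
            out / f"slopes_{scale}.csv", index=False)
    gating.decisions_to_frame(decisions).to_csv(
        out / "gate_decisions.csv", index=False)
    report = gating.gating_report(decisions, verdicts)
    if not any(v for v in verdicts.values()):
        report += "\nNo suitable markers under the current criteria.\n"
    (out / "gating_report.md").write_text(report)
    if correlations is not None:
        correlations["rho_change"].to_csv(out / "corr_change.csv",
                                          float_format="%.4f")
        correlations["rho_slope"].to_csv(out / "corr_slope.csv",
                                         float_format="%.4f")
        correlations["p_slope"].to_csv(out / "corr_slope_p.csv",
                                       float_format="%.4f")
        association.plot_heatmap(correlations["rho_change"],
                                 out / "corr_change.png",
                                 f"Changes ({config.gating_scale})")
        association.plot_heatmap(correlations["rho_slope"],
                                 out / "corr_slope.png",
                                 f"Slopes ({config.gating_scale})")
    cfg_dict = dataclasses.asdict(config)
    if config.scenario is not None:
        cfg_dict["scenario"] = dataclasses.asdict(config.scenario)
    io.write_manifest(out / "manifest.json", cfg_dict, config.seed)
    return {"panel": averaged, "cv": cv, "exclusions": exclusions,
            "changes": change_table, "constants": constants, "fits": fits,
            "decisions": decisions, "verdicts": verdicts,
            "correlations": correlations, "out_dir": str(out)}
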