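"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided.  ``simulate_change_values`` draws change-scale
responses directly from the random-intercept/random-slope model

    delta_il = alpha_i + beta_i * l + eps_il,

the data-generating process of the power study and the parameter-recovery
tests.  ``simulate_concentration_panel`` emulates the full study layout on
the raw concentration scale: per-subject lognormal baselines, a response
injected multiplicatively at the post-test timepoints so that the relative
change transform recovers the intended delta structure, duplicate wells
with marker-specific intra-assay CV, and detection-limit flagging.

Randomness is split per subject (one child seed stream each), so enlarging
``n_subjects`` appends subjects without perturbing earlier subjects' draws.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (LOAD_CODE_TO_PCT, POST_TIMEPOINTS, SimulationConfig)

CHANGE_COLUMNS = ["subject_id", "load_code", "timepoint", "delta"]
PANEL_COLUMNS = ["subject_id", "marker", "load_pct", "load_code",
                 "timepoint", "replicate", "concentration", "out_of_range"]


def _subject_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _draw_alpha_beta(rng: np.random.Generator, cfg: SimulationConfig):
    """Bivariate-normal (alpha, beta) via the Cholesky construction; exact
    for degenerate (zero-SD) components."""
    z1, z2 = rng.standard_normal(2)
    alpha = cfg.mu_alpha + cfg.sd_alpha * z1
    rho = cfg.rho_alpha_beta
    beta = cfg.mu_beta + cfg.sd_beta * (rho * z1 + math.sqrt(1 - rho * rho) * z2)
    return alpha, beta


def simulate_change_values(config: SimulationConfig,
                           timepoint: str = "t1") -> pd.DataFrame:
    """Draw one change table from the individual-response model.

    Returns a long table with columns ``subject_id, load_code, timepoint,
    delta``; one row per subject x load code.  Reproducible for a given
    ``config.seed``.
    """
    cfg = config.validate()
    loads = np.asarray(cfg.load_codes, dtype=float)
    rows = []
    for i, rng in enumerate(_subject_rngs(cfg.seed, cfg.n_subjects), start=1):
        alpha, beta = _draw_alpha_beta(rng, cfg)
        eps = cfg.sd_error * rng.standard_normal(loads.size)
        delta = alpha + beta * loads + eps
        for l, d in zip(cfg.load_codes, delta):
            rows.append((i, int(l), timepoint, float(d)))
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


def simulate_concentration_panel(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a raw-scale duplicate-well concentration panel.

    For each subject and marker a resting baseline ``b`` is drawn once from
    a lognormal with the configured median and geometric CV and held fixed
    across the three test days (pre-test rows at t-1 and t0 equal ``b``
    before assay noise).  At post-test timepoint ``t`` under load code ``l``
    the true concentration is

        y = b * (1 + w_t * (alpha_i + beta_i * l + eps_ilt) / 100)

    with ``w_t`` the response-profile weight, so that the relative change
    from the same-day t0 equals the intended delta structure (exactly so at
    the timepoint with w=1 and in the absence of assay noise).  Duplicates
    are lognormal-multiplicative with the marker's intra-assay CV (mean-one
    noise, keeping concentrations positive); values beyond the detection
    limits are clipped to the limit and flagged ``out_of_range``.
    """
    cfg = config.validate()
    if not cfg.markers:
        from .errors import ConfigurationError
        raise ConfigurationError("markers", "at least one marker spec required")
    loads = list(cfg.load_codes)
    post = [tp for tp in cfg.timepoints if tp in cfg.response_profile]
    pre = [tp for tp in cfg.timepoints if tp not in cfg.response_profile]
    rows = []
    for i, rng in enumerate(_subject_rngs(cfg.seed, cfg.n_subjects), start=1):
        for marker, spec in cfg.markers.items():
            # lognormal baseline: median b_med, geometric CV gcv
            sigma_b = math.sqrt(math.log(1.0 + spec.baseline_gcv ** 2))
            b = spec.baseline_median * math.exp(sigma_b * rng.standard_normal())
            alpha, beta = _draw_alpha_beta(rng, cfg)
            sigma_d = math.sqrt(math.log(1.0 + (spec.cv_intra / 100.0) ** 2))
            for l in loads:
                for tp in cfg.timepoints:
                    if tp in pre:
                        y = b
                    else:
                        w = cfg.response_profile[tp]
                        eps = cfg.sd_error * rng.standard_normal()
                        delta = alpha + beta * l + eps
                        y = b * (1.0 + w * delta / 100.0)
                    y = max(y, 0.0)
                    for rep in (1, 2):
                        if sigma_d > 0:
                            z = rng.standard_normal()
                            obs = y * math.exp(sigma_d * z - 0.5 * sigma_d ** 2)
                        else:
                            obs = y
                        lo, hi = spec.detection_limits
                        flagged = obs < lo or obs > hi
                        obs = min(max(obs, lo), hi)
                        rows.append((i, marker, LOAD_CODE_TO_PCT[int(l)],
                                     int(l), tp, rep, float(obs), flagged))
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_change_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)
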