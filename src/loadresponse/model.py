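"""Response-model fitting and inference for one marker x timepoint x scale.

Wraps the REML engine into the quantities the two-stage framework needs:
point estimates of (mu_alpha, sd_alpha, mu_beta, sd_beta), Wald tests and
normal-reference CIs for the means, and boundary likelihood-ratio tests
plus profile-likelihood intervals for the SDs.  Testing an SD removes that
random effect *and* its covariance with the remaining one, so the
reference distribution is the 50:50 mixture of chi-square(1) and
chi-square(2); when the tested effect is the only random effect the
mixture is chi-square(0):chi-square(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import reml
from .errors import InferenceUnavailableError, InputIntegrityError


@dataclass
class ResponseFit:
    """Fitted individual-response model for one marker/timepoint/scale."""

    marker: str
    timepoint: str
    scale: str
    mu_alpha_hat: float
    sd_alpha_hat: float
    mu_beta_hat: float
    sd_beta_hat: float
    rho_hat: float | None
    sd_error_hat: float
    se_mu_alpha: float
    se_mu_beta: float
    ci_mu_alpha: tuple[float, float]
    ci_mu_beta: tuple[float, float]
    p_mu_alpha: float
    p_mu_beta: float
    p_sd_alpha: float | None = None
    p_sd_beta: float | None = None
    ci_sd_alpha: tuple[float, float] | None = None
    ci_sd_beta: tuple[float, float] | None = None
    n_subjects: int = 0
    converged: bool = True
    boundary: dict = field(default_factory=dict)
    loglik: float = float("nan")


def _slice_arrays(changes: pd.DataFrame):
    delta = changes["delta"].to_numpy(dtype=float)
    load = changes["load_code"].to_numpy(dtype=float)
    subject = changes["subject_id"].to_numpy()
    counts = pd.Series(load).groupby(pd.Series(subject)).nunique()
    if (counts >= 2).sum() < 2:
        raise InputIntegrityError(
            "need >= 2 subjects with >= 2 load levels each")
    return delta, load, subject


def fit_response_model(changes: pd.DataFrame, marker: str | None = None,
                       timepoint: str | None = None, scale: str | None = None,
                       compute_sd_tests: bool = True,
                       compute_sd_cis: bool = True,
                       level: float = 0.95, seed: int = 0) -> ResponseFit:
    """REML fit plus full inference on one change-table slice.

    ``changes`` may be a pre-sliced table or a full one with ``marker`` /
    ``timepoint`` / ``scale`` selectors.  Set ``compute_sd_tests`` /
    ``compute_sd_cis`` to False to skip the (reduced-model) likelihood
    machinery when only point estimates and Wald tests are needed, e.g.
    inside large simulations.
    """
    sub = changes
    for col, val in (("marker", marker), ("timepoint", timepoint),
                     ("scale", scale)):
        if val is not None and col in sub.columns:
            sub = sub[sub[col] == val]
    if sub.empty:
        raise InputIntegrityError(
            f"no change records for marker={marker} timepoint={timepoint}")
    delta, load, subject = _slice_arrays(sub)
    data = reml.LMMData.from_arrays(delta, load, subject)
    full = reml.fit_lmm(data, None, None, effects=("intercept", "slope"),
                        seed=seed)
    z = stats.norm.ppf(0.5 + level / 2.0)

    def wald(est, se):
        if se <= 0:
            return (est, est), 1.0 if est == 0 else 0.0
        return (est - z * se, est + z * se), 2.0 * stats.norm.sf(abs(est) / se)

    ci_a, p_a = wald(full.mu_alpha, full.se_fixed[0])
    ci_b, p_b = wald(full.mu_beta, full.se_fixed[1])
    fit = ResponseFit(
        marker=marker or (sub["marker"].iloc[0] if "marker" in sub else ""),
        timepoint=timepoint or (sub["timepoint"].iloc[0]
                                if "timepoint" in sub else ""),
        scale=scale or (sub["scale"].iloc[0] if "scale" in sub else ""),
        mu_alpha_hat=full.mu_alpha, sd_alpha_hat=full.sd_re["intercept"],
        mu_beta_hat=full.mu_beta, sd_beta_hat=full.sd_re["slope"],
        rho_hat=full.corr, sd_error_hat=full.sd_error,
        se_mu_alpha=float(full.se_fixed[0]), se_mu_beta=float(full.se_fixed[1]),
        ci_mu_alpha=ci_a, ci_mu_beta=ci_b, p_mu_alpha=p_a, p_mu_beta=p_b,
        n_subjects=full.n_subjects, converged=full.converged,
        boundary=dict(full.boundary), loglik=full.loglik)
    if compute_sd_tests:
        fit.p_sd_alpha = test_sd(data, fit, "alpha", seed=seed, _full=full)
        fit.p_sd_beta = test_sd(data, fit, "beta", seed=seed, _full=full)
    if compute_sd_cis:
        fit.ci_sd_alpha = ci_sd(data, fit, "alpha", level=level, seed=seed)
        fit.ci_sd_beta = ci_sd(data, fit, "beta", level=level, seed=seed)
    return fit


def test_mean(fit: ResponseFit, which: str):
    """Wald test of a fixed effect against 0 (normal reference)."""
    if not fit.converged:
        raise InferenceUnavailableError("model fit did not converge")
    if which == "alpha":
        return fit.mu_alpha_hat, fit.ci_mu_alpha, fit.p_mu_alpha
    if which == "beta":
        return fit.mu_beta_hat, fit.ci_mu_beta, fit.p_mu_beta
    raise ValueError(f"unknown fixed effect {which!r}")


def _as_data(changes) -> reml.LMMData:
    if isinstance(changes, reml.LMMData):
        return changes
    delta, load, subject = _slice_arrays(changes)
    return reml.LMMData.from_arrays(delta, load, subject)


def test_sd(changes, fit: ResponseFit, which: str, seed: int = 0,
            _full: reml.REMLFit | None = None) -> float:
    """Boundary likelihood-ratio test for a random-effect SD.

    Refits the reduced model with the tested random effect (and its
    covariance with the other effect) removed; the LRT statistic is
    referenced against the 50:50 chi-square(1):chi-square(2) mixture.
    """
    if not fit.converged:
        raise InferenceUnavailableError("model fit did not converge")
    data = _as_data(changes)
    if _full is None:
        _full = reml.fit_lmm(data, None, None,
                             effects=("intercept", "slope"), seed=seed)
    kept = "slope" if which == "alpha" else "intercept"
    reduced = reml.fit_lmm(data, None, None, effects=(kept,), seed=seed)
    if not reduced.converged:
        raise InferenceUnavailableError("reduced model did not converge")
    _, p = reml.lrt_boundary(_full, reduced, dfs=(1, 2))
    return p


def ci_sd(changes, fit: ResponseFit, which: str, level: float = 0.95,
          seed: int = 0) -> tuple[float, float]:
    """Profile-REML confidence interval for sd_alpha or sd_beta.

    The lower bound is clipped at 0 and the upper bound is infinity when
    the profile deviance never crosses the mixture threshold (the
    "0.0 [0.0; inf]" pattern typical of variance components estimated at
    the boundary in small samples).
    """
    if not fit.converged:
        raise InferenceUnavailableError("model fit did not converge")
    data = _as_data(changes)
    effect = "intercept" if which == "alpha" else "slope"
    other = "slope" if which == "alpha" else "intercept"
    return reml.profile_sd_interval(data, effect, other, level=level,
                                    seed=seed)


def fits_to_frame(fits) -> pd.DataFrame:
    """Response fits as a summary-table frame (one row per fit) with the
    layout of the published response tables: estimate, 95% CI and p-value
    for the mean and the SD."""
    rows = []
    for f in fits:
        rows.append({
            "marker": f.marker, "timepoint": f.timepoint, "scale": f.scale,
            "est_mean": f.mu_alpha_hat, "ci_mean_lo": f.ci_mu_alpha[0],
            "ci_mean_hi": f.ci_mu_alpha[1], "p_mean": f.p_mu_alpha,
            "est_sd": f.sd_alpha_hat,
            "ci_sd_lo": None if f.ci_sd_alpha is None else f.ci_sd_alpha[0],
            "ci_sd_hi": None if f.ci_sd_alpha is None else f.ci_sd_alpha[1],
            "p_sd": f.p_sd_alpha,
            "n_subjects": f.n_subjects, "converged": f.converged,
        })
    return pd.DataFrame(rows)


def slope_fits_to_frame(fits) -> pd.DataFrame:
    """Like :func:`fits_to_frame` but reporting the slope (dose-response)
    parameters mu_beta / sd_beta, matching the slope-table layout."""
    rows = []
    for f in fits:
        rows.append({
            "marker": f.marker, "timepoint": f.timepoint, "scale": f.scale,
            "est_mean": f.mu_beta_hat, "ci_mean_lo": f.ci_mu_beta[0],
            "ci_mean_hi": f.ci_mu_beta[1], "p_mean": f.p_mu_beta,
            "est_sd": f.sd_beta_hat,
            "ci_sd_lo": None if f.ci_sd_beta is None else f.ci_sd_beta[0],
            "ci_sd_hi": None if f.ci_sd_beta is None else f.ci_sd_beta[1],
            "p_sd": f.p_sd_beta,
            "n_subjects": f.n_subjects, "converged": f.converged,
        })
    return pd.DataFrame(rows)
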