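"""Restricted maximum likelihood engine for the individual-response model.

The model for change value ``delta_il`` of subject i at centered load code
l is

    delta_il = mu_alpha + mu_beta * l + a_i + b_i * l + eps_il

with (a_i, b_i) ~ N(0, Psi) bivariate normal and eps i.i.d. N(0, sd_error^2).
Fixed effects are always (intercept, load); the random-effect structure is
configurable so that the nested reduced models needed for boundary
likelihood-ratio tests — random intercept only, random slope only — can be
fitted with identical fixed effects (a valid REML comparison).

The REML criterion is maximized over the residual SD and the Cholesky
factor of Psi, parametrized on the direct scale with nonnegativity bounds
on the diagonal so that boundary solutions land exactly at zero.  The
Cholesky is ordered with a chosen random effect first, which makes its SD a
single parameter that can be fixed — the device used for profile-likelihood
confidence intervals.

Fixed effects are profiled out by generalized least squares at each
candidate covariance, so the optimization runs over at most four free
parameters.  Subjects sharing a load pattern share one 3x3 covariance
factorization, which keeps a fit of a balanced 24-subject dataset in the
millisecond range — fast enough for the 1000-replicate power simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

BOUNDARY_TOL = 1e-6
_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class LMMData:
    """Change values grouped by subject, with per-pattern caching."""

    y_groups: list[np.ndarray]          # stacked responses per load pattern
    load_patterns: list[np.ndarray]     # unique sorted load-code vectors
    n_subjects: int
    n_obs: int

    @classmethod
    def from_arrays(cls, delta, load, subject) -> "LMMData":
        delta = np.asarray(delta, dtype=float)
        load = np.asarray(load, dtype=float)
        subject = np.asarray(subject)
        order = np.lexsort((load, subject))
        delta, load, subject = delta[order], load[order], subject[order]
        patterns: dict[tuple, list[np.ndarray]] = {}
        for sid in pd_unique(subject):
            sel = subject == sid
            key = tuple(load[sel])
            patterns.setdefault(key, []).append(delta[sel])
        y_groups, load_patterns = [], []
        for key, ys in patterns.items():
            load_patterns.append(np.asarray(key, dtype=float))
            y_groups.append(np.vstack(ys))
        n_subj = sum(len(g) for g in y_groups)
        n_obs = sum(g.size for g in y_groups)
        return cls(y_groups, load_patterns, n_subj, n_obs)


def pd_unique(arr):
    """Unique values preserving first-appearance order."""
    _, idx = np.unique(arr, return_index=True)
    return arr[np.sort(idx)]


@dataclass
class REMLFit:
    effects: tuple[str, ...]            # random effects, Cholesky order
    fixed: np.ndarray                   # (mu_alpha, mu_beta)
    se_fixed: np.ndarray
    sd_re: dict                         # SD per random effect
    corr: float | None                  # random-effect correlation (full model)
    sd_error: float
    loglik: float                       # restricted log-likelihood
    converged: bool
    boundary: dict = field(default_factory=dict)
    n_subjects: int = 0
    n_obs: int = 0

    @property
    def mu_alpha(self):
        return float(self.fixed[0])

    @property
    def mu_beta(self):
        return float(self.fixed[1])


def _chol_solve(cf: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve V x = b given the lower Cholesky factor of V via two
    triangular solves (stable down to near-singular V)."""
    from scipy.linalg import solve_triangular
    z = solve_triangular(cf, b, lower=True)
    return solve_triangular(cf.T, z, lower=False)


def _design(effects: tuple[str, ...], loads: np.ndarray) -> np.ndarray:
    cols = {"intercept": np.ones_like(loads), "slope": loads}
    return np.column_stack([cols[e] for e in effects])


def _neg_reml(theta, data: LMMData, effects, fixed_sd):
    """Negative restricted log-likelihood at covariance parameters theta.

    theta = [sd_error, chol entries...]; if ``fixed_sd`` is not None the
    leading Cholesky diagonal (the SD of effects[0]) is held at that value
    and excluded from theta.
    """
    q = len(effects)
    sd_error = theta[0]
    chol_entries = list(theta[1:])
    if fixed_sd is not None:
        chol_entries = [fixed_sd] + chol_entries
    L = np.zeros((q, q))
    pos = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = chol_entries[pos]
            pos += 1
    Psi = L @ L.T
    p = 2  # fixed effects: intercept + load
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for loads, Y in zip(data.load_patterns, data.y_groups):
        n_i, k = Y.shape[1], Y.shape[0]
        Z = _design(effects, loads)
        X = np.column_stack([np.ones(n_i), loads])
        V = Z @ Psi @ Z.T + (sd_error ** 2) * np.eye(n_i)
        try:
            cf = np.linalg.cholesky(V)
            Vinv_X = _chol_solve(cf, X)        # n_i x p
            W = _chol_solve(cf, Y.T)           # n_i x k
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * k * np.log(np.diag(cf)).sum()
        XtViX += k * (X.T @ Vinv_X)
        XtViy += X.T @ W.sum(axis=1)
        ytViy += float((Y.T * W).sum())
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - float(beta @ XtViy)
    n_eff = data.n_obs - p
    return 0.5 * (n_eff * _LOG2PI + logdet + logdet_X + quad)


def _fixed_effects_at(theta, data: LMMData, effects, fixed_sd):
    """Fixed-effect GLS estimates and covariance at given theta."""
    q = len(effects)
    sd_error = theta[0]
    chol_entries = list(theta[1:])
    if fixed_sd is not None:
        chol_entries = [fixed_sd] + chol_entries
    L = np.zeros((q, q))
    pos = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = chol_entries[pos]
            pos += 1
    Psi = L @ L.T
    XtViX = np.zeros((2, 2))
    XtViy = np.zeros(2)
    for loads, Y in zip(data.load_patterns, data.y_groups):
        n_i, k = Y.shape[1], Y.shape[0]
        Z = _design(effects, loads)
        X = np.column_stack([np.ones(n_i), loads])
        V = Z @ Psi @ Z.T + (sd_error ** 2) * np.eye(n_i)
        cf = np.linalg.cholesky(V)
        XtViX += k * (X.T @ _chol_solve(cf, X))
        W = _chol_solve(cf, Y.T)
        XtViy += X.T @ W.sum(axis=1)
    cov = np.linalg.inv(XtViX)
    beta = cov @ XtViy
    return beta, cov, L, sd_error


def _moment_starts(data: LMMData):
    """Per-subject OLS moments for starting values."""
    intercepts, slopes, resid_ss, resid_n = [], [], 0.0, 0
    for loads, Y in zip(data.load_patterns, data.y_groups):
        X = np.column_stack([np.ones_like(loads), loads])
        if len(loads) >= 2 and np.ptp(loads) > 0:
            coef, res, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
            intercepts.extend(coef[0])
            slopes.extend(coef[1])
            if len(loads) > 2:
                fitted = X @ coef
                resid_ss += float(((Y.T - fitted) ** 2).sum())
                resid_n += (len(loads) - 2) * Y.shape[0]
        else:
            intercepts.extend(Y.mean(axis=1))
    scale = max(float(np.std(np.concatenate(data.y_groups, axis=None))), 1e-6)
    sd_e = math.sqrt(resid_ss / resid_n) if resid_n > 0 else 0.5 * scale
    sd_a = float(np.std(intercepts)) if len(intercepts) > 1 else 0.5 * scale
    sd_b = float(np.std(slopes)) if len(slopes) > 1 else 0.5 * scale
    return (max(sd_e, 0.05 * scale), max(sd_a, 0.05 * scale),
            max(sd_b, 0.05 * scale), scale)


def _exact_interpolation(data: LMMData, effects, floor, scale) -> "REMLFit | None":
    """Handle noise-free degenerate input: if the pooled fixed-effects OLS
    interpolates every observation, all variance components are 0 at the
    boundary and optimization is unnecessary (and ill-conditioned).  The
    restricted log-likelihood is evaluated at the floored residual SD so
    that nested model comparisons on the same data cancel exactly."""
    X_all = np.vstack([np.tile(np.column_stack([np.ones_like(l), l]),
                               (len(Y), 1))
                       for l, Y in zip(data.load_patterns, data.y_groups)])
    y_all = np.concatenate([Y.ravel() for Y in data.y_groups])
    beta, *_ = np.linalg.lstsq(X_all, y_all, rcond=None)
    resid = y_all - X_all @ beta
    if np.abs(resid).max() > 1e-9 * max(scale, 1.0):
        return None
    q = len(effects)
    theta = np.zeros(1 + q * (q + 1) // 2)
    theta[0] = floor
    loglik = -_neg_reml(theta, data, effects, None)
    _, cov, _, _ = _fixed_effects_at(theta, data, effects, None)
    return REMLFit(
        effects=tuple(effects), fixed=beta, se_fixed=np.sqrt(np.diag(cov)),
        sd_re={e: 0.0 for e in effects},
        corr=0.0 if q == 2 else None, sd_error=0.0, loglik=loglik,
        converged=True, boundary={e: True for e in effects},
        n_subjects=data.n_subjects, n_obs=data.n_obs)


def fit_lmm(delta, load, subject,
            effects: tuple[str, ...] = ("intercept", "slope"),
            fixed_sd: float | None = None,
            n_restarts: int = 5, tol: float = 1e-8,
            seed: int = 0) -> REMLFit:
    """REML fit of the response model with the given random-effect set.

    ``effects`` lists the random effects in Cholesky order; put the effect
    whose SD is profiled first and pass ``fixed_sd`` to constrain it.
    Restarts from jittered starting values guard against local optima; the
    fit is flagged non-converged only if every start fails.
    """
    data = delta if isinstance(delta, LMMData) else LMMData.from_arrays(
        delta, load, subject)
    q = len(effects)
    sd_e0, sd_a0, sd_b0, scale = _moment_starts(data)
    start_sd = {"intercept": sd_a0, "slope": sd_b0}
    # residual-SD floor: keeps V invertible; 1e-6 of the data scale caps the
    # condition number near 1e12, well inside float64 headroom
    floor = max(1e-12, 1e-6 * scale)

    exact = _exact_interpolation(data, effects, floor, scale)
    if exact is not None:
        return exact

    def pack_start(jitter_rng=None):
        vals = [sd_e0]
        diag0 = [start_sd[e] for e in effects]
        pos = 0
        for i in range(q):
            for j in range(i + 1):
                vals.append(diag0[i] if i == j else 0.0)
                pos += 1
        if fixed_sd is not None:
            vals.pop(1)  # leading Cholesky diagonal is fixed
        v = np.asarray(vals, dtype=float)
        if jitter_rng is not None:
            v = v * np.exp(0.5 * jitter_rng.standard_normal(v.size))
            v[v == 0] = 0.3 * scale * jitter_rng.random()
        return v

    # bounds: sd_error floored away from 0; Cholesky diagonals >= 0
    bounds = [(floor, None)]
    pos = 0
    for i in range(q):
        for j in range(i + 1):
            if fixed_sd is not None and i == 0 and j == 0:
                continue
            bounds.append((0.0, None) if i == j else (None, None))

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for attempt in range(n_restarts + 1):
        x0 = pack_start(None if attempt == 0 else rng)
        res = optimize.minimize(
            _neg_reml, x0, args=(data, effects, fixed_sd),
            method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
        if res.success and res.fun < 1e11:
            converged = True
            break
    near_floor = best.fun < 1e11 and best.x[0] <= 5.0 * floor
    if (not converged or near_floor) and best.fun < 1e11:
        # gradient-based line searches are unreliable on the noise floor of
        # the criterion when the residual SD collapses to its bound; polish
        # with a bounded derivative-free simplex search
        nm = optimize.minimize(
            _neg_reml, best.x, args=(data, effects, fixed_sd),
            method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-8 * scale, "fatol": 1e-8, "maxiter": 2000})
        if nm.fun <= best.fun:
            best = nm
        converged = converged or bool(nm.success)
    theta = best.x
    beta, cov, L, sd_error = _fixed_effects_at(theta, data, effects, fixed_sd)
    diag = np.diag(L)
    sd_re = {}
    boundary = {}
    for i, e in enumerate(effects):
        s = float(np.sqrt((L[i, :i + 1] ** 2).sum()))
        s = 0.0 if s < BOUNDARY_TOL * scale else s
        sd_re[e] = s
        boundary[e] = s == 0.0
    corr = None
    if q == 2:
        s0, s1 = sd_re[effects[0]], sd_re[effects[1]]
        if s0 > 0 and s1 > 0:
            corr = float(np.clip((L @ L.T)[0, 1] / (s0 * s1), -1.0, 1.0))
        else:
            corr = 0.0
    sd_error = 0.0 if sd_error <= 2 * floor else float(sd_error)
    return REMLFit(
        effects=tuple(effects), fixed=beta,
        se_fixed=np.sqrt(np.diag(cov)), sd_re=sd_re, corr=corr,
        sd_error=sd_error, loglik=-float(best.fun), converged=converged,
        boundary=boundary, n_subjects=data.n_subjects, n_obs=data.n_obs)


# ---------------------------------------------------------------------------
# boundary likelihood-ratio machinery

def mixture_sf(q: float, dfs: tuple[int, int]) -> float:
    """Tail probability of a 50:50 mixture of chi-square distributions.

    A chi-square with 0 degrees of freedom is a point mass at 0, so for the
    (0, 1) mixture the tail at q > 0 is 0.5 * P(chi2_1 >= q).
    """
    if q <= 0:
        return 1.0
    tails = [stats.chi2.sf(q, df) if df > 0 else 0.0 for df in dfs]
    return float(0.5 * (tails[0] + tails[1]))


def mixture_quantile(alpha: float, dfs: tuple[int, int]) -> float:
    """Upper-alpha quantile of the 50:50 chi-square mixture."""
    if mixture_sf(0.0, dfs) <= alpha:
        return 0.0
    return float(optimize.brentq(lambda q: mixture_sf(q, dfs) - alpha,
                                 1e-12, 200.0))


def lrt_boundary(full: REMLFit, reduced: REMLFit,
                 dfs: tuple[int, int]) -> tuple[float, float]:
    """Boundary LRT statistic (clipped at 0) and mixture chi-square p-value."""
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return stat, mixture_sf(stat, dfs)


def profile_sd_interval(data_or_arrays, which: str,
                        other: str | None, level: float = 0.95,
                        seed: int = 0) -> tuple[float, float]:
    """Profile-REML confidence interval for a random-effect SD.

    The interval collects all SD values whose profile restricted deviance
    stays below the upper-alpha quantile of the same chi-square mixture
    used by the boundary test (so an SD of 0 lies in the interval exactly
    when the boundary test is non-significant at 1 - level).  The upper
    bound is reported as infinity when the profile stays below the
    threshold over the whole searched range (200x the data scale), i.e.
    the data place no practical upper limit on the SD.
    """
    if isinstance(data_or_arrays, LMMData):
        data = data_or_arrays
    else:
        data = LMMData.from_arrays(*data_or_arrays)
    effects = (which,) if other is None else (which, other)
    dfs = (0, 1) if other is None else (1, 2)
    alpha = 1.0 - level
    qcrit = mixture_quantile(alpha, dfs)
    full = fit_lmm(data, None, None, effects=effects, seed=seed)
    llmax = full.loglik
    sd_hat = full.sd_re[which]
    scale = max(sd_hat, full.sd_error, 1e-3)

    def deviance(s):
        r = fit_lmm(data, None, None, effects=effects, fixed_sd=s, seed=seed)
        return 2.0 * (llmax - r.loglik)

    # lower bound
    if deviance(0.0) <= qcrit:
        lower = 0.0
    else:
        lower = float(optimize.brentq(lambda s: deviance(s) - qcrit,
                                      1e-9 * scale, max(sd_hat, 1e-9 * scale),
                                      xtol=1e-4 * scale))
    # upper bound
    hi = max(2.0 * scale, sd_hat + scale)
    cap = 200.0 * scale
    while deviance(hi) <= qcrit:
        hi *= 2.0
        if hi > cap:
            return lower, math.inf
    lo_bracket = max(sd_hat, 1e-9 * scale)
    upper = float(optimize.brentq(lambda s: deviance(s) - qcrit,
                                  lo_bracket, hi, xtol=1e-4 * scale))
    return lower, upper
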