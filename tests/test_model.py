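"""Response-model fitting: exact cases, identities, oracles, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from loadresponse import SimulationConfig, simulate_change_values
from loadresponse.errors import InputIntegrityError
from loadresponse.model import fit_response_model
from loadresponse.model import test_mean as wald_mean_inference
from loadresponse.reml import (LMMData, fit_lmm, lrt_boundary, mixture_sf,
                               profile_sd_interval)

from conftest import make_change_table


def brute_force_reml(delta, load, subject, effects=("intercept", "slope")):
    """Independent REML oracle: the restricted likelihood evaluated from the
    full stacked covariance matrix with generic dense linear algebra (the
    P-matrix form), maximized by differential evolution plus a simplex
    polish.  Shares no code path with the package engine."""
    delta = np.asarray(delta, float)
    load = np.asarray(load, float)
    subject = np.asarray(subject)
    subjects = list(dict.fromkeys(subject))
    X = np.column_stack([np.ones_like(load), load])
    n, p = len(delta), 2

    def build_V(params):
        if len(effects) == 2:
            sde, sa, sb, rho = params
            Psi = np.array([[sa ** 2, rho * sa * sb],
                            [rho * sa * sb, sb ** 2]])
        else:
            sde, s = params
            Psi = np.array([[s ** 2]])
        V = np.zeros((n, n))
        for sid in subjects:
            idx = np.where(subject == sid)[0]
            cols = {"intercept": np.ones(len(idx)), "slope": load[idx]}
            Z = np.column_stack([cols[e] for e in effects])
            V[np.ix_(idx, idx)] = Z @ Psi @ Z.T
        return V + sde ** 2 * np.eye(n)

    def neg_restricted_ll(params):
        V = build_V(params)
        sign, logdetV = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e12
        Vinv = np.linalg.inv(V)
        XtViX = X.T @ Vinv @ X
        sign2, logdetX = np.linalg.slogdet(XtViX)
        if sign2 <= 0:
            return 1e12
        P = Vinv - Vinv @ X @ np.linalg.inv(XtViX) @ X.T @ Vinv
        quad = float(delta @ P @ delta)
        return 0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX + quad)

    scale = float(np.std(delta))
    if len(effects) == 2:
        bounds = [(1e-4 * scale, 4 * scale), (0, 4 * scale),
                  (0, 4 * scale), (-1.0, 1.0)]
    else:
        bounds = [(1e-4 * scale, 4 * scale), (0, 4 * scale)]
    de = optimize.differential_evolution(neg_restricted_ll, bounds, seed=0,
                                         tol=1e-10, maxiter=400)
    nm = optimize.minimize(neg_restricted_ll, de.x, method="Nelder-Mead",
                           bounds=bounds,
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
    best = nm if nm.fun <= de.fun else de
    V = build_V(best.x)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ delta)
    return {"loglik": -best.fun, "beta": beta, "params": best.x}


class TestExactCases:
    def test_noise_free_interpolating_data(self):
        table = make_change_table({s: (3, 5, 7) for s in range(1, 7)})
        fit = fit_response_model(table, compute_sd_tests=False,
                                 compute_sd_cis=False)
        assert fit.mu_alpha_hat == pytest.approx(5.0)
        assert fit.mu_beta_hat == pytest.approx(2.0)
        assert fit.sd_alpha_hat == 0.0
        assert fit.sd_beta_hat == 0.0
        assert fit.sd_error_hat == 0.0
        assert fit.boundary == {"intercept": True, "slope": True}

    def test_all_identical_deltas_hit_boundary_without_error(self):
        table = make_change_table({s: (4, 4, 4) for s in range(1, 5)})
        fit = fit_response_model(table, compute_sd_tests=False,
                                 compute_sd_cis=False)
        assert fit.mu_alpha_hat == pytest.approx(4.0)
        assert fit.sd_alpha_hat == fit.sd_beta_hat == 0.0

    def test_two_subjects_with_flat_heterogeneous_levels(self):
        """Triples (0,0,0) and (10,10,10): intercept variation without
        slope variation; the intercept SD is the REML between-subject SD
        sqrt(50)."""
        table = make_change_table({1: (0, 0, 0), 2: (10, 10, 10)})
        fit = fit_response_model(table, compute_sd_tests=False,
                                 compute_sd_cis=False)
        assert fit.mu_alpha_hat == pytest.approx(5.0, abs=1e-6)
        assert fit.mu_beta_hat == pytest.approx(0.0, abs=1e-6)
        assert fit.sd_alpha_hat == pytest.approx(np.sqrt(50.0), abs=0.05)
        assert fit.sd_beta_hat == 0.0

    def test_too_few_subjects_rejected(self):
        table = make_change_table({1: (1, 2, 3)})
        with pytest.raises(InputIntegrityError):
            fit_response_model(table)


class TestBalancedDataIdentities:
    def test_fixed_effects_equal_closed_forms(self, clinical_changes):
        """On balanced complete data the REML fixed effects reduce to the
        grand mean (centered loads) and the half-difference of the extreme
        load means."""
        fit = fit_response_model(clinical_changes, compute_sd_tests=False,
                                 compute_sd_cis=False)
        wide = clinical_changes.pivot(index="subject_id", columns="load_code",
                                      values="delta")
        assert fit.mu_alpha_hat == pytest.approx(
            wide.to_numpy().mean(), abs=1e-5)
        assert fit.mu_beta_hat == pytest.approx(
            (wide[1].mean() - wide[-1].mean()) / 2.0, abs=1e-5)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [2, 9])
    def test_full_model_matches_brute_force(self, seed):
        cfg = SimulationConfig(n_subjects=3, seed=seed)
        t = simulate_change_values(cfg)
        delta = t["delta"].to_numpy()
        load = t["load_code"].to_numpy(float)
        subj = t["subject_id"].to_numpy()
        mine = fit_lmm(delta, load, subj)
        oracle = brute_force_reml(delta, load, subj)
        assert mine.loglik == pytest.approx(oracle["loglik"], abs=1e-3)
        assert mine.mu_alpha == pytest.approx(oracle["beta"][0], abs=1e-3)
        assert mine.mu_beta == pytest.approx(oracle["beta"][1], abs=1e-3)

    def test_reduced_model_matches_brute_force(self):
        cfg = SimulationConfig(n_subjects=3, seed=2)
        t = simulate_change_values(cfg)
        delta = t["delta"].to_numpy()
        load = t["load_code"].to_numpy(float)
        subj = t["subject_id"].to_numpy()
        mine = fit_lmm(delta, load, subj, effects=("intercept",))
        oracle = brute_force_reml(delta, load, subj, effects=("intercept",))
        assert mine.loglik == pytest.approx(oracle["loglik"], abs=1e-3)

    def test_matches_statsmodels_mixedlm(self, clinical_changes):
        """Independent cross-check of the full fit on a 24-subject dataset
        against statsmodels' REML MixedLM."""
        sm = pytest.importorskip("statsmodels.api")
        df = clinical_changes
        exog = sm.add_constant(pd.DataFrame({"l": df["load_code"].astype(float)}))
        res = sm.MixedLM(df["delta"], exog, groups=df["subject_id"],
                         exog_re=exog).fit(reml=True)
        mine = fit_response_model(df, compute_sd_tests=False,
                                  compute_sd_cis=False)
        assert mine.mu_alpha_hat == pytest.approx(res.fe_params.iloc[0],
                                                  abs=1e-4)
        assert mine.mu_beta_hat == pytest.approx(res.fe_params.iloc[1],
                                                 abs=1e-4)
        assert mine.sd_alpha_hat == pytest.approx(
            np.sqrt(res.cov_re.iloc[0, 0]), rel=1e-3)
        assert mine.sd_beta_hat == pytest.approx(
            np.sqrt(res.cov_re.iloc[1, 1]), rel=1e-3)
        assert mine.sd_error_hat == pytest.approx(np.sqrt(res.scale),
                                                  rel=1e-3)


class TestInference:
    def test_wald_p_is_one_at_null_estimate(self):
        table = make_change_table({1: (-1, 0, 1), 2: (1, 0, -1),
                                   3: (-2, 0, 2), 4: (2, 0, -2)})
        fit = fit_response_model(table, compute_sd_tests=False,
                                 compute_sd_cis=False)
        est, ci, p = wald_mean_inference(fit, "alpha")
        assert est == pytest.approx(0.0, abs=1e-8)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_wald_quantile_identity(self):
        """An estimate equal to 1.96 standard errors gives p close to 5%."""
        z = stats.norm.isf(0.025)
        p = 2 * stats.norm.sf(z)
        assert p == pytest.approx(0.05, abs=1e-12)

    @pytest.mark.parametrize("q, dfs, expected", [
        (0.0, (1, 2), 1.0),
        (0.0, (0, 1), 1.0),
        (2.706, (0, 1), 0.5 * stats.chi2.sf(2.706, 1)),
    ])
    def test_mixture_tail_values(self, q, dfs, expected):
        assert mixture_sf(q, dfs) == pytest.approx(expected)
        if q == 2.706 and dfs == (0, 1):
            assert mixture_sf(q, dfs) == pytest.approx(0.05, abs=1e-3)

    def test_lrt_statistic_clipped_at_zero(self, clinical_changes):
        data = LMMData.from_arrays(
            clinical_changes["delta"].to_numpy(),
            clinical_changes["load_code"].to_numpy(float),
            clinical_changes["subject_id"].to_numpy())
        full = fit_lmm(data, None, None)
        stat, p = lrt_boundary(full, full, dfs=(1, 2))
        assert stat == 0.0 and p == 1.0

    def test_sd_test_p_small_with_strong_heterogeneity(self):
        """Constructed data with large spread in both per-subject levels and
        per-subject slopes plus small noise: both boundary tests reject."""
        rng = np.random.default_rng(0)
        table = make_change_table({
            s: tuple(3.0 * s + 2.0 * s * l + rng.normal(0, 0.5)
                     for l in (-1, 0, 1))
            for s in range(1, 13)})
        fit = fit_response_model(table, compute_sd_cis=False)
        assert 0.0 <= fit.p_sd_alpha < 0.05
        assert 0.0 <= fit.p_sd_beta < 0.05


class TestProfileCI:
    def test_interval_contains_estimate(self, clinical_changes):
        fit = fit_response_model(clinical_changes, compute_sd_tests=False,
                                 compute_sd_cis=True)
        lo, hi = fit.ci_sd_alpha
        assert lo <= fit.sd_alpha_hat <= hi
        lo, hi = fit.ci_sd_beta
        assert lo <= fit.sd_beta_hat <= hi

    def test_boundary_estimate_gives_zero_lower_bound(self):
        """With no between-subject structure the SD estimate is 0, the lower
        bound is exactly 0 (the boundary-test-consistent interval), and the
        upper bound reflects weak information: the interval is wide relative
        to any slope heterogeneity the data could show."""
        rng = np.random.default_rng(1)
        table = make_change_table(
            {s: tuple(rng.normal(0, 1, 3)) for s in range(1, 9)})
        fit = fit_response_model(table, compute_sd_tests=True,
                                 compute_sd_cis=True)
        lo, hi = fit.ci_sd_beta
        assert lo == 0.0
        assert fit.p_sd_beta > 0.05  # 0 is inside <=> test non-significant
        assert hi > fit.sd_beta_hat

    def test_noise_free_heterogeneous_intercepts_exclude_zero(self):
        table = make_change_table({1: (0, 0, 0), 2: (10, 10, 10),
                                   3: (20, 20, 20), 4: (-10, -10, -10)})
        data = (table["delta"].to_numpy(),
                table["load_code"].to_numpy(float),
                table["subject_id"].to_numpy())
        lo, hi = profile_sd_interval(data, "intercept", "slope")
        assert lo > 0.0

    def test_coverage_on_simulated_data(self):
        """The profile interval for the intercept SD covers the generating
        value in about 95% of replicates (checked loosely at 40 reps)."""
        hits = 0
        reps = 40
        for seed in range(reps):
            cfg = SimulationConfig(n_subjects=60, sd_alpha=10.0, seed=seed)
            t = simulate_change_values(cfg)
            data = (t["delta"].to_numpy(), t["load_code"].to_numpy(float),
                    t["subject_id"].to_numpy())
            lo, hi = profile_sd_interval(data, "intercept", "slope")
            hits += lo <= 10.0 <= hi
        assert hits / reps >= 0.85


class TestRecovery:
    def test_parameter_recovery_moderate_n(self):
        cfg = SimulationConfig(n_subjects=200, seed=17)
        t = simulate_change_values(cfg)
        fit = fit_response_model(t, compute_sd_tests=False,
                                 compute_sd_cis=False)
        assert fit.mu_alpha_hat == pytest.approx(5.0, rel=0.15)
        assert fit.mu_beta_hat == pytest.approx(5.0, rel=0.15)
        assert fit.sd_alpha_hat == pytest.approx(5.0, rel=0.2)
        assert fit.sd_beta_hat == pytest.approx(5.0, rel=0.2)
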