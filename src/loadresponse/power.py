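"""Monte-Carlo power study for the four response-model parameters.

Each replicate simulates a 24-subject crossover dataset from the
individual-response model, fits the random-intercept/random-slope model by
REML, and records rejections at the 5% level: two-sided Wald tests for the
means mu_alpha and mu_beta, boundary mixture chi-square likelihood-ratio
tests for the SDs sd_alpha and sd_beta.  Powers are rejection proportions
over the converged replicates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import reml
from .config import SimulationConfig
from .synthetic import simulate_change_values

log = logging.getLogger(__name__)

PARAMS = ("mu_alpha", "sd_alpha", "mu_beta", "sd_beta")


@dataclass(frozen=True)
class PowerScenario:
    mu_alpha: float = 5.0
    sd_alpha: float = 5.0
    mu_beta: float = 5.0
    sd_beta: float = 5.0
    rho_alpha_beta: float = 0.0
    sd_error: float = 5.0
    n_subjects: int = 24
    n_reps: int = 1000
    alpha: float = 0.05

    def to_sim_config(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            n_subjects=self.n_subjects, mu_alpha=self.mu_alpha,
            sd_alpha=self.sd_alpha, mu_beta=self.mu_beta,
            sd_beta=self.sd_beta, rho_alpha_beta=self.rho_alpha_beta,
            sd_error=self.sd_error, seed=seed).validate()


@dataclass
class PowerTable:
    scenario: PowerScenario
    seed: int
    power: dict = field(default_factory=dict)       # param -> proportion
    mc_se: dict = field(default_factory=dict)       # param -> binomial SE
    n_converged: int = 0
    n_reps: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"parameter": p, "power": self.power[p],
                 "mc_se": self.mc_se[p]} for p in PARAMS]
        df = pd.DataFrame(rows)
        for f in ("mu_alpha", "sd_alpha", "mu_beta", "sd_beta", "sd_error",
                  "n_subjects", "n_reps", "alpha"):
            df[f"scenario_{f}"] = getattr(self.scenario, f)
        df["seed"] = self.seed
        df["n_converged"] = self.n_converged
        return df

    def summary(self) -> str:
        s = self.scenario
        head = (f"Power at alpha={s.alpha:g}, n={s.n_subjects}, "
                f"sd_error={s.sd_error:g} "
                f"(mu_a={s.mu_alpha:g}, sd_a={s.sd_alpha:g}, "
                f"mu_b={s.mu_beta:g}, sd_b={s.sd_beta:g}; "
                f"{self.n_converged}/{self.n_reps} replicates)")
        body = "\n".join(
            f"  {p:9s}: {100 * self.power[p]:5.1f}%  "
            f"(MC SE {100 * self.mc_se[p]:.1f})" for p in PARAMS)
        return head + "\n" + body


def _one_replicate(scenario: PowerScenario, seed: int) -> dict | None:
    cfg = scenario.to_sim_config(seed)
    table = simulate_change_values(cfg)
    data = reml.LMMData.from_arrays(table["delta"].to_numpy(),
                                    table["load_code"].to_numpy(dtype=float),
                                    table["subject_id"].to_numpy())
    full = reml.fit_lmm(data, None, None, effects=("intercept", "slope"))
    red_slope = reml.fit_lmm(data, None, None, effects=("slope",))
    red_int = reml.fit_lmm(data, None, None, effects=("intercept",))
    if not (full.converged and red_slope.converged and red_int.converged):
        return None
    alpha = scenario.alpha
    p_mu_a = 2 * stats.norm.sf(abs(full.mu_alpha) / full.se_fixed[0])
    p_mu_b = 2 * stats.norm.sf(abs(full.mu_beta) / full.se_fixed[1])
    _, p_sd_a = reml.lrt_boundary(full, red_slope, dfs=(1, 2))
    _, p_sd_b = reml.lrt_boundary(full, red_int, dfs=(1, 2))
    return {"mu_alpha": p_mu_a < alpha, "sd_alpha": p_sd_a < alpha,
            "mu_beta": p_mu_b < alpha, "sd_beta": p_sd_b < alpha}


def run_power_study(scenario: PowerScenario, seed: int = 0) -> PowerTable:
    """Rejection proportions for the four parameters under one scenario.

    Replicate seeds are spawned deterministically from ``seed``; replicates
    with any non-converged fit are excluded and counted, with a warning if
    they exceed 5% of the total.
    """
    if scenario.n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    child_seeds = np.random.SeedSequence(seed).generate_state(scenario.n_reps)
    rejections = {p: 0 for p in PARAMS}
    n_conv = 0
    for rep_seed in child_seeds:
        res = _one_replicate(scenario, int(rep_seed) % (2 ** 31))
        if res is None:
            continue
        n_conv += 1
        for p in PARAMS:
            rejections[p] += res[p]
    if n_conv < 0.95 * scenario.n_reps:
        log.warning("run_power_study: %d/%d replicates failed to converge",
                    scenario.n_reps - n_conv, scenario.n_reps)
    power = {p: rejections[p] / n_conv for p in PARAMS}
    mc_se = {p: math.sqrt(power[p] * (1 - power[p]) / n_conv) for p in PARAMS}
    return PowerTable(scenario=scenario, seed=seed, power=power, mc_se=mc_se,
                      n_converged=n_conv, n_reps=scenario.n_reps)


def run_power_grid(base: PowerScenario, sd_errors=(5.0, 7.0),
                   seed: int = 0) -> pd.DataFrame:
    """Power table over a grid of residual SDs (the headline comparison:
    how inter-individual variation becomes hard to detect as assay/
    biological noise grows)."""
    frames = []
    for i, sd_e in enumerate(sd_errors):
        table = run_power_study(replace(base, sd_error=sd_e), seed=seed + i)
        frames.append(table.to_frame())
    return pd.concat(frames, ignore_index=True)
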