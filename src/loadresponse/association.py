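"""Interrelationships among suitable markers.

Two kinds of association are quantified between marker/timepoint
combinations:

* correlation of the **individual changes**: the Spearman correlation is
  computed within each load level and the three values are averaged, so
  within-subject dependence across the three test days never contaminates
  a single correlation; inference uses a subject-level bootstrap with a
  normal approximation on the Fisher z scale;
* correlation of the **individual dose-response slopes**: each subject's
  OLS slope of change on load code (equal to (delta(+1) - delta(-1))/2
  with complete, equally spaced loads), compared across subjects by plain
  Spearman correlation.

Ties are handled by midranks throughout (scipy's default).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError

log = logging.getLogger(__name__)


def individual_slopes(changes: pd.DataFrame) -> pd.DataFrame:
    """Per-subject dose-response slope of delta on the load code.

    Returns one row per subject x marker x timepoint (x scale) with the
    OLS slope over the available load levels; subjects with fewer than two
    load levels are skipped with a log entry.
    """
    group_cols = [c for c in ("subject_id", "marker", "timepoint", "scale")
                  if c in changes.columns]
    rows = []
    n_skipped = 0
    for key, grp in changes.groupby(group_cols, sort=False):
        loads = grp["load_code"].to_numpy(dtype=float)
        if len(np.unique(loads)) < 2:
            n_skipped += 1
            continue
        slope = np.polyfit(loads, grp["delta"].to_numpy(dtype=float), 1)[0]
        rows.append(dict(zip(group_cols, key if isinstance(key, tuple)
                             else (key,))) | {"slope": float(slope)})
    if n_skipped:
        log.warning("individual_slopes: skipped %d subject cell(s) with <2 "
                    "load levels", n_skipped)
    return pd.DataFrame(rows)


def _spearman_pairs(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with midranks (Pearson correlation of the ranks);
    NaN when either input is constant."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def _per_load_arrays(a: pd.DataFrame, b: pd.DataFrame):
    """Align two change slices on subjects; one (x, y) pair of arrays per
    load code, NaN where a subject's value is missing."""
    subjects = sorted(set(a["subject_id"]) | set(b["subject_id"]))
    sub_idx = {s: i for i, s in enumerate(subjects)}
    loads = sorted(set(a["load_code"]) | set(b["load_code"]))
    out = []
    for load in loads:
        x = np.full(len(subjects), np.nan)
        y = np.full(len(subjects), np.nan)
        ga = a[a["load_code"] == load]
        gb = b[b["load_code"] == load]
        x[[sub_idx[s] for s in ga["subject_id"]]] = ga["delta"].to_numpy()
        y[[sub_idx[s] for s in gb["subject_id"]]] = gb["delta"].to_numpy()
        out.append((load, x, y))
    return out, np.asarray(subjects)


def _avg_spearman_arrays(per_load, idx=None, min_pairs: int = 3,
                         warn: bool = False) -> float:
    rhos = []
    for load, x, y in per_load:
        if idx is not None:
            x, y = x[idx], y[idx]
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_pairs:
            if warn:
                log.warning("average_spearman: load %s dropped (%d pairs)",
                            load, int(ok.sum()))
            continue
        rho = _spearman_pairs(x[ok], y[ok])
        if math.isnan(rho):
            if warn:
                log.warning("average_spearman: load %s dropped "
                            "(constant input)", load)
            continue
        rhos.append(rho)
    if not rhos:
        raise UndefinedCorrelationError("no load level with enough pairs")
    return float(np.mean(rhos))


def average_spearman(changes_a: pd.DataFrame, changes_b: pd.DataFrame,
                     min_pairs: int = 3) -> float:
    """Mean of the per-load-level Spearman correlations of two change
    variables observed on the same subjects.  Load levels with fewer than
    ``min_pairs`` complete pairs (or constant values) are dropped with a
    warning."""
    per_load, _ = _per_load_arrays(changes_a, changes_b)
    return _avg_spearman_arrays(per_load, min_pairs=min_pairs, warn=True)


def bootstrap_correlation_inference(changes_a: pd.DataFrame,
                                    changes_b: pd.DataFrame,
                                    n_boot: int = 2000, seed: int = 0,
                                    level: float = 0.95,
                                    max_retries: int = 100) -> dict:
    """Subject-level bootstrap inference for the averaged Spearman rho.

    Subjects are resampled with replacement keeping each subject's full
    load profile intact; Fisher's z = atanh(rho_avg) is computed per
    replicate, and a normal approximation on the z scale yields the CI
    (back-transformed by tanh) and the two-sided p-value for rho = 0.
    Degenerate replicates (undefined correlation) are redrawn up to
    ``max_retries`` times each, then counted.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    per_load, subjects = _per_load_arrays(changes_a, changes_b)
    rho_hat = _avg_spearman_arrays(per_load, warn=True)
    rng = np.random.default_rng(seed)
    n = len(subjects)
    zs = []
    n_degenerate = 0
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            try:
                rho = _avg_spearman_arrays(per_load, idx=idx)
                break
            except UndefinedCorrelationError:
                continue
        else:
            n_degenerate += 1
            continue
        zs.append(math.atanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)))
    zs = np.asarray(zs)
    z_hat = math.atanh(np.clip(rho_hat, -1 + 1e-12, 1 - 1e-12))
    se = float(zs.std(ddof=1))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    if se == 0:
        ci = (rho_hat, rho_hat)
        p = 0.0 if rho_hat != 0 else 1.0
    else:
        ci = (math.tanh(z_hat - zq * se), math.tanh(z_hat + zq * se))
        p = 2.0 * stats.norm.sf(abs(z_hat) / se)
    return {"rho": rho_hat, "ci": ci, "p": float(p), "n_boot": len(zs),
            "n_degenerate": n_degenerate, "kind": "change"}


def slope_correlation(slopes_a: pd.DataFrame,
                      slopes_b: pd.DataFrame) -> dict:
    """Plain Spearman correlation of per-subject slopes across subjects."""
    merged = slopes_a.merge(slopes_b, on="subject_id", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise UndefinedCorrelationError(
            f"only {len(merged)} overlapping subjects")
    res = stats.spearmanr(merged["slope_a"], merged["slope_b"])
    return {"rho": float(res.statistic), "p": float(res.pvalue),
            "n": len(merged), "kind": "slope"}


def correlation_matrix(selected, changes: pd.DataFrame,
                       slopes: pd.DataFrame | None = None,
                       kind: str = "change", n_boot: int | None = None,
                       seed: int = 0):
    """Symmetric correlation and p-value matrices over selected combos.

    ``selected`` is a list of (marker, timepoint) pairs (the criterion-I
    survivors).  For ``kind="change"`` entries are averaged Spearman
    correlations (bootstrap p-values when ``n_boot`` is set, otherwise no
    p-matrix); for ``kind="slope"`` plain Spearman correlations of the
    per-subject slopes with asymptotic p-values.
    """
    labels = [f"{m} ({tp})" for m, tp in selected]
    n = len(selected)
    rho = pd.DataFrame(np.eye(n), index=labels, columns=labels)
    pval = pd.DataFrame(np.zeros((n, n)), index=labels, columns=labels)
    np.fill_diagonal(pval.values, np.nan)
    if kind == "slope" and slopes is None:
        slopes = individual_slopes(changes)

    def slice_changes(m, tp):
        return changes[(changes["marker"] == m)
                       & (changes["timepoint"] == tp)]

    def slice_slopes(m, tp):
        return slopes[(slopes["marker"] == m) & (slopes["timepoint"] == tp)]

    for i in range(n):
        for j in range(i + 1, n):
            mi, ti = selected[i]
            mj, tj = selected[j]
            if kind == "change":
                if n_boot:
                    est = bootstrap_correlation_inference(
                        slice_changes(mi, ti), slice_changes(mj, tj),
                        n_boot=n_boot, seed=seed + 1000 * i + j)
                    r, p = est["rho"], est["p"]
                else:
                    r = average_spearman(slice_changes(mi, ti),
                                         slice_changes(mj, tj))
                    p = np.nan
            else:
                est = slope_correlation(slice_slopes(mi, ti),
                                        slice_slopes(mj, tj))
                r, p = est["rho"], est["p"]
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval


def plot_heatmap(rho: pd.DataFrame, path, title: str = "") -> None:
    """Render a correlation matrix as a heat map image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(rho) + 2,) * 2)
    im = ax.imshow(rho.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(rho)), rho.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(rho)), rho.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Spearman rho")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
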