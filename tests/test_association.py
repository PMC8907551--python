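"""Marker interrelationships: slopes, averaged Spearman, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from loadresponse import (SimulationConfig, average_spearman,
                          bootstrap_correlation_inference, correlation_matrix,
                          individual_slopes, simulate_change_values,
                          slope_correlation)
from loadresponse.errors import UndefinedCorrelationError

from conftest import make_change_table


def change_rows(per_load_values, marker="A", timepoint="t1"):
    """per_load_values: {load: [values by subject index]}."""
    rows = []
    for load, vals in per_load_values.items():
        for sid, v in enumerate(vals, start=1):
            rows.append((sid, marker, load, timepoint, float(v), "relative"))
    return pd.DataFrame(rows, columns=[
        "subject_id", "marker", "load_code", "timepoint", "delta", "scale"])


class TestIndividualSlopes:
    @pytest.mark.parametrize("triple, expected", [
        ((0, 5, 10), 5.0),
        ((3, 3, 3), 0.0),
        ((2, 9, 4), 1.0),   # OLS slope = half-difference of the extremes
    ])
    def test_closed_form_on_complete_loads(self, triple, expected):
        table = make_change_table({1: triple, 2: triple})
        slopes = individual_slopes(table)
        assert slopes["slope"].iloc[0] == pytest.approx(expected)

    def test_equals_half_difference_exactly(self, clinical_changes):
        slopes = individual_slopes(clinical_changes).set_index("subject_id")
        wide = clinical_changes.pivot(index="subject_id", columns="load_code",
                                      values="delta")
        expected = (wide[1] - wide[-1]) / 2.0
        assert np.allclose(slopes["slope"], expected[slopes.index])

    def test_single_load_subject_skipped(self, caplog):
        table = make_change_table({1: (0, 5, 10)})
        extra = pd.DataFrame([(2, "M", 0, "t1", 3.0, "relative")],
                             columns=table.columns)
        with caplog.at_level("WARNING"):
            slopes = individual_slopes(pd.concat([table, extra]))
        assert set(slopes["subject_id"]) == {1}


class TestAverageSpearman:
    def test_identical_variables_give_plus_one(self):
        a = change_rows({-1: [1, 2, 3, 4, 5], 0: [2, 1, 4, 3, 5],
                         1: [5, 4, 3, 2, 1]})
        assert average_spearman(a, a) == pytest.approx(1.0)

    def test_antimonotone_within_loads_gives_minus_one(self):
        a = change_rows({l: [1, 2, 3, 4, 5] for l in (-1, 0, 1)})
        b = change_rows({l: [10, 8, 6, 4, 2] for l in (-1, 0, 1)}, marker="B")
        assert average_spearman(a, b) == pytest.approx(-1.0)

    def test_hand_computed_per_load_average(self):
        """Per-load Spearman values 0.5, 0.0, 0.1 (rank oracle) average to
        0.2."""
        a = change_rows({l: [1, 2, 3, 4, 5] for l in (-1, 0, 1)})
        b = change_rows({-1: [2, 4, 1, 3, 5], 0: [2, 5, 3, 1, 4],
                         1: [4, 2, 3, 1, 5]}, marker="B")
        assert average_spearman(a, b) == pytest.approx(0.2)

    def test_monotone_transform_invariance_within_loads(self):
        rng = np.random.default_rng(3)
        vals = {l: rng.normal(size=8) for l in (-1, 0, 1)}
        a = change_rows(vals)
        b = change_rows({l: np.exp(2 * v) - 5 for l, v in vals.items()},
                        marker="B")
        assert average_spearman(a, b) == pytest.approx(1.0)

    def test_short_load_level_dropped_with_warning(self, caplog):
        a = change_rows({-1: [1, 2, 3, 4], 0: [1, 2]})
        b = change_rows({-1: [1, 3, 2, 4], 0: [2, 1]}, marker="B")
        with caplog.at_level("WARNING"):
            rho = average_spearman(a, b)
        assert "dropped" in caplog.text
        assert rho == pytest.approx(0.8)

    def test_all_levels_dropped_raises(self):
        a = change_rows({0: [1, 2]})
        b = change_rows({0: [2, 1]}, marker="B")
        with pytest.raises(UndefinedCorrelationError):
            average_spearman(a, b)


class TestBootstrap:
    def test_perfect_dependence_limit(self):
        a = change_rows({l: np.arange(10) + l for l in (-1, 0, 1)})
        est = bootstrap_correlation_inference(a, a, n_boot=200, seed=0)
        assert est["rho"] == pytest.approx(1.0)
        assert est["ci"][1] == pytest.approx(1.0, abs=1e-9)
        assert est["p"] < 1e-6

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        a = change_rows({l: rng.normal(size=12) for l in (-1, 0, 1)})
        b = change_rows({l: rng.normal(size=12) for l in (-1, 0, 1)},
                        marker="B")
        e1 = bootstrap_correlation_inference(a, b, n_boot=300, seed=9)
        e2 = bootstrap_correlation_inference(a, b, n_boot=300, seed=9)
        assert e1 == e2

    def test_null_calibration(self):
        """Independent variables: the bootstrap p-value rejects at close to
        the nominal 5% rate (checked over 200 simulated datasets)."""
        n_datasets, rejections = 200, 0
        master = np.random.SeedSequence(0).generate_state(n_datasets)
        for ds_seed in master:
            rng = np.random.default_rng(int(ds_seed) % (2 ** 31))
            a = change_rows({l: rng.normal(size=24) for l in (-1, 0, 1)})
            b = change_rows({l: rng.normal(size=24) for l in (-1, 0, 1)},
                            marker="B")
            est = bootstrap_correlation_inference(a, b, n_boot=200,
                                                  seed=int(ds_seed) % 2**31)
            rejections += est["p"] < 0.05
        rate = rejections / n_datasets
        # binomial SE at p=0.05, n=200 is 1.5%: accept within ~3 SE
        assert 0.01 <= rate <= 0.10

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (24, 96, 384):
            rng = np.random.default_rng(11)
            base = {l: rng.normal(size=n) for l in (-1, 0, 1)}
            noise = {l: v + rng.normal(scale=1.0, size=n)
                     for l, v in base.items()}
            a = change_rows(base)
            b = change_rows(noise, marker="B")
            est = bootstrap_correlation_inference(a, b, n_boot=300, seed=2)
            widths.append(est["ci"][1] - est["ci"][0])
        assert widths[0] > widths[1] > widths[2]


class TestSlopeCorrelation:
    def slopes(self, values, marker="A"):
        return pd.DataFrame({"subject_id": np.arange(1, len(values) + 1),
                             "marker": marker, "timepoint": "t1",
                             "slope": values})

    def test_identical_sets_give_one(self):
        s = self.slopes([1.0, 2.0, 5.0, 3.0])
        assert slope_correlation(s, s)["rho"] == pytest.approx(1.0)

    def test_reversed_sets_give_minus_one(self):
        a = self.slopes([1, 2, 3, 4])
        b = self.slopes([4, 3, 2, 1], marker="B")
        assert slope_correlation(a, b)["rho"] == pytest.approx(-1.0)

    def test_rank_formula_value(self):
        """(1,2,3,4,5) vs (1,3,2,5,4): sum of squared rank differences 4,
        rho = 1 - 6*4/120 = 0.8 by the rank oracle."""
        a = self.slopes([1, 2, 3, 4, 5])
        b = self.slopes([1, 3, 2, 5, 4], marker="B")
        assert slope_correlation(a, b)["rho"] == pytest.approx(0.8)

    def test_too_few_overlapping_subjects(self):
        a = self.slopes([1, 2])
        b = self.slopes([2, 1], marker="B")
        with pytest.raises(UndefinedCorrelationError):
            slope_correlation(a, b)


class TestCorrelationMatrix:
    N_SUBJ = 60  # null correlations have SE ~ 0.13 at this size

    def build_changes(self):
        rng = np.random.default_rng(21)
        frames = []
        n = self.N_SUBJ
        shared = rng.normal(size=n)  # latent slope shared by two markers
        for marker, slope_base in (("A", shared), ("B", shared),
                                   ("C", rng.normal(size=n))):
            rows = []
            for sid in range(1, n + 1):
                alpha = rng.normal(5, 2)
                beta = 3 * slope_base[sid - 1] + rng.normal(0, 0.3)
                for l in (-1, 0, 1):
                    rows.append((sid, marker, l, "t1",
                                 alpha + beta * l + rng.normal(0, 0.3),
                                 "relative"))
            frames.append(pd.DataFrame(rows, columns=[
                "subject_id", "marker", "load_code", "timepoint", "delta",
                "scale"]))
        return pd.concat(frames, ignore_index=True)

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        changes = self.build_changes()
        combos = [("A", "t1"), ("B", "t1"), ("C", "t1")]
        rho, _ = correlation_matrix(combos, changes, kind="change")
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T)

    def test_shared_latent_slope_detected(self):
        changes = self.build_changes()
        combos = [("A", "t1"), ("B", "t1"), ("C", "t1")]
        rho, _ = correlation_matrix(combos, changes, kind="slope")
        assert rho.loc["A (t1)", "B (t1)"] > 0.8
        assert abs(rho.loc["A (t1)", "C (t1)"]) < 0.4
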