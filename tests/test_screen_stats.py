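import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subcell.evaluate import prob_columns
from subcell.preprocess import CellCrop
from subcell.screen_stats import (abundance_fold_change, abundance_table,
                                  build_flux_network, calibrate_scores,
                                  change_scores, fit_outlier_mixture, flux_graph,
                                  mean_abundance, welch_t)
from subcell.simulate import MorphologyParams, simulate_screen


class TestWelchT:
    def test_hand_computed_triple(self):
        # means 2 vs 5, s^2 = 1 each, n = 3: t = 3 / sqrt(2/3)
        t = welch_t([1, 2, 3], [4, 5, 6], min_cells=3)
        assert t == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-12)
        assert t == pytest.approx(3.674, abs=1e-3)

    def test_identical_samples_zero(self):
        assert welch_t([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        assert welch_t(a, b) == pytest.approx(-welch_t(b, a), abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 30)))
            b = rng.normal(0.5, 2, int(rng.integers(5, 30)))
            expected = stats.ttest_ind(b, a, equal_var=False).statistic
            assert welch_t(a, b) == pytest.approx(expected, rel=1e-12)

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match=">= 5"):
            welch_t([1, 2], [1, 2, 3, 4, 5])

    def test_both_variances_zero_undefined(self):
        assert np.isnan(welch_t([1] * 5, [1] * 5))


class TestOutlierMixture:
    def test_planted_outliers_called(self):
        rng = np.random.default_rng(123)
        null = rng.normal(0, 1, 1000)
        planted = np.array([20.0] * 5 + [-20.0] * 5)
        scores = np.concatenate([null, planted])
        fit = fit_outlier_mixture(scores)
        calls = fit.outlier
        assert calls[-10:].sum() >= 9
        assert calls[:-10].mean() <= 0.01
        assert abs(fit.mu) < 0.2 and abs(np.sqrt(fit.sigma2) - 1.0) < 0.2

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0, 1, 500), [15.0, -12.0]])
        fit = fit_outlier_mixture(scores)
        diffs = np.diff(fit.loglik)
        assert (diffs >= -1e-9).all()

    def test_no_extreme_scores_no_calls(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(-1, 1, 300)
        fit = fit_outlier_mixture(scores)
        assert fit.outlier.sum() == 0

    def test_too_few_scores(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_outlier_mixture(np.arange(5.0))

    def test_degenerate_spread(self):
        with pytest.raises(ValueError, match="spread"):
            fit_outlier_mixture(np.ones(20))

    def test_nan_scores_get_nan_posterior(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0, 1, 50), [np.nan]])
        fit = fit_outlier_mixture(scores)
        assert np.isnan(fit.responsibilities[-1])
        assert np.isfinite(fit.responsibilities[:-1]).all()

    def test_pi_out_fixed_not_reestimated(self):
        rng = np.random.default_rng(2)
        fit = fit_outlier_mixture(rng.normal(0, 1, 200), pi_out=0.01)
        assert fit.pi_out == 0.01


class TestAbundance:
    def test_boundary_fold_change_not_flagged(self):
        dpl, flag = abundance_fold_change(2.0, 1.0)
        assert dpl == 1.0 and flag is False

    def test_no_change(self):
        assert abundance_fold_change(1.0, 1.0) == (0.0, False)

    def test_threefold_flagged(self):
        dpl, flag = abundance_fold_change(3.0, 1.0)
        assert dpl == pytest.approx(np.log2(3), abs=1e-12)
        assert flag is True

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a, b = rng.uniform(0.1, 10, 2)
            assert abundance_fold_change(b, a)[0] == pytest.approx(
                -abundance_fold_change(a, b)[0], abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            abundance_fold_change(0.0, 1.0)

    def test_mean_abundance_single_cell(self):
        px = np.zeros((2, 64, 64), dtype=np.float32)
        px[0] = 3.0
        crop = CellCrop(px)
        assert mean_abundance([crop]) == pytest.approx(3.0)

    def test_mean_abundance_linearity(self):
        rng = np.random.default_rng(4)
        px = rng.uniform(0, 100, (2, 64, 64)).astype(np.float32)
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:40, 10:40] = True
        c1 = CellCrop(px, meta={"cell_mask": mask})
        c2 = CellCrop(px * 2, meta={"cell_mask": mask})
        assert mean_abundance([c2]) == pytest.approx(2 * mean_abundance([c1]))

    def test_mean_abundance_empty(self):
        with pytest.raises(ValueError):
            mean_abundance([])

    def test_planted_twofold_screen(self):
        params = MorphologyParams(background_level=20.0)
        screen = simulate_screen(1, cells_per_protein=50, shift_fraction=0.0,
                                 abundance_effects={0: 2.0}, params=params,
                                 seed=21, class_names=("cytoplasm",))
        table = abundance_table(screen.crops["A"], screen.crops["B"])
        assert abs(table.loc[0, "dpl"] - 1.0) <= 0.15
        assert bool(table.loc[0, "abundance_flag"]) in (True, False)


CLASSES = ("cytoplasm", "nucleus")


def _pred_table(pid_probs, condition="A"):
    """pid_probs: list of (protein_id, p_cytoplasm)."""
    rows = []
    for i, (pid, p) in enumerate(pid_probs):
        rows.append({"cell_id": f"{condition}{i}", "protein_id": pid,
                     "condition": condition, "p_cytoplasm": p,
                     "p_nucleus": 1 - p})
    return pd.DataFrame(rows)


class TestChangeScores:
    def test_shifted_protein_scores_large(self):
        a = _pred_table([("P1", 0.9 + 0.01 * i) for i in range(8)])
        b = _pred_table([("P1", 0.1 + 0.01 * i) for i in range(8)], "B")
        out = change_scores(a, b, CLASSES)
        t_cyt = out[out["class"] == "cytoplasm"]["t_score"].iloc[0]
        assert t_cyt < -10  # strong decrease of cytoplasm in B

    def test_min_cells_skipped_flag(self):
        a = _pred_table([("P1", 0.5)] * 3)
        b = _pred_table([("P1", 0.5)] * 8, "B")
        out = change_scores(a, b, CLASSES)
        assert out["skipped"].all()
        assert out["t_score"].isna().all()

    def test_calibration_adds_columns(self):
        rng = np.random.default_rng(0)
        rows_a = [("P%03d" % i, p) for i in range(40)
                  for p in rng.uniform(0.4, 0.6, 6)]
        rows_b = [("P%03d" % i, p) for i in range(40)
                  for p in rng.uniform(0.4, 0.6, 6)]
        out = change_scores(_pred_table(rows_a), _pred_table(rows_b, "B"), CLASSES)
        calibrated, fits = calibrate_scores(out)
        assert {"outlier_posterior", "outlier_call"} <= set(calibrated.columns)
        assert set(fits) == set(CLASSES)


class TestFluxNetwork:
    def _profiles(self, pid, p_cyt_a, p_cyt_b):
        a = pd.DataFrame({"protein_id": [pid], "p_cytoplasm": [p_cyt_a],
                          "p_nucleus": [1 - p_cyt_a], "n_cells": [10]})
        b = pd.DataFrame({"protein_id": [pid], "p_cytoplasm": [p_cyt_b],
                          "p_nucleus": [1 - p_cyt_b], "n_cells": [10]})
        return a, b

    def test_all_below_threshold_empty(self):
        scores = pd.DataFrame({"protein_id": ["P1", "P1"],
                               "class": list(CLASSES),
                               "t_score": [4.0, -6.0]})
        a, b = self._profiles("P1", 0.2, 0.8)
        edges = build_flux_network(scores, a, b, CLASSES)
        assert edges.empty

    def test_stated_rule_single_edge(self):
        scores = pd.DataFrame({"protein_id": ["P1", "P1"],
                               "class": list(CLASSES),
                               "t_score": [12.0, -15.0]})  # cytoplasm up, nucleus down
        a, b = self._profiles("P1", 0.1, 0.9)  # dominant A compartment: nucleus
        edges = build_flux_network(scores, a, b, CLASSES)
        assert len(edges) == 1
        e = edges.iloc[0]
        assert (e["source"], e["target"], e["weight"]) == ("nucleus", "cytoplasm", 12.0)
        assert bool(e["dominant_changed"])

    def test_edge_weights_match_scores(self):
        scores = pd.DataFrame({"protein_id": ["P1"] * 2, "class": list(CLASSES),
                               "t_score": [25.0, 11.0]})
        a, b = self._profiles("P1", 0.9, 0.9)
        edges = build_flux_network(scores, a, b, CLASSES)
        assert sorted(edges["weight"]) == [11.0, 25.0]
        assert set(edges["source"]) == {"cytoplasm"}

    def test_graph_view(self):
        scores = pd.DataFrame({"protein_id": ["P1"], "class": ["cytoplasm"],
                               "t_score": [12.0]})
        a, b = self._profiles("P1", 0.1, 0.9)
        g = flux_graph(build_flux_network(scores, a, b, CLASSES))
        assert g.has_edge("nucleus", "cytoplasm")


class TestNullScreenCalibration:
    def test_null_outlier_rate_bounded(self):
        # pure null: per-protein per-class t scores from identical generators
        rng = np.random.default_rng(99)
        rows_a, rows_b = [], []
        for i in range(500):
            pid = f"P{i:04d}"
            rows_a += [(pid, p) for p in rng.beta(5, 5, 8)]
            rows_b += [(pid, p) for p in rng.beta(5, 5, 8)]
        out = change_scores(_pred_table(rows_a), _pred_table(rows_b, "B"), CLASSES)
        calibrated, _ = calibrate_scores(out)
        rate = calibrated["outlier_call"].mean()
        assert rate <= 0.02
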