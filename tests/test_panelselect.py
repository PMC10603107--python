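import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from exoscreen import (
    CombinationModel,
    MarkerPanel,
    PanelSimConfig,
    evaluate_fixed_combination,
    exhaustive_search,
    fit_logistic,
    generate_marker_panel,
    linear_score,
    ppv,
    sensitivity_at_specificity,
    youden_cutoff,
)
from exoscreen.synthdata import MarkerSpec


def make_panel(case_vals: dict, control_vals: dict) -> MarkerPanel:
    markers = list(case_vals)
    n_case = len(next(iter(case_vals.values())))
    n_ctrl = len(next(iter(control_vals.values())))
    idx = [f"c{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_ctrl)]
    mat = pd.DataFrame(
        {m: list(case_vals[m]) + list(control_vals[m]) for m in markers}, index=idx
    )
    labels = pd.Series(["case"] * n_case + ["control"] * n_ctrl, index=idx)
    return MarkerPanel(intensities=mat, labels=labels)


class TestFitLogistic:
    def test_null_marker_zero_slope(self):
        vals = [1.0, 2.0, 4.0, 8.0, 16.0]
        panel = make_panel({"M": vals}, {"M": vals})
        m = fit_logistic(panel, ["M"])
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-5)
        # null log-likelihood: n*ln(1/2); AIC = 2k - 2L with k = 2
        assert m.aic == pytest.approx(4 - 2 * 10 * np.log(0.5), abs=1e-6)

    def test_aic_identity_from_predicted_probabilities(self):
        rng = np.random.default_rng(0)
        panel = make_panel(
            {"A": rng.lognormal(1, 0.5, 30), "B": rng.lognormal(0.5, 0.5, 30)},
            {"A": rng.lognormal(0, 0.5, 30), "B": rng.lognormal(0, 0.5, 30)},
        )
        m = fit_logistic(panel, ["A", "B"])
        X = np.log(panel.intensities[["A", "B"]].to_numpy())
        y = (panel.labels == "case").to_numpy(float)
        eta = m.intercept + X @ m.coefficients
        p = 1 / (1 + np.exp(-eta))
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert m.aic == pytest.approx(2 * 3 - 2 * llf, abs=1e-8)

    def test_coefficient_recovery_large_n(self):
        # logistic model on log intensities: eta = b0 + 2*log(x1) - 1*log(x2)
        rng = np.random.default_rng(1)
        n = 4000
        x1, x2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        eta = 0.3 + 2.0 * x1 - 1.0 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        idx = [f"s{i}" for i in range(n)]
        panel = MarkerPanel(
            intensities=pd.DataFrame({"A": np.exp(x1), "B": np.exp(x2)}, index=idx),
            labels=pd.Series(np.where(y, "case", "control"), index=idx),
        )
        m = fit_logistic(panel, ["A", "B"])
        assert m.coefficients[0] == pytest.approx(2.0, rel=0.15)
        assert m.coefficients[1] == pytest.approx(-1.0, rel=0.15)

    def test_separation_flagged_and_finite(self):
        panel = make_panel({"M": [100.0, 120, 140]}, {"M": [1.0, 2, 3]})
        with pytest.warns(RuntimeWarning):
            m = fit_logistic(panel, ["M"])
        assert m.separation
        assert np.all(np.isfinite(m.coefficients))


class TestExhaustiveSearch:
    def test_counts_all_subsets(self, chip_panel):
        panel, _ = chip_panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, models2 = exhaustive_search(panel, panel.markers[:2])
            best, models7 = exhaustive_search(panel, panel.markers)
        assert len(models2) == 3
        assert len(models7) == 127
        assert best.aic == min(m.aic for m in models7)

    def test_tie_break_prefers_fewer_markers(self, chip_panel):
        panel, _ = chip_panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, models = exhaustive_search(panel, panel.markers)
        for m in models:
            if m.aic == best.aic:
                assert len(best.markers) <= len(m.markers)

    def test_candidate_bounds(self, chip_panel):
        panel, _ = chip_panel
        with pytest.raises(ValueError):
            exhaustive_search(panel, [])


class TestLinearScore:
    def _fixed_model(self):
        return CombinationModel(
            markers=("IGSF8", "ITGA5"),
            coefficients=np.array([11.299, 14.935]),
            intercept=-5.0,
            log_likelihood=0.0,
            aic=6.0,
            n_obs=30,
        )

    def test_reported_coefficients_at_unit_log(self):
        e = float(np.e)
        panel = make_panel(
            {"IGSF8": [e, e], "ITGA5": [e, e]},
            {"IGSF8": [e, e], "ITGA5": [e, e]},
        )
        s = linear_score(self._fixed_model(), panel)
        assert np.allclose(s, 11.299 + 14.935)
        assert s.iloc[0] == pytest.approx(26.234, abs=1e-12)

    def test_zero_coefficients_zero_scores(self):
        model = CombinationModel(
            markers=("A",), coefficients=np.array([0.0]), intercept=1.0,
            log_likelihood=0.0, aic=4.0, n_obs=4,
        )
        panel = make_panel({"A": [1.0, 5.0]}, {"A": [2.0, 9.0]})
        assert (linear_score(model, panel) == 0).all()

    def test_intercept_does_not_affect_operating_points(self, chip_panel):
        panel, _ = chip_panel
        m1 = self._fixed_model()
        m2 = CombinationModel(
            markers=m1.markers, coefficients=m1.coefficients, intercept=100.0,
            log_likelihood=0.0, aic=6.0, n_obs=30,
        )
        p1 = evaluate_fixed_combination(m1, panel)
        p2 = evaluate_fixed_combination(m2, panel)
        assert (p1.sensitivity, p1.ppv) == (p2.sensitivity, p2.ppv)

    def test_nonpositive_intensity_named(self):
        model = self._fixed_model()
        idx = ["c0", "c1", "h0"]
        mat = pd.DataFrame(
            {"IGSF8": [1.0, 1.0, 1.0], "ITGA5": [1.0, 1.0, 1.0]}, index=idx
        )
        panel = MarkerPanel(
            intensities=mat,
            labels=pd.Series(["case", "case", "control"], index=idx),
        )
        panel.intensities.loc["c1", "ITGA5"] = -1.0  # corrupt after validation
        with pytest.raises(ValueError, match="ITGA5"):
            linear_score(model, panel)


class TestOperatingPoints:
    def test_youden_perfect_separation(self):
        perf = youden_cutoff([10.0, 11, 12], [1.0, 2, 3])
        assert perf.youden_j == 1.0
        assert perf.sensitivity == perf.specificity == 1.0

    def test_youden_identical_classes_degenerate(self):
        perf = youden_cutoff([1.0, 2, 3], [1.0, 2, 3])
        assert perf.youden_j == pytest.approx(0.0)

    def test_youden_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pos = rng.normal(0.8, 1, 12)
            neg = rng.normal(0, 1, 15)
            perf = youden_cutoff(pos, neg)
            best_j = max(
                np.mean(pos > c) + np.mean(neg <= c) - 1
                for c in np.concatenate([pos, neg, [pos.min() - 1, neg.max() + 1]])
            )
            assert perf.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_sensitivity_forced_spec_with_few_controls(self):
        neg = np.arange(1.0, 21.0)  # 20 controls
        pos = np.arange(21.0, 31.0)
        sens, cutoff = sensitivity_at_specificity(pos, neg, 0.998)
        assert sens == 1.0
        assert cutoff > neg.max()  # cutoff forced above control maximum

    def test_sensitivity_zero_when_cases_below_controls(self):
        sens, _ = sensitivity_at_specificity([0.1, 0.2], np.arange(1.0, 21.0), 0.998)
        assert sens == 0.0

    def test_sensitivity_matches_sweep_oracle(self):
        rng = np.random.default_rng(13)
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 40)
        sens, cutoff = sensitivity_at_specificity(pos, neg, 0.8)
        # oracle: brute-force over a fine cutoff lattice
        grid = np.sort(np.concatenate([pos, neg]))
        feasible = [
            (c, np.mean(pos > c)) for c in (grid[:-1] + grid[1:]) / 2
            if np.mean(neg <= c) >= 0.8
        ]
        assert sens == max(s for _, s in feasible)
        assert np.mean(neg <= cutoff) >= 0.8

    @pytest.mark.parametrize(
        "sens,expected",
        [(0.30, 0.057), (0.40, 0.074), (0.60, 0.107), (0.80, 0.138), (0.90, 0.153)],
    )
    def test_ppv_at_screening_prevalence(self, sens, expected):
        assert round(ppv(sens, 0.998, 1 / 2500), 3) == expected

    def test_ppv_edge_cases(self):
        assert ppv(1.0, 1.0, 0.3) == 1.0
        with pytest.warns(RuntimeWarning):
            assert ppv(0.0, 1.0, 0.5) == 0.0

    def test_ppv_monotone_in_both_arguments(self):
        s = np.linspace(0.05, 1.0, 30)
        q = np.linspace(0.0, 0.999, 30)
        for qq in q[::7]:
            vals = [ppv(x, qq, 0.01) for x in s]
            assert np.all(np.diff(vals) > 0)
        for ss in s[::7]:
            vals = [ppv(ss, x, 0.01) for x in q]
            assert np.all(np.diff(vals) > 0)


class TestEvaluateFixedCombination:
    def test_self_application_consistency(self, chip_panel):
        panel, _ = chip_panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best, _ = exhaustive_search(panel, panel.markers)
        perf = evaluate_fixed_combination(best, panel)
        scores = linear_score(best, panel)
        pos = scores[panel.labels == "case"].to_numpy()
        neg = scores[panel.labels == "control"].to_numpy()
        sens, _ = sensitivity_at_specificity(pos, neg, 0.998)
        assert perf.sensitivity == sens
        assert perf.ppv == ppv(sens, 0.998, perf.prevalence)

    def test_validation_panel_ppv_within_monte_carlo_band(self):
        # a fixed two-marker model applied to fresh panels from the training
        # distribution: mean validation sensitivity tracks training sensitivity
        specs = [MarkerSpec("IGSF8", 1.8), MarkerSpec("ITGA5", 2.3)]
        train, _ = generate_marker_panel(
            PanelSimConfig(markers=specs, seed=100)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_logistic(train, ["IGSF8", "ITGA5"])
        train_perf = evaluate_fixed_combination(model, train)
        sens = []
        for seed in range(60):
            val, _ = generate_marker_panel(
                PanelSimConfig(markers=specs, seed=1000 + seed)
            )
            sens.append(evaluate_fixed_combination(model, val).sensitivity)
        band = 3 * np.std(sens) / np.sqrt(len(sens)) + 0.15
        assert abs(np.mean(sens) - train_perf.sensitivity) < band

    def test_missing_marker_named(self, chip_panel):
        panel, _ = chip_panel
        model = CombinationModel(
            markers=("ITGA5", "NOT_THERE"),
            coefficients=np.array([1.0, 1.0]), intercept=0.0,
            log_likelihood=0.0, aic=6.0, n_obs=30,
        )
        with pytest.raises(KeyError, match="NOT_THERE"):
            evaluate_fixed_combination(model, panel)
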