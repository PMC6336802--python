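"""Remission criterion, feature construction, and the elastic-net ensemble:
selection behaviour, weighted odds ratios, permutation calibration, and
held-out performance against a concordance oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from fepstrat.panss import classify_remission
from fepstrat.prediction import (
    EnsembleConfig,
    RemissionEnsemble,
    _enet_fit,
    build_features,
    evaluate_performance,
    permutation_pvalues,
    weighted_odds_ratios,
)


class TestClassifyRemission:
    ITEMS = ["P1", "P2", "P3", "N1", "N4", "N6", "G5", "G9"]

    def test_all_items_at_cutoff_is_remitter(self):
        df = pd.DataFrame([[3, 2, 3, 3, 2, 3, 1, 3]], columns=self.ITEMS)
        assert classify_remission(df).iloc[0]

    def test_single_item_above_cutoff_is_nonremitter(self):
        df = pd.DataFrame([[3, 2, 3, 4, 2, 3, 1, 3]], columns=self.ITEMS)
        assert not classify_remission(df).iloc[0]

    def test_study_sized_fixture_remission_rate(self):
        # 223 remitter-consistent and 102 non-remitter-consistent profiles
        rem = pd.DataFrame(np.full((223, 8), 2), columns=self.ITEMS)
        non = pd.DataFrame(np.full((102, 8), 2), columns=self.ITEMS)
        non["N1"] = 5
        rate = classify_remission(pd.concat([rem, non], ignore_index=True)).mean()
        assert round(100 * rate, 1) == 68.6

    def test_missing_item_rejected(self):
        df = pd.DataFrame([[1] * 7], columns=self.ITEMS[:-1])
        with pytest.raises(ValueError, match="G9"):
            classify_remission(df)


class TestBuildFeatures:
    def make_inputs(self):
        idx = pd.Index(["a", "b", "c", "d"], name="patient_id")
        log_table = pd.DataFrame(
            {"IL-15": [0.1, 0.5, 0.3, 0.9], "CXCL12": [3.3, 3.5, 3.2, 3.6]}, index=idx
        )
        cov = pd.DataFrame(
            {
                "sex": ["male", "female", "male", "male"],
                "age": [20.0, 30.0, 25.0, 40.0],
                "drug_use": [True, False, False, True],
            },
            index=idx,
        )
        return log_table, cov

    def test_male_encoded_one(self):
        log_table, cov = self.make_inputs()
        ft = build_features(log_table, cov)
        assert list(ft.X["male"]) == [1.0, 0.0, 1.0, 1.0]
        assert "male" in ft.binary_columns

    def test_standardization_round_trip(self):
        log_table, cov = self.make_inputs()
        ft = build_features(log_table, cov)
        np.testing.assert_allclose(ft.unstandardize("age"), cov["age"], atol=1e-10)
        assert ft.X["age"].mean() == pytest.approx(0, abs=1e-10)

    def test_missing_value_drops_patient(self):
        log_table, cov = self.make_inputs()
        cov.loc["b", "age"] = np.nan
        ft = build_features(log_table, cov)
        assert ft.dropped_patients == ["b"]
        assert len(ft.X) == 3

    def test_disjoint_ids_rejected(self):
        log_table, cov = self.make_inputs()
        cov.index = pd.Index(["x", "y", "z", "w"])
        with pytest.raises(ValueError, match="overlap"):
            build_features(log_table, cov)


class TestWeightedOddsRatios:
    def test_constant_coefficient(self):
        coefs = np.full((10, 1), np.log(2.0))
        sel = np.ones((10, 1), dtype=bool)
        tab = weighted_odds_ratios(coefs, sel, ["v"])
        assert tab.loc["v", "weighted_or"] == pytest.approx(2.0)
        assert tab.loc["v", "selection_proportion"] == 1.0

    def test_never_selected_reports_unity(self):
        coefs = np.zeros((5, 1))
        sel = np.zeros((5, 1), dtype=bool)
        tab = weighted_odds_ratios(coefs, sel, ["v"])
        assert tab.loc["v", "weighted_or"] == 1.0
        assert tab.loc["v", "selection_proportion"] == 0.0

    def test_stated_averaging_rule(self):
        coefs = np.array([[np.log(2.0)], [np.log(8.0)]])
        sel = np.ones((2, 1), dtype=bool)
        tab = weighted_odds_ratios(coefs, sel, ["v"])
        assert tab.loc["v", "weighted_or"] == pytest.approx(5.0)

    def test_proportion_scaled_mode(self):
        coefs = np.array([[np.log(4.0)], [0.0]])
        sel = np.array([[True], [False]])
        tab = weighted_odds_ratios(coefs, sel, ["v"], mode="proportion-scaled")
        assert tab.loc["v", "weighted_or"] == pytest.approx(np.exp(0.5 * np.log(4.0)))


def logistic_data(n, betas, seed, intercept=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(betas)))
    y = (rng.random(n) < expit(intercept + X @ np.asarray(betas))).astype(int)
    return X, y


class TestPermutationPvalues:
    def test_single_permutation_values(self):
        X, y = logistic_data(80, [1.0, 0.0], seed=0)
        p = permutation_pvalues(X, y, 0.5, 0.05, B=1, seed=0)
        assert set(np.round(p, 6)) <= {0.5, 1.0}

    def test_dominant_predictor_reaches_floor(self):
        X, y = logistic_data(400, [np.log(8.0), 0.0, 0.0], seed=1)
        p = permutation_pvalues(X, y, 0.5, 0.02, B=199, seed=2)
        assert p.iloc[0] == pytest.approx(1 / 200)

    def test_noise_variable_p_is_not_small(self):
        # median permutation p of a pure-noise variable over replicates
        meds = []
        for seed in range(20):
            X, y = logistic_data(120, [0.0, 0.0, 0.0, 0.0], seed=seed)
            p = permutation_pvalues(X, y, 0.5, 0.05, B=49, seed=seed)
            meds.append(p.iloc[0])
        assert np.median(meds) > 0.2

    def test_null_rejection_rate_calibrated(self):
        # nominal 0.05 test on an independent noise variable
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            X, y = logistic_data(120, [0.0] * 5, seed=1000 + seed)
            p = permutation_pvalues(X, y, 0.5, 0.05, B=99, seed=seed)
            rejections += p.iloc[0] <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestEvaluatePerformance:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        perf = evaluate_performance([(y, p)], threshold=0.5)
        assert perf.mean_auc == 1.0
        assert perf.sensitivity == 1.0
        assert perf.specificity == 1.0

    def test_constant_score(self):
        y = np.array([0, 1, 0, 1])
        p = np.full(4, 0.3)
        perf = evaluate_performance([(y, p)], threshold=0.5)
        assert perf.mean_auc == pytest.approx(0.5)
        assert perf.sensitivity == 0.0
        assert perf.specificity == 1.0

    def test_auc_matches_concordance_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        p = rng.random(50)
        perf = evaluate_performance([(y, p)], threshold=0.5)
        pos, neg = p[y == 1], p[y == 0]
        conc = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        ) / (len(pos) * len(neg))
        assert perf.mean_auc == pytest.approx(conc, abs=1e-10)

    def test_singleclass_drawing_excluded(self):
        y_all_neg = np.zeros(5, dtype=int)
        perf = evaluate_performance([(y_all_neg, np.linspace(0, 1, 5))])
        assert perf.n_excluded_drawings == 1
        assert np.isnan(perf.mean_auc)


class TestEnsemble:
    def test_strong_signal_variable_dominates_selection(self):
        cfg = EnsembleConfig(n_partitions=5)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 41))
            y = (rng.random(400) < expit(np.log(8.0) * X[:, 0])).astype(int)
            Xdf = pd.DataFrame(X, columns=["signal"] + [f"noise{j}" for j in range(40)])
            res = RemissionEnsemble(Xdf, y.astype(bool), cfg).fit(seed=seed)
            props = res.selection_proportions
            assert props["signal"] > 0.95
            assert props["signal"] >= props.drop("signal").max()

    def test_lambda_path_monotone_selection(self):
        X, y = logistic_data(200, [1.0, -0.5, 0.3, 0.0, 0.0, 0.0], seed=3)
        lams = np.geomspace(1e-4, 0.5, 12)
        counts = []
        for lam in lams:
            co, _ = _enet_fit(X, y, alpha=0.8, lam=lam, max_iter=3000, tol=1e-5)
            counts.append(int((co != 0).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ridge_limit_selects_everything(self):
        X, y = logistic_data(150, [0.5, 0.0, 0.2, 0.0], seed=4)
        co, _ = _enet_fit(X, y, alpha=0.05, lam=1e-5, max_iter=5000, tol=1e-6)
        assert (co != 0).all()

    def test_refit_with_all_variables_reproduces_full_fit(self):
        X, y = logistic_data(150, [1.0, 0.0, 0.0], seed=5)
        Xdf = pd.DataFrame(X, columns=["a", "b", "c"])
        cfg = EnsembleConfig(n_partitions=2)
        model = RemissionEnsemble(Xdf, y.astype(bool), cfg)
        full = model.fit(seed=9)
        reduced = model.refit_reduced(["a", "b", "c"], seed=9)
        np.testing.assert_allclose(full.coefs, reduced.coefs, atol=1e-12)

    def test_refit_unknown_variable_rejected(self):
        X, y = logistic_data(60, [1.0], seed=6)
        model = RemissionEnsemble(pd.DataFrame(X, columns=["a"]), y.astype(bool),
                                  EnsembleConfig(n_partitions=1))
        with pytest.raises(ValueError, match="unknown"):
            model.refit_reduced(["zz"])

    def test_single_class_outcome_rejected(self):
        X, _ = logistic_data(60, [1.0], seed=7)
        with pytest.raises(ValueError, match="class"):
            RemissionEnsemble(pd.DataFrame(X), np.ones(60, dtype=bool))
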