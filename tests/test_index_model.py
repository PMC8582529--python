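import itertools
import json
import warnings

import numpy as np
import pandas as pd
import pytest

from qfibrec.index_model import (
    PUBLISHED_COEFFICIENTS,
    PUBLISHED_CUTOFF,
    CombinedIndexRegressor,
    LinearIndexModel,
    NormalizationParams,
    RiskThreshold,
    apply_normalization,
    fit_linear_index,
    fit_normalization,
    loocv_predict,
    published_combined_model,
    score_and_classify,
    sequential_forward_selection,
)
from qfibrec.synthetic import CohortSimParams, generate_cohort


def rss_of(X, y, cols):
    """Independent least-squares RSS oracle via the normal equations."""
    A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in cols])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    r = y - A @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestNormalization:
    def test_minmax_formula(self):
        t = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out = apply_normalization(t, fit_normalization(t))
        assert out["a"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_feature_maps_to_zero(self):
        t = pd.DataFrame({"a": [5.0, 5.0, 5.0]})
        out = apply_normalization(t, fit_normalization(t))
        assert out["a"].tolist() == [0.0, 0.0, 0.0]

    def test_unseen_values_clipped(self):
        params = fit_normalization(pd.DataFrame({"a": [2.0, 6.0]}))
        out = apply_normalization(pd.DataFrame({"a": [8.0, 0.0]}), params)
        assert out["a"].tolist() == [1.0, 0.0]

    def test_non_numeric_rejected(self):
        with pytest.raises(ValueError, match="non-numeric"):
            fit_normalization(pd.DataFrame({"a": ["x", "y"]}))

    def test_fitted_table_lands_in_unit_interval(self, cohort64):
        data, _ = cohort64
        out = apply_normalization(data.features, fit_normalization(data.features))
        v = out.to_numpy()
        assert v.min() >= 0.0 and v.max() <= 1.0


# ---------------------------------------------------------------------------
# sequential forward selection
# ---------------------------------------------------------------------------


class TestSFS:
    def test_first_pick_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 12)), columns=[f"f{i}" for i in range(12)])
        y = 2.0 * X["f7"].to_numpy()
        assert sequential_forward_selection(X, y, 1) == ["f7"]
        # oracle: exhaustive single-feature RSS
        best = min(X.columns, key=lambda c: rss_of(X, y, [c]))
        assert best == "f7"

    def test_pair_matches_exhaustive_pair_search(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 10)), columns=[f"f{i}" for i in range(10)])
        y = X["f2"].to_numpy() + X["f8"].to_numpy()
        sel = sequential_forward_selection(X, y, 2)
        oracle = min(
            itertools.combinations(X.columns, 2), key=lambda p: rss_of(X, y, list(p))
        )
        assert set(sel) == set(oracle) == {"f2", "f8"}

    def test_k_zero_empty_selection(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        assert sequential_forward_selection(X, [0.0, 1.0, 0.0], 0) == []

    def test_collinear_candidate_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "dup": x, "b": rng.normal(size=30)})
        y = x + 0.1 * X["b"].to_numpy()
        with pytest.warns(UserWarning, match="collinear"):
            sel = sequential_forward_selection(X, y, 2)
        assert sel == ["a", "b"]  # 'dup' adds no rank and is skipped

    def test_tie_breaks_toward_pool_order(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        X = pd.DataFrame({"late": x, "early": x.copy()})
        sel = sequential_forward_selection(X, 2 * x, 1, pool=["early", "late"])
        assert sel == ["early"]


# ---------------------------------------------------------------------------
# linear fit
# ---------------------------------------------------------------------------


class TestLinearFit:
    def test_noiseless_interpolation(self):
        x = np.linspace(0, 1, 10)
        model = fit_linear_index(pd.DataFrame({"x1": x}), 0.5 + 0.2 * x)
        assert model.intercept == pytest.approx(0.5, abs=1e-12)
        assert model.coefficients[0] == pytest.approx(0.2, abs=1e-12)

    def test_all_zero_labels(self):
        rng = np.random.default_rng(0)
        model = fit_linear_index(pd.DataFrame({"x": rng.normal(size=8)}), np.zeros(8))
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = rng.normal(size=20)
        model = fit_linear_index(X, y)
        A = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_singular_design_raise_mode_names_columns(self):
        x = np.arange(6.0)
        X = pd.DataFrame({"a": x, "twice_a": 2 * x})
        with pytest.raises(ValueError, match="twice_a"):
            fit_linear_index(X, x, on_singular="raise")


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


class TestLoocv:
    def test_fold_count_equals_n(self, cohort64):
        data, labels = cohort64
        res = loocv_predict(data.features, labels)
        assert res.n_folds == 64
        assert len(res.predictions) == 64
        assert all(sz == 63 for sz in res.fold_train_sizes)

    def test_constant_predictor_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(size=12)
        X = pd.DataFrame({"c": np.full(12, 3.0)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = loocv_predict(X, y, k_max=1, taxonomy=None)
        expected = (y.sum() - y) / (len(y) - 1)  # leave-one-out mean
        np.testing.assert_allclose(res.predictions, expected, atol=1e-10)

    def test_row_order_invariance(self, cohort64):
        data, labels = cohort64
        perm = np.random.default_rng(5).permutation(64)
        r1 = loocv_predict(data.features, labels)
        r2 = loocv_predict(data.features.iloc[perm], labels[perm])
        np.testing.assert_allclose(r1.predictions[perm], r2.predictions, atol=1e-10)

    def test_too_small_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="at least 3"):
            loocv_predict(X, [0, 1], k_max=1, taxonomy=None)

    def test_nested_mode_selects_per_fold(self, cohort64):
        data, labels = cohort64
        res = loocv_predict(data.features, labels, k_max=3, mode="nested")
        assert res.selected_features is None
        assert len(res.fold_selected) == 64
        assert all(len(s) == 3 for s in res.fold_selected)


# ---------------------------------------------------------------------------
# published model and scoring
# ---------------------------------------------------------------------------


class TestPublishedModel:
    def test_structure(self, taxonomy):
        m = published_combined_model()
        assert len(m.feature_names) == 18
        assert sum("/" in n for n in m.feature_names) == 9
        assert all(n in taxonomy for n in m.feature_names)
        assert m.intercept == 3.838

    def test_all_zero_vector_scores_intercept(self):
        m = published_combined_model()
        assert m.score({n: 0.0 for n in m.feature_names}) == pytest.approx(3.838)

    def test_all_ones_vector_matches_hand_sum(self):
        m = published_combined_model()
        # frozen oracle: intercept plus the sum of the 18 printed coefficients
        hand_sum = 3.838 + sum(c for _, c in PUBLISHED_COEFFICIENTS)
        assert hand_sum == pytest.approx(-3.237, abs=1e-9)
        assert m.score({n: 1.0 for n in m.feature_names}) == pytest.approx(-3.237)

    def test_missing_feature_error_lists_names(self):
        m = published_combined_model()
        with pytest.raises(KeyError, match="SHG"):
            m.score({"StrOrientation": 1.0})


class TestScoreAndClassify:
    @pytest.mark.parametrize(
        "index,risk", [(0.564, "high"), (0.121, "low"), (0.501, "low")]
    )
    def test_cutoff_rule_is_strict(self, index, risk):
        model = LinearIndexModel([], np.array([]), intercept=index)
        got_index, got_risk = score_and_classify(pd.DataFrame(index=[0]), model)
        assert got_index[0] == pytest.approx(index)
        assert got_risk[0] == risk

    def test_default_cutoff_is_published(self):
        assert RiskThreshold().cutoff == PUBLISHED_CUTOFF == 0.501


# ---------------------------------------------------------------------------
# estimator behaviour and recovery
# ---------------------------------------------------------------------------


class TestEstimator:
    def test_sklearn_contract(self, cohort64):
        from sklearn.base import clone

        data, labels = cohort64
        est = CombinedIndexRegressor(k_max=4)
        clone(est)  # get_params/set_params round-trip
        est.fit(data.features, labels)
        assert len(est.selected_features_) == 4
        assert est.coef_.shape == (4,)
        preds = est.predict(data.features)
        assert preds.shape == (64,)
        risk = est.classify(data.features)
        assert set(risk) <= {"high", "low"}

    def test_pool_restriction(self, cohort64, taxonomy):
        data, labels = cohort64
        est = CombinedIndexRegressor(pool="portal", k_max=11).fit(data.features, labels)
        assert len(est.selected_features_) == 11
        assert all(taxonomy.region_of(n) == "portal" for n in est.selected_features_)

    def test_model_json_roundtrip(self, tmp_path, cohort64):
        data, labels = cohort64
        est = CombinedIndexRegressor(k_max=3).fit(data.features, labels)
        path = tmp_path / "model.json"
        est.model_.to_json(path)
        back = LinearIndexModel.from_json(path)
        np.testing.assert_allclose(back.score(data.features), est.predict(data.features))

    def test_planted_signal_recovery_noiseless(self):
        # uncorrelated features, no latent noise: regressing the latent itself
        # must recover the planted feature set and proportional coefficients
        params = CohortSimParams(noise_sd=0.0, severity_corr=0.0, seed=9)
        data = generate_cohort(params)
        planted = list(params.true_feature_names)
        sel = sequential_forward_selection(
            apply_normalization(data.features, fit_normalization(data.features)),
            data.latent_index,
            k_max=len(planted),
        )
        assert set(sel) == set(planted)
        Xn = apply_normalization(data.features, fit_normalization(data.features))
        model = fit_linear_index(Xn[planted], data.latent_index)
        ratios = model.coefficients / np.asarray(params.true_coefficients)
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-6)

    def test_noiseless_loocv_ranks_labels_perfectly(self):
        from qfibrec.outcome_stats import roc_auc

        data = generate_cohort(CohortSimParams(noise_sd=0.0, seed=10))
        labels = np.array([r.early_recurrence for r in data.records])
        res = loocv_predict(data.features, labels)
        assert roc_auc(res.predictions, labels).auc >= 0.99
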