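"""Cross-validated prediction, greedy wrapper selection, final fits."""

import numpy as np
import pandas as pd
import pytest

from painsense import (
    CVConfig,
    ModelSpec,
    cv_predict,
    fit_final,
    wrapper_select,
)
from painsense.types import ValidationError


def linear_data(rng, n=60, n_features=3, noise=0.01):
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    y = 3.0 * X["f0"].to_numpy() + rng.normal(0, noise, n)
    return X, y


def oracle_greedy_forward(spec, X, y, cv, tol):
    """Independent exhaustive-greedy search: at every step evaluate every
    candidate addition (lexicographic order, strict improvement picks the
    first), sharing only the CV objective with the implementation."""
    def obj(cols):
        preds = cv_predict(spec, X[list(cols)], y, cv)
        return float(np.sqrt(np.mean((np.asarray(y) - preds) ** 2)))

    chosen = []
    best_so_far = obj([])
    candidates = sorted(X.columns)
    while candidates:
        scores = [(obj(chosen + [c]), c) for c in candidates]
        best_score = min(s for s, _ in scores)
        best_c = next(c for s, c in scores if s == best_score)
        if best_so_far - best_score > tol:
            chosen.append(best_c)
            candidates.remove(best_c)
            best_so_far = best_score
        else:
            break
    return chosen, best_so_far


class TestCvPredict:
    def test_linear_truth_recovered_by_ridge(self, rng):
        X, y = linear_data(rng, n=80)
        preds = cv_predict(ModelSpec("ridge", hyperparams={"alpha": 1e-6}), X, y)
        oof_rmse = np.sqrt(np.mean((y - preds) ** 2))
        assert oof_rmse < 0.05 * np.std(y)

    def test_leave_one_out_boundary(self, rng):
        X, y = linear_data(rng, n=12)
        preds = cv_predict(ModelSpec("ridge"), X, y, CVConfig(k=12))
        assert preds.shape == (12,)

    def test_deterministic_given_seed(self, rng):
        X, y = linear_data(rng, n=40)
        cv = CVConfig(k=5, shuffle_seed=3)
        for family in ("ridge", "lasso", "gpr", "svr"):
            a = cv_predict(ModelSpec(family), X, y, cv)
            b = cv_predict(ModelSpec(family), X, y, cv)
            np.testing.assert_array_equal(a, b)

    def test_too_few_samples_rejected(self, rng):
        X, y = linear_data(rng, n=5)
        with pytest.raises(ValidationError, match="smaller than k"):
            cv_predict(ModelSpec("ridge"), X, y, CVConfig(k=10))

    def test_empty_feature_set_predicts_training_mean(self, rng):
        X, y = linear_data(rng, n=30)
        preds = cv_predict(ModelSpec("ridge"), X[[]], y, CVConfig(k=3, shuffle_seed=0))
        # each prediction is a fold-mean, so all lie within the y range
        assert preds.min() >= y.min() and preds.max() <= y.max()
        assert np.unique(preds).size <= 3

    def test_missing_values_rejected(self, rng):
        X, y = linear_data(rng, n=30)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            cv_predict(ModelSpec("ridge"), X, y, CVConfig(k=3))

    def test_svm_classifier_predicts_levels(self, rng):
        X, _ = linear_data(rng, n=60, n_features=2)
        y = (X["f0"] > 0).astype(int).to_numpy() * 3
        preds = cv_predict(ModelSpec("svm"), X, y, CVConfig(k=5))
        assert set(np.unique(preds)) <= {0.0, 3.0}
        assert np.mean(preds == y) > 0.8


class TestWrapperSelect:
    @pytest.mark.parametrize("family", ["ridge", "svr"])
    def test_forward_matches_exhaustive_greedy_oracle(self, rng, family):
        spec = ModelSpec(family)
        cv = CVConfig(k=5, shuffle_seed=1)
        for _ in range(3):
            n_feat = int(rng.integers(3, 7))
            X = pd.DataFrame(rng.normal(size=(40, n_feat)),
                             columns=[f"g{i}" for i in range(n_feat)])
            y = X.iloc[:, 0].to_numpy() * 2 + rng.normal(0, 0.5, 40)
            res = wrapper_select("forward", spec, X, y, cv, tol=1e-4)
            oracle_sel, oracle_obj = oracle_greedy_forward(spec, X, y, cv, 1e-4)
            assert res.selected == oracle_sel
            assert res.objective == pytest.approx(oracle_obj, rel=1e-12)

    def test_single_informative_feature_selected(self, rng):
        X = pd.DataFrame({"only": rng.normal(size=50)})
        y = 2.0 * X["only"].to_numpy() + rng.normal(0, 0.1, 50)
        res = wrapper_select("forward", ModelSpec("ridge"), X, y, CVConfig(k=5))
        assert res.selected == ["only"]

    def test_single_noise_feature_rejected(self, rng):
        X = pd.DataFrame({"noise": rng.normal(size=50)})
        y = rng.normal(size=50)
        res = wrapper_select("forward", ModelSpec("ridge"), X, y, CVConfig(k=5))
        assert res.selected == []

    def test_backward_no_worse_than_full_set(self, rng):
        cv = CVConfig(k=5, shuffle_seed=2)
        spec = ModelSpec("ridge")
        X, y = linear_data(rng, n=50, n_features=6, noise=0.5)
        full_preds = cv_predict(spec, X, y, cv)
        full_rmse = float(np.sqrt(np.mean((y - full_preds) ** 2)))
        res = wrapper_select("backward", spec, X, y, cv, tol=1e-4)
        assert res.objective <= full_rmse + 1e-4

    def test_forward_trajectory_recorded(self, rng):
        X, y = linear_data(rng, n=40, n_features=3)
        res = wrapper_select("forward", ModelSpec("ridge"), X, y, CVConfig(k=4))
        # empty set + every candidate evaluation appears in the trajectory
        assert res.trajectory[0][0] == ()
        assert len(res.trajectory) >= 1 + 3

    def test_svm_objective_rejected(self, rng):
        X, y = linear_data(rng, n=40)
        with pytest.raises(ValidationError, match="svm"):
            wrapper_select("forward", ModelSpec("svm"), X, y)


class TestFitFinal:
    def test_predict_close_to_training_targets(self, rng):
        X, y = linear_data(rng, n=50)
        model = fit_final(ModelSpec("ridge", hyperparams={"alpha": 1e-6}),
                          X, y, selected=["f0"])
        assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) < 0.1 * np.std(y)

    def test_missing_selected_column_named(self, rng):
        X, y = linear_data(rng, n=30)
        model = fit_final(ModelSpec("ridge"), X, y, selected=["f0", "f1"])
        with pytest.raises(ValidationError, match="f1"):
            model.predict(X[["f0"]])

    def test_huge_regularization_predicts_mean(self, rng):
        X, y = linear_data(rng, n=40)
        model = fit_final(ModelSpec("ridge", hyperparams={"alpha": 1e9}),
                          X, y, selected=list(X.columns))
        np.testing.assert_allclose(model.predict(X), np.mean(y), atol=0.01 * np.std(y))

    def test_empty_selection_rejected(self, rng):
        X, y = linear_data(rng, n=30)
        with pytest.raises(ValidationError, match="non-empty"):
            fit_final(ModelSpec("ridge"), X, y, selected=[])


class TestFamilyBehaviour:
    def test_all_families_beat_mean_only_with_signal(self, rng):
        """Out-of-fold RMSE stays at or below the mean-only baseline (the
        population sd of y) plus slack, for every family, across seeds."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(80, 4)), columns=list("abcd"))
            y = 2.0 * X["a"].to_numpy() - X["b"].to_numpy() + r.normal(0, 0.5, 80)
            sd = np.std(y)
            for family in ("ridge", "lasso", "gpr", "svr"):
                preds = cv_predict(ModelSpec(family), X, y, CVConfig(k=10, shuffle_seed=seed))
                oof = np.sqrt(np.mean((y - preds) ** 2))
                assert oof <= sd + 0.05 * sd, (family, seed)

    def test_kernel_families_win_on_quadratic_link(self):
        """With a quadratic feature-target link (the inverted-U residual
        situation), GPR/SVR beat ridge/lasso in a majority of seeds."""
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            r = np.random.default_rng(100 + seed)
            X = pd.DataFrame({"x": r.uniform(-2, 2, 90), "z": r.normal(size=90)})
            y = 4.0 - X["x"].to_numpy() ** 2 + r.normal(0, 0.3, 90)
            cv = CVConfig(k=10, shuffle_seed=seed)

            def oof(family):
                p = cv_predict(ModelSpec(family), X, y, cv)
                return np.sqrt(np.mean((y - p) ** 2))

            best_nonlinear = min(oof("gpr"), oof("svr"))
            best_linear = min(oof("ridge"), oof("lasso"))
            wins += best_nonlinear < best_linear
        assert wins > n_seeds // 2
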