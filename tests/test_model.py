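"""Cross-validated boosted regression: scoring, folds, tuning."""

import warnings

import numpy as np
import pandas as pd
import pytest

import relmine as rm
from relmine.model import (
    ModelConfig,
    cross_validate_target,
    run_all_targets,
    summary_table,
    tune_hyperparameters,
)


def binary_features(n, p, seed, density=0.4):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        (rng.random((n, p)) < density).astype(np.int64),
        columns=[f"ilp{i + 1}" for i in range(p)],
        index=[f"g{i:04d}" for i in range(n)],
    )
    return X, rng


class TestCrossValidate:
    def test_perfect_linear_signal_near_r2_one(self):
        X, rng = binary_features(500, 10, 0)
        y = pd.Series(3.0 * X["ilp4"], index=X.index, name="prot", dtype=float)
        res = cross_validate_target(X, y, ModelConfig(seed=0))
        assert res.mean_r2 >= 0.95
        assert len(res.r2_folds) == 5

    def test_pure_noise_target_r2_not_positive(self):
        X, rng = binary_features(500, 10, 1)
        y = pd.Series(rng.normal(0, 1, 500), index=X.index, name="noise")
        res = cross_validate_target(X, y, ModelConfig(seed=1))
        assert -0.3 < res.mean_r2 <= 0.05

    def test_train_mean_baseline_r2_near_zero(self):
        """Predicting the train-fold mean scores ~0 held-out R^2."""
        from sklearn.model_selection import KFold

        X, rng = binary_features(500, 5, 2)
        y = rng.normal(0, 1, 500)
        scores = []
        for tr, te in KFold(5, shuffle=True, random_state=0).split(X):
            pred = np.full(len(te), y[tr].mean())
            ss_res = np.sum((y[te] - pred) ** 2)
            ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
            scores.append(1 - ss_res / ss_tot)
        assert abs(np.mean(scores)) < 0.05

    def test_constant_target_rejected(self):
        X, _ = binary_features(50, 3, 3)
        y = pd.Series(1.0, index=X.index, name="const")
        with pytest.raises(ValueError, match="constant"):
            cross_validate_target(X, y, ModelConfig(seed=0))

    def test_too_few_rows_rejected(self):
        X, rng = binary_features(4, 3, 4)
        y = pd.Series(rng.normal(size=4), index=X.index, name="t")
        with pytest.raises(ValueError, match="folds"):
            cross_validate_target(X, y, ModelConfig(n_folds=5, seed=0))

    def test_missing_y_rows_dropped_per_target(self):
        X, rng = binary_features(100, 4, 5)
        y = pd.Series(rng.normal(size=100), index=X.index, name="t")
        y.iloc[:20] = np.nan
        res = cross_validate_target(X, y, ModelConfig(seed=0))
        assert res.n_rows == 80
        assert res.oof_predictions.index.equals(y.dropna().index)

    def test_fold_partition_disjoint_cover_and_shared(self):
        X, rng = binary_features(120, 4, 6)
        y1 = pd.Series(rng.normal(size=120), index=X.index, name="a")
        y2 = pd.Series(rng.normal(size=120), index=X.index, name="b")
        r1 = cross_validate_target(X, y1, ModelConfig(seed=9))
        r2 = cross_validate_target(X, y2, ModelConfig(seed=9))
        flat = [i for fold in r1.fold_test_index for i in fold]
        assert sorted(flat) == sorted(X.index)
        assert len(flat) == len(set(flat))
        assert r1.fold_test_index == r2.fold_test_index

    def test_r2_matches_independent_reimplementation(self):
        X, rng = binary_features(200, 6, 7)
        y = pd.Series(
            2.0 * X["ilp2"] + rng.normal(0, 0.5, 200), index=X.index, name="t"
        )
        res = cross_validate_target(X, y, ModelConfig(seed=3))
        for fold, (rows, r2) in enumerate(zip(res.fold_test_index, res.r2_folds)):
            yt = y.loc[rows].to_numpy()
            pred = res.oof_predictions.loc[rows].to_numpy()
            ref = 1.0 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2)
            assert abs(r2 - ref) < 1e-10

    def test_mean_sd_consistent_with_folds(self):
        X, rng = binary_features(150, 4, 8)
        y = pd.Series(
            X["ilp1"] + rng.normal(0, 1, 150), index=X.index, name="t"
        )
        res = cross_validate_target(X, y, ModelConfig(seed=0))
        assert res.mean_r2 == pytest.approx(np.mean(res.r2_folds))
        assert res.sd_r2 == pytest.approx(np.std(res.r2_folds, ddof=1))
        assert all(r <= 1.0 for r in res.r2_folds)


class TestRunAllTargets:
    def test_ranking_strong_weak_noise(self):
        X, rng = binary_features(400, 8, 10, density=0.5)
        bit = X["ilp3"].to_numpy()
        Y = pd.DataFrame(
            {
                "strong": 2.0 * bit + rng.normal(0, 0.5, 400),
                "weak": 0.5 * bit + rng.normal(0, 0.5, 400),
                "noise": rng.normal(0, 0.5, 400),
            },
            index=X.index,
        )
        results, errors = run_all_targets(X, Y, ModelConfig(seed=2))
        assert not errors
        board = summary_table(results)
        assert board["target"].tolist()[:2] == ["strong", "weak"]
        assert board["target"].tolist()[-1] == "noise"

    def test_duplicated_target_identical_result(self):
        X, rng = binary_features(200, 5, 11)
        y = 1.5 * X["ilp1"].to_numpy() + rng.normal(0, 0.5, 200)
        Y = pd.DataFrame({"a": y, "b": y}, index=X.index)
        results, _ = run_all_targets(X, Y, ModelConfig(seed=4))
        da, db = results[0].to_dict(), results[1].to_dict()
        da.pop("target"), db.pop("target")
        assert da == db

    def test_empty_target_matrix(self):
        X, _ = binary_features(50, 3, 12)
        results, errors = run_all_targets(
            X, pd.DataFrame(index=X.index), ModelConfig(seed=0)
        )
        assert results == [] and errors == {}

    def test_per_target_errors_recorded_run_continues(self):
        X, rng = binary_features(100, 4, 13)
        Y = pd.DataFrame(
            {
                "bad": np.ones(100),
                "good": X["ilp1"].to_numpy() + rng.normal(0, 0.3, 100),
            },
            index=X.index,
        )
        results, errors = run_all_targets(X, Y, ModelConfig(seed=0))
        assert [r.target for r in results] == ["good"]
        assert "bad" in errors and "constant" in errors["bad"]


class TestTuning:
    def test_budget_one_returns_single_evaluated_config(self):
        X, rng = binary_features(120, 5, 14)
        y = pd.Series(
            X["ilp2"] + rng.normal(0, 0.5, 120), index=X.index, name="t"
        )
        cfg = tune_hyperparameters(X, y, budget=1, seed=3)
        assert isinstance(cfg, ModelConfig)
        # the returned config is inside the documented space
        assert 0.01 <= cfg.learning_rate <= 0.3
        assert 2 <= cfg.max_depth <= 8

    def test_best_mse_monotone_in_budget(self):
        X, rng = binary_features(150, 5, 15)
        y = pd.Series(
            2.0 * X["ilp1"] + rng.normal(0, 0.5, 150), index=X.index, name="t"
        )
        m_small = cross_validate_target(
            X, y, tune_hyperparameters(X, y, budget=3, seed=5)
        ).mean_mse
        m_large = cross_validate_target(
            X, y, tune_hyperparameters(X, y, budget=8, seed=5)
        ).mean_mse
        assert m_large <= m_small + 1e-12

    def test_tuned_not_much_worse_than_default_on_strong_signal(self):
        X, rng = binary_features(300, 6, 16, density=0.5)
        y = pd.Series(
            2.0 * X["ilp4"] + rng.normal(0, 0.5, 300), index=X.index, name="t"
        )
        default = cross_validate_target(X, y, ModelConfig(seed=6)).mean_r2
        tuned_cfg = tune_hyperparameters(X, y, budget=8, seed=6)
        tuned = cross_validate_target(X, y, tuned_cfg).mean_r2
        assert tuned >= default - 0.02

    def test_invalid_budget(self):
        X, rng = binary_features(50, 3, 17)
        y = pd.Series(rng.normal(size=50), index=X.index, name="t")
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, budget=0)
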