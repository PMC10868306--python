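"""Shapley and gain attribution, aggregation, max-deviation reports."""

import numpy as np
import pandas as pd
import pytest

import relmine as rm
from relmine.explain import (
    AttributionMatrix,
    aggregate_importance,
    gain_attribution,
    importance_table,
    max_deviation_report,
    mean_abs_shap,
    shapley_attribution,
)
from relmine.model import ModelConfig, cross_validate_target


def make_target(n=300, p=8, seed=0, effect=2.0, noise=0.5, signal_col="ilp3"):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        (rng.random((n, p)) < 0.4).astype(np.int64),
        columns=[f"ilp{i + 1}" for i in range(p)],
        index=[f"g{i:04d}" for i in range(n)],
    )
    y = pd.Series(
        effect * X[signal_col] + rng.normal(0, noise, n),
        index=X.index,
        name="prot",
    )
    return X, y


class TestShapley:
    def test_local_accuracy_within_1e6_everywhere(self):
        for seed, effect in [(0, 2.0), (1, 0.0)]:
            X, y = make_target(seed=seed, effect=effect, noise=1.0)
            res = cross_validate_target(X, y, ModelConfig(seed=seed))
            attr = shapley_attribution(res, X)
            assert attr.local_accuracy_error() < 1e-6
            attr.assert_local_accuracy(1e-6)

    def test_matches_xgboost_builtin_treeshap(self):
        """Cross-check against the backend's own (float32) exact TreeSHAP."""
        import xgboost as xgb

        X, y = make_target(seed=2)
        res = cross_validate_target(X, y, ModelConfig(seed=2))
        attr = shapley_attribution(res, X)
        for model, rows in zip(res.models, res.fold_test_index):
            ref = model.get_booster().predict(
                xgb.DMatrix(X.loc[rows]), pred_contribs=True
            )
            mine = attr.values.loc[rows].to_numpy()
            assert np.abs(mine - ref[:, :-1]).max() < 1e-4
            assert np.abs(
                attr.base_values.loc[rows].to_numpy() - ref[:, -1]
            ).max() < 1e-4

    def test_single_feature_model_attributes_only_it(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"ilp1": (rng.random(200) < 0.5).astype(np.int64)},
            index=[f"g{i}" for i in range(200)],
        )
        y = pd.Series(2.0 * X["ilp1"] + rng.normal(0, 0.3, 200), index=X.index,
                      name="t")
        res = cross_validate_target(X, y, ModelConfig(seed=3))
        attr = shapley_attribution(res, X)
        assert (attr.values["ilp1"].abs() > 0).any()

    def test_unused_feature_has_zero_mean_abs_shap_and_gain(self):
        X, y = make_target(seed=4, effect=3.0, noise=0.1)
        X = X.copy()
        X["ilp_dead"] = 0  # constant: cannot be split on
        res = cross_validate_target(X, y, ModelConfig(seed=4))
        attr = shapley_attribution(res, X)
        assert mean_abs_shap(attr)["ilp_dead"] == 0.0
        assert gain_attribution(res)["ilp_dead"] == 0.0

    def test_planted_pattern_is_top_attribution(self):
        for seed in range(3):
            X, y = make_target(seed=seed, effect=2.0, noise=0.5)
            res = cross_validate_target(X, y, ModelConfig(seed=seed))
            attr = shapley_attribution(res, X)
            assert mean_abs_shap(attr).idxmax() == "ilp3"
            assert gain_attribution(res).idxmax() == "ilp3"

    def test_out_of_fold_rows_cover_all_used_rows(self):
        X, y = make_target(seed=5)
        y.iloc[:30] = np.nan
        res = cross_validate_target(X, y, ModelConfig(seed=5))
        attr = shapley_attribution(res, X)
        assert attr.values.index.equals(res.oof_predictions.index)

    def test_refit_on_all_variant(self):
        X, y = make_target(seed=6)
        res = cross_validate_target(X, y, ModelConfig(seed=6))
        attr = shapley_attribution(res, X, refit_on_all=True)
        assert attr.local_accuracy_error() < 1e-6
        assert mean_abs_shap(attr).idxmax() == "ilp3"

    def test_non_tree_learner_rejected(self):
        from sklearn.linear_model import LinearRegression

        X, y = make_target(seed=7)
        res = cross_validate_target(X, y, ModelConfig(seed=7))
        res.models = [LinearRegression().fit(X, y)] * len(res.models)
        with pytest.raises(TypeError, match="sampling"):
            shapley_attribution(res, X)


class TestGain:
    def test_single_feature_gets_all_gain(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(
            {"ilp1": (rng.random(200) < 0.5).astype(np.int64)},
            index=[f"g{i}" for i in range(200)],
        )
        y = pd.Series(X["ilp1"] + rng.normal(0, 0.2, 200), index=X.index, name="t")
        res = cross_validate_target(X, y, ModelConfig(seed=8))
        g = gain_attribution(res)
        assert g["ilp1"] == pytest.approx(1.0)

    def test_l1_normalized(self):
        X, y = make_target(seed=9)
        res = cross_validate_target(X, y, ModelConfig(seed=9))
        assert gain_attribution(res).sum() == pytest.approx(1.0)


class TestAggregation:
    def test_identical_vectors_aggregate_to_themselves(self):
        v = pd.Series({"a": 0.6, "b": 0.3, "c": 0.1})
        agg = aggregate_importance({"t1": v, "t2": v}, {"t1": 0.5, "t2": 0.4})
        assert agg.n_targets == 2
        assert agg.frame["mean_share"].to_dict() == pytest.approx(v.to_dict())
        assert (agg.frame["ci_hi"] - agg.frame["ci_lo"]).abs().max() == 0.0

    def test_r2_filter_excludes_nonpositive(self):
        va = pd.Series({"a": 1.0, "b": 0.0})
        vb = pd.Series({"a": 0.0, "b": 1.0})
        agg = aggregate_importance(
            {"good": va, "bad": vb}, {"good": 0.3, "bad": -0.1}, r2_threshold=0.0
        )
        assert agg.n_targets == 1
        assert agg.frame["mean_share"]["a"] == pytest.approx(1.0)

    def test_no_qualifying_target_raises(self):
        v = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="no target"):
            aggregate_importance({"t": v}, {"t": -0.5}, r2_threshold=0.0)

    def test_threshold_none_includes_everything(self):
        v = pd.Series({"a": 1.0})
        agg = aggregate_importance({"t": v}, {"t": -0.5}, r2_threshold=None)
        assert agg.n_targets == 1

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(10)
        vs = {f"t{i}": pd.Series(rng.random(5), index=list("abcde")) for i in range(4)}
        r2 = {t: 0.2 for t in vs}
        a = aggregate_importance(vs, r2)
        b = aggregate_importance(dict(reversed(list(vs.items()))), r2)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        # duplicating a target whose vector equals the others leaves the
        # aggregate mean unchanged
        same = pd.Series(rng.random(5), index=list("abcde"))
        base = aggregate_importance({"t1": same, "t2": same}, {"t1": 0.2, "t2": 0.2})
        dup = aggregate_importance(
            {"t1": same, "t2": same, "t2_copy": same},
            {"t1": 0.2, "t2": 0.2, "t2_copy": 0.2},
        )
        assert dup.frame["mean_share"].to_dict() == pytest.approx(
            base.frame["mean_share"].to_dict()
        )

    def test_max_normalization_variant(self):
        v = pd.Series({"a": 0.4, "b": 0.2})
        agg = aggregate_importance({"t": v}, {"t": 0.5}, normalization="max")
        assert agg.frame["mean_share"]["a"] == pytest.approx(1.0)
        assert agg.frame["mean_share"]["b"] == pytest.approx(0.5)

    def test_importance_table_combines_shap_and_gain(self):
        v = pd.Series({"a": 0.7, "b": 0.3})
        g = pd.Series({"a": 0.5, "b": 0.5})
        table = importance_table(
            aggregate_importance({"t": v}, {"t": 0.5}),
            aggregate_importance({"t": g}, {"t": 0.5}),
        )
        assert list(table.columns) == [
            "mean_share_shapley", "ci_lo", "ci_hi", "mean_share_gain",
        ]


class TestMaxDeviation:
    def test_rare_strong_pattern_beats_common_weak_on_max_deviation(self):
        """A rare descriptor with a large planted effect outranks a common
        weak one under max-deviation while losing under mean |Shapley|."""
        rng = np.random.default_rng(12)
        n = 400
        rare = np.zeros(n, dtype=np.int64)
        rare[rng.choice(n, size=5, replace=False)] = 1  # support 5 of 400
        common = (rng.random(n) < 0.5).astype(np.int64)
        X = pd.DataFrame(
            {"ilp_rare": rare, "ilp_common": common},
            index=[f"g{i:04d}" for i in range(n)],
        )
        y = pd.Series(
            5.0 * rare + 0.5 * common + rng.normal(0, 0.1, n),
            index=X.index,
            name="t",
        )
        res = cross_validate_target(X, y, ModelConfig(seed=12, min_child_weight=1.0))
        attr = shapley_attribution(res, X)
        assert mean_abs_shap(attr).idxmax() == "ilp_common"
        report = max_deviation_report(attr, 2)
        assert report["feature"].iloc[0] == "ilp_rare"

    def test_single_feature_extreme(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(
            {"ilp1": (rng.random(150) < 0.5).astype(np.int64)},
            index=[f"g{i}" for i in range(150)],
        )
        y = pd.Series(X["ilp1"] + rng.normal(0, 0.2, 150), index=X.index, name="t")
        res = cross_validate_target(X, y, ModelConfig(seed=13))
        attr = shapley_attribution(res, X)
        rep = max_deviation_report(attr, 1)
        assert rep["feature"].iloc[0] == "ilp1"
        assert rep["max_abs_shap"].iloc[0] == pytest.approx(
            attr.values["ilp1"].abs().max()
        )

    def test_all_zero_ties_broken_by_feature_id(self):
        idx = [f"g{i}" for i in range(4)]
        zeros = pd.DataFrame(0.0, index=idx, columns=["ilp2", "ilp1", "ilp3"])
        attr = AttributionMatrix(
            "t", zeros, pd.Series(0.0, index=idx), pd.Series(0.0, index=idx)
        )
        rep = max_deviation_report(attr, 3)
        assert rep["feature"].tolist() == ["ilp1", "ilp2", "ilp3"]
        assert (rep["max_abs_shap"] == 0).all()

    def test_k_beyond_feature_count_warns_and_truncates(self):
        idx = ["g1", "g2"]
        attr = AttributionMatrix(
            "t",
            pd.DataFrame(0.0, index=idx, columns=["a"]),
            pd.Series(0.0, index=idx),
            pd.Series(0.0, index=idx),
        )
        with pytest.warns(UserWarning, match="truncating"):
            rep = max_deviation_report(attr, 5)
        assert len(rep) == 1
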