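"""Feature attribution: Shapley values, split gain, cross-model reports.

Two complementary importance views are computed per protein model:

* **Shapley values** (exact, tree-specific): an additive per-sample
  decomposition of the model output, computed out-of-fold -- each fold
  model attributes only its held-out rows, so importances inherit the
  cross-validation discipline of the evaluation. Mean |Shapley| per
  feature summarises global importance; the maximum |Shapley| over
  samples highlights descriptors that move individual predictions
  strongly even when rare.
* **Gain** (model-specific): total split-gain credited to each feature,
  summed over fold models and L1-normalized.

For cross-model figures, per-target importance vectors are normalized
(L1 shares by default, max-scaling optional), averaged over all targets
whose mean CV R^2 exceeds a threshold (``> 0`` by convention, excluding
models no better than the mean), and reported with a normal-approximation
95% confidence interval across targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._treeshap import TreeEnsemble, margin_predictions, shap_values
from .model import TargetResult

__all__ = [
    "AttributionMatrix",
    "ImportanceSummary",
    "shapley_attribution",
    "mean_abs_shap",
    "gain_attribution",
    "aggregate_importance",
    "importance_table",
    "max_deviation_report",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(eq=False)
class AttributionMatrix:
    """Per-sample per-feature Shapley values for one target (target units)."""

    target: str
    values: pd.DataFrame  # rows = samples (ORF), columns = features
    base_values: pd.Series  # per-sample base value (per fold model)
    predictions: pd.Series  # margin predictions of the attributing model

    def local_accuracy_error(self) -> float:
        """max over samples of |base + sum(phi) - prediction|."""
        total = self.base_values.to_numpy() + self.values.to_numpy().sum(axis=1)
        return float(np.max(np.abs(total - self.predictions.to_numpy())))

    def assert_local_accuracy(self, tol: float = 1e-6) -> None:
        err = self.local_accuracy_error()
        if err > tol:
            raise AssertionError(
                f"local accuracy violated for {self.target}: {err:.3g} > {tol}"
            )


def _ensemble(model) -> TreeEnsemble:
    get_booster = getattr(model, "get_booster", None)
    if get_booster is None:
        raise TypeError(
            "exact Shapley attribution requires a tree booster exposing "
            "get_booster(); use a sampling-based explainer for other learners"
        )
    return TreeEnsemble(get_booster())


def shapley_attribution(
    result: TargetResult, X: pd.DataFrame, refit_on_all: bool = False
) -> AttributionMatrix:
    """Exact Shapley values for one target's fitted models.

    By default each fold model attributes its *held-out* rows and the
    per-fold matrices are concatenated (out-of-fold attribution, matching
    the cross-validated evaluation). With ``refit_on_all`` a single model
    is refit on all usable rows and attributes every row; this is the
    optimistic variant and is off by default.

    The local-accuracy identity ``base + sum(phi) = prediction`` holds to
    float64 precision on every row.
    """
    used = result.oof_predictions.index
    Xu = X.loc[used]
    cols = list(Xu.columns)
    if refit_on_all:
        from sklearn.base import clone

        model = clone(result.models[0])
        model.fit(Xu, result.y_used)
        ens = _ensemble(model)
        phi, base = shap_values(ens, Xu.to_numpy(dtype=np.float64))
        return AttributionMatrix(
            target=result.target,
            values=pd.DataFrame(phi, index=Xu.index, columns=cols),
            base_values=pd.Series(base, index=Xu.index),
            predictions=pd.Series(
                margin_predictions(ens, Xu.to_numpy(dtype=np.float64)),
                index=Xu.index,
            ),
        )
    frames = []
    bases = []
    preds = []
    for model, rows in zip(result.models, result.fold_test_index):
        ens = _ensemble(model)
        Xf = Xu.loc[rows]
        phi, base = shap_values(ens, Xf.to_numpy(dtype=np.float64))
        frames.append(pd.DataFrame(phi, index=Xf.index, columns=cols))
        bases.append(pd.Series(base, index=Xf.index))
        preds.append(
            pd.Series(
                margin_predictions(ens, Xf.to_numpy(dtype=np.float64)),
                index=Xf.index,
            )
        )
    values = pd.concat(frames).loc[used]
    return AttributionMatrix(
        target=result.target,
        values=values,
        base_values=pd.concat(bases).loc[used],
        predictions=pd.concat(preds).loc[used],
    )


def mean_abs_shap(attr: AttributionMatrix) -> pd.Series:
    """Global importance: mean |Shapley| per feature (target units)."""
    return attr.values.abs().mean(axis=0)


def gain_attribution(result: TargetResult) -> pd.Series:
    """Total split gain per feature over fold models, L1-normalized.

    Features never used in any split receive exactly 0.
    """
    feature_names = None
    total: dict[str, float] = {}
    for model in result.models:
        booster = _ensemble(model)  # validates it is a tree model
        bst = model.get_booster()
        feature_names = bst.feature_names
        for feat, gain in bst.get_score(importance_type="total_gain").items():
            total[feat] = total.get(feat, 0.0) + float(gain)
    vec = pd.Series(total, dtype=float).reindex(feature_names).fillna(0.0)
    s = vec.sum()
    return vec / s if s > 0 else vec


def _normalize(vec: pd.Series, method: str) -> pd.Series:
    v = vec.astype(float).abs()
    if method == "l1":
        s = v.sum()
        return v / s if s > 0 else v
    if method == "max":
        m = v.max()
        return v / m if m > 0 else v
    raise ValueError(f"unknown normalization {method!r} (use 'l1' or 'max')")


@dataclass(eq=False)
class ImportanceSummary:
    """Cross-model aggregate of normalized per-feature importances."""

    frame: pd.DataFrame  # index feature; mean_share, ci_lo, ci_hi
    n_targets: int
    normalization: str

    def top(self, k: int) -> pd.DataFrame:
        return self.frame.head(k)


def aggregate_importance(
    per_target: Mapping[str, pd.Series],
    r2_table: Mapping[str, float],
    r2_threshold: float | None = 0.0,
    normalization: str = "l1",
) -> ImportanceSummary:
    """Normalize per-target importance vectors and average feature-wise.

    Targets with mean R^2 <= ``r2_threshold`` are excluded (the
    positive-R^2 convention for cross-model figures); pass ``None`` to
    aggregate over every target regardless of fit quality. Each included
    vector is normalized (L1 shares by default) and the across-target
    mean with a normal-approximation 95% CI per feature is returned,
    ranked by mean share descending (ties by feature id).
    """
    if r2_threshold is None:
        included = sorted(per_target)
    else:
        included = sorted(
            t for t in per_target if r2_table[t] > r2_threshold
        )
    if not included:
        raise ValueError(
            f"no target with mean R^2 above {r2_threshold}; nothing to aggregate"
        )
    mat = pd.DataFrame(
        {t: _normalize(per_target[t], normalization) for t in included}
    )
    mean = mat.mean(axis=1)
    n = len(included)
    if n > 1:
        half = Z95 * mat.std(axis=1, ddof=1) / np.sqrt(n)
    else:
        half = pd.Series(0.0, index=mat.index)
    frame = pd.DataFrame(
        {"mean_share": mean, "ci_lo": mean - half, "ci_hi": mean + half}
    )
    frame = frame.sort_values(
        ["mean_share"], ascending=False, kind="mergesort"
    )
    # stable tie-break by feature id
    frame = frame.loc[
        sorted(frame.index, key=lambda f: (-frame.loc[f, "mean_share"], f))
    ]
    return ImportanceSummary(frame, n_targets=n, normalization=normalization)


def importance_table(
    shap_summary: ImportanceSummary, gain_summary: ImportanceSummary
) -> pd.DataFrame:
    """Combined export table: Shapley shares with CI plus gain shares."""
    out = shap_summary.frame.rename(
        columns={"mean_share": "mean_share_shapley"}
    ).copy()
    out["mean_share_gain"] = gain_summary.frame["mean_share"].reindex(out.index)
    out.index.name = "feature"
    return out


def max_deviation_report(attr: AttributionMatrix, k: int) -> pd.DataFrame:
    """Features ranked by maximum |Shapley| over samples (top-k).

    Each row carries the extreme sample's id and the signed attribution
    there -- descriptors that strongly move a handful of predictions rank
    high here even when their mean |Shapley| is small. Ties are broken by
    feature id; ``k`` beyond the number of features warns and truncates.
    """
    if k > attr.values.shape[1]:
        warnings.warn(
            f"k={k} exceeds {attr.values.shape[1]} features; truncating",
            stacklevel=2,
        )
        k = attr.values.shape[1]
    magnitude = attr.values.abs()
    max_abs = magnitude.max(axis=0)
    order = sorted(attr.values.columns, key=lambda f: (-max_abs[f], f))[:k]
    rows = []
    for f in order:
        sample = magnitude[f].idxmax()
        rows.append(
            {
                "feature": f,
                "max_abs_shap": float(max_abs[f]),
                "sample": sample,
                "value": float(attr.values.at[sample, f]),
            }
        )
    return pd.DataFrame(rows, columns=["feature", "max_abs_shap", "sample", "value"])
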