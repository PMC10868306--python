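"""scikit-learn estimator surface for the mining + propositionalization step.

:class:`RelationalPatternMiner` is a transformer: ``fit`` runs the
levelwise frequent-pattern search over the configured knowledge base
using the input identifiers as positive examples, ``transform`` evaluates
the mined patterns as binary features for any identifier list. It
composes with sklearn pipelines, e.g.::

    Pipeline([
        ("patterns", RelationalPatternMiner(kb=kb, bias=modes)),
        ("booster", make_regressor(ModelConfig())),
    ])

The module-level :func:`relmine.miner.mine` /
:func:`relmine.propositional.propositionalize` functions are the
underlying implementation; the estimator is a thin stateful wrapper.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .kb import KnowledgeBase
from .miner import MinerConstraints, ModeDeclaration, PatternSet, mine
from .pattern import matches

__all__ = ["RelationalPatternMiner"]


def _as_names(X) -> list[str]:
    if isinstance(X, pd.DataFrame):
        if X.shape[1] != 1:
            raise ValueError("expected a single identifier column")
        return [str(v) for v in X.iloc[:, 0]]
    if isinstance(X, pd.Series):
        return [str(v) for v in X]
    arr = np.asarray(X)
    if arr.ndim == 2:
        if arr.shape[1] != 1:
            raise ValueError("expected a single identifier column")
        arr = arr[:, 0]
    return [str(v) for v in arr]


class RelationalPatternMiner(TransformerMixin, BaseEstimator):
    """Mine frequent relational patterns and expose them as binary features.

    Parameters mirror :class:`~relmine.miner.MinerConstraints`; ``kb`` and
    ``bias`` must be provided before fitting. ``X`` is a sequence (or
    single column) of example identifiers of type gene.

    Attributes
    ----------
    pattern_set_ : PatternSet
        Mined patterns with coverage over the fit examples.
    feature_names_out_ : list of str
        Descriptor ids (``ilp1`` ... ``ilpN``) in discovery order.
    """

    def __init__(
        self,
        kb: KnowledgeBase | None = None,
        bias: Sequence[ModeDeclaration] | None = None,
        min_support_fraction: float = 0.00025,
        max_features: int = 2048,
        max_clause_length: int = 10,
        max_var_layers: int = 10,
        drop_coverage_duplicates: bool = False,
        seed: int = 0,
    ):
        self.kb = kb
        self.bias = bias
        self.min_support_fraction = min_support_fraction
        self.max_features = max_features
        self.max_clause_length = max_clause_length
        self.max_var_layers = max_var_layers
        self.drop_coverage_duplicates = drop_coverage_duplicates
        self.seed = seed

    def _constraints(self) -> MinerConstraints:
        return MinerConstraints(
            min_support_fraction=self.min_support_fraction,
            max_features=self.max_features,
            max_clause_length=self.max_clause_length,
            max_var_layers=self.max_var_layers,
            drop_coverage_duplicates=self.drop_coverage_duplicates,
        )

    def fit(self, X, y=None):
        if self.kb is None or not self.bias:
            raise ValueError("kb and bias must be set before fitting")
        names = _as_names(X)
        self.pattern_set_: PatternSet = mine(
            self.kb, names, self.bias, self._constraints(), seed=self.seed
        )
        self.feature_names_out_ = list(self.pattern_set_.ids)
        self.n_features_out_ = len(self.feature_names_out_)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "pattern_set_")
        names = _as_names(X)
        if tuple(names) == tuple(self.pattern_set_.examples):
            data = {
                p.id: cov.bits.astype(np.int64) for p, cov in self.pattern_set_
            }
        else:
            data = {
                p.id: np.fromiter(
                    (matches(p, e, self.kb) for e in names),
                    dtype=np.int64,
                    count=len(names),
                )
                for p, _ in self.pattern_set_
            }
        return pd.DataFrame(data, index=pd.Index(names, name="orf"))

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)
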