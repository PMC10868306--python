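"""Propositionalization: pattern sets -> binary design matrices.

Each mined pattern becomes one 0/1 column (pattern-covers-example
indicator) over the positive examples; the matrix is then inner-joined on
the ORF identifier with quantitative target tables (per-protein
abundances) and, optionally, continuous amino-acid concentration
features. Missing target values are preserved as missing -- rows are
dropped per target at training time, never imputed. Binary features are
stored as 0/1 integers and continuous columns as floats; no scaling is
applied (tree learners are scale-invariant).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kb import Constant
from .miner import PatternSet
from .pattern import translate

__all__ = [
    "PropositionalDataset",
    "propositionalize",
    "merge_targets",
    "add_continuous_features",
]


@dataclass(frozen=True)
class PropositionalDataset:
    """A design matrix keyed by ORF with typed column groups.

    ``frame`` holds all columns; ``feature_columns`` are the binary
    pattern indicators, ``continuous_columns`` the amino-acid
    concentrations, and ``target_columns`` the per-protein abundances.
    ``provenance`` carries the miner's provenance plus join reports.
    """

    frame: pd.DataFrame
    feature_columns: tuple[str, ...] = ()
    continuous_columns: tuple[str, ...] = ()
    target_columns: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate ORF key {dup!r}")
        known = (
            set(self.feature_columns)
            | set(self.continuous_columns)
            | set(self.target_columns)
        )
        unknown = [c for c in self.frame.columns if c not in known]
        if unknown:
            raise ValueError(f"untyped columns: {unknown}")
        overlap = set(self.feature_columns) & set(self.target_columns)
        if overlap:
            raise ValueError(f"columns both feature and target: {sorted(overlap)}")

    @property
    def X(self) -> pd.DataFrame:
        """Predictor block: binary pattern columns then continuous columns."""
        return self.frame[list(self.feature_columns) + list(self.continuous_columns)]

    @property
    def Y(self) -> pd.DataFrame:
        return self.frame[list(self.target_columns)]

    def column_support(self, column: str) -> int:
        return int(self.frame[column].sum())


def propositionalize(
    ps: PatternSet, examples: Sequence[Constant | str]
) -> PropositionalDataset:
    """Binary matrix of shape ``len(examples) x len(ps)``.

    ``examples`` must be exactly the example list the pattern set's
    coverage was computed over, in the same order.
    """
    names = [e.name if isinstance(e, Constant) else e for e in examples]
    if tuple(names) != tuple(ps.examples):
        raise ValueError(
            "examples do not match the pattern set's coverage examples "
            f"({len(names)} given, {len(ps.examples)} mined)"
        )
    data = {p.id: cov.bits.astype(np.int64) for p, cov in ps}
    frame = pd.DataFrame(data, index=pd.Index(names, name="orf"), dtype=np.int64)
    return PropositionalDataset(
        frame,
        feature_columns=tuple(ps.ids),
        provenance=dict(ps.provenance),
    )


def merge_targets(
    d: PropositionalDataset, targets: pd.DataFrame
) -> PropositionalDataset:
    """Inner join on ORF with the quantitative target table.

    Drops non-overlapping keys on both sides (counts recorded in
    ``provenance['merge_report']``); target missing values are preserved.
    A zero-overlap join or a duplicate ORF key raises.
    """
    if targets.index.has_duplicates:
        dup = targets.index[targets.index.duplicated()][0]
        raise ValueError(f"duplicate ORF key in targets: {dup!r}")
    collision = set(targets.columns) & set(d.frame.columns)
    if collision:
        raise ValueError(f"target columns collide with features: {sorted(collision)}")
    common = d.frame.index.intersection(targets.index)
    if len(common) == 0:
        raise ValueError("zero overlap between feature ORFs and target ORFs")
    merged = d.frame.loc[common].join(targets.loc[common], how="inner")
    report = {
        "dropped_feature_rows": int(len(d.frame) - len(common)),
        "dropped_target_rows": int(len(targets) - len(common)),
        "n_rows": int(len(common)),
    }
    prov = {**d.provenance, "merge_report": report}
    return PropositionalDataset(
        merged,
        feature_columns=d.feature_columns,
        continuous_columns=d.continuous_columns,
        target_columns=d.target_columns + tuple(targets.columns),
        provenance=prov,
    )


def add_continuous_features(
    d: PropositionalDataset, aa: pd.DataFrame
) -> PropositionalDataset:
    """Inner-join continuous features (amino-acid concentrations) on ORF.

    The added columns are flagged continuous for downstream typing. The
    knowledge base used for mining must have had the target-derived
    relations (amino-acid accumulation phenotypes) removed before the
    pattern search; if the provenance flag recording that removal is
    absent, a warning cites the leakage rule.
    """
    if not d.feature_columns:
        raise ValueError("dataset has no pattern features yet")
    if aa.index.has_duplicates:
        dup = aa.index[aa.index.duplicated()][0]
        raise ValueError(f"duplicate ORF key in amino-acid table: {dup!r}")
    collision = set(aa.columns) & set(d.frame.columns)
    if collision:
        raise ValueError(
            f"amino-acid columns collide with existing columns: {sorted(collision)}"
        )
    if not d.provenance.get("target_derived_removed"):
        warnings.warn(
            "adding continuous features to patterns mined from a KB without "
            "target-derived relations removed: relations derived from the "
            "prediction targets must be deleted before mining to prevent "
            "leakage",
            stacklevel=2,
        )
    common = d.frame.index.intersection(aa.index)
    if len(common) == 0:
        raise ValueError("zero overlap between dataset ORFs and amino-acid ORFs")
    merged = d.frame.loc[common].join(aa.loc[common].astype(float), how="inner")
    report = {
        "dropped_dataset_rows": int(len(d.frame) - len(common)),
        "dropped_aa_rows": int(len(aa) - len(common)),
        "n_rows": int(len(common)),
    }
    prov = {**d.provenance, "aa_merge_report": report}
    return PropositionalDataset(
        merged,
        feature_columns=d.feature_columns,
        continuous_columns=d.continuous_columns + tuple(aa.columns),
        target_columns=d.target_columns,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# CSV round trip


def write_dataset(d: PropositionalDataset, features_path, sidecar_path=None,
                  ps: PatternSet | None = None) -> None:
    """Write the full frame as CSV plus an optional descriptor sidecar
    (pattern id -> clause text and English translation)."""
    d.frame.to_csv(features_path, float_format="%.10g")
    if sidecar_path is not None and ps is not None:
        mapping = {
            p.id: {"clause": p.to_clause(), "english": translate(p)} for p, _ in ps
        }
        payload = {
            "descriptors": mapping,
            "feature_columns": list(d.feature_columns),
            "continuous_columns": list(d.continuous_columns),
            "target_columns": list(d.target_columns),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
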