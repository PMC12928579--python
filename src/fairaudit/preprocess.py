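"""Deterministic data preparation.

Fixed stage order: clean -> drop_high_missingness -> impute ->
minmax_normalize -> binarize_sensitive -> split.  Imputation and
normalization statistics are fitted on training rows only by default (the
``fit_scope`` switch allows fitting on all rows for the laxer reading);
a leakage guard in the test suite asserts that test rows never influence
fitted statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cohort import (
    Cohort,
    CohortError,
    SensitiveSpec,
    default_sensitive_specs,
    ROLE_CLINICAL,
    ROLE_GROUP,
    ROLE_LEAK,
)

__all__ = [
    "NormalizationParams",
    "SplitPlan",
    "PipelineError",
    "clean",
    "drop_high_missingness",
    "impute",
    "minmax_normalize",
    "binarize_sensitive",
    "exclude_sensitive_from_features",
    "split",
    "prepare",
]


class PipelineError(RuntimeError):
    """A preprocessing stage cannot proceed."""


# ---------------------------------------------------------------------------

def clean(cohort: Cohort) -> Cohort:
    """Remove exact duplicate rows and coerce numeric-like text to numbers.

    The first occurrence of a duplicate is kept and row order is preserved.
    Cells that cannot be coerced become missing.  Always succeeds; change
    counts are logged in ``meta['clean_log']``.
    """
    df = cohort.df.copy()
    before = len(df)
    df = df.drop_duplicates(keep="first").reset_index(drop=True)
    duplicates_removed = before - len(df)

    coerced_cells = 0
    for col in cohort.clinical_columns:
        if df[col].dtype == object:
            as_num = pd.to_numeric(df[col], errors="coerce")
            coerced_cells += int(df[col].notna().sum())
            df[col] = as_num
    out = cohort.copy(df=df)
    out.meta["clean_log"] = {
        "duplicates_removed": duplicates_removed,
        "text_cells_processed": coerced_cells,
    }
    return out


def drop_high_missingness(cohort: Cohort, threshold: float = 0.30) -> Cohort:
    """Drop clinical features with strictly more than ``threshold`` missing.

    A feature at exactly the threshold is retained.  Sensitive and label
    columns are never dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    to_drop = [c for c in cohort.clinical_columns
               if cohort.df[c].isna().mean() > threshold]
    remaining = [c for c in cohort.clinical_columns if c not in to_drop]
    if not remaining:
        raise PipelineError(
            "all clinical features exceed the missingness threshold; "
            "the pipeline cannot proceed")
    df = cohort.df.drop(columns=to_drop)
    roles = {c: r for c, r in cohort.roles.items() if c not in to_drop}
    out = cohort.copy(df=df, roles=roles)
    out.meta["missingness_log"] = {
        "threshold": threshold,
        "dropped": to_drop,
    }
    return out


def impute(cohort: Cohort, train_index: np.ndarray | None = None) -> Cohort:
    """Fill missing cells: median for numeric columns, mode for categorical.

    Statistics are computed on ``train_index`` rows (all rows when ``None``)
    and applied everywhere.  Mode ties break toward the smallest value for
    determinism.  A feature with zero observed training values is an error.
    """
    df = cohort.df.copy()
    fit_rows = df.index if train_index is None else df.index[train_index]
    filled = {}
    for col in df.columns:
        if cohort.roles[col] == "label" or not df[col].isna().any():
            continue
        observed = df.loc[fit_rows, col].dropna()
        if observed.empty:
            raise PipelineError(
                f"feature {col!r} has no observed training values to impute from")
        if pd.api.types.is_numeric_dtype(df[col]):
            value = float(observed.median())
        else:
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            value = sorted(top)[0]
        n_missing = int(df[col].isna().sum())
        df[col] = df[col].fillna(value)
        filled[col] = {"value": value, "n_filled": n_missing}
    out = cohort.copy(df=df)
    out.meta["impute_log"] = filled
    return out


@dataclass
class NormalizationParams:
    """Per-feature min/max fitted on training rows, with target interval."""

    y_min: dict[str, float]
    y_max: dict[str, float]
    c: float = 0.0
    d: float = 1.0

    def __post_init__(self):
        if self.d <= self.c:
            raise ValueError("target interval requires d > c")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"y_min": self.y_min, "y_max": self.y_max,
             "c": self.c, "d": self.d}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def minmax_normalize(cohort: Cohort,
                     params: NormalizationParams | str = "fit",
                     train_index: np.ndarray | None = None,
                     feature_range: tuple[float, float] = (0.0, 1.0),
                     ) -> tuple[Cohort, NormalizationParams]:
    """Rescale clinical features: y' = (y - ymin)/(ymax - ymin) * (d - c) + c.

    With ``params="fit"`` the min/max are taken from training rows
    (``train_index``; all rows when ``None``) and applied everywhere;
    out-of-range values in non-training rows are clipped into [c, d] and the
    clip count logged.  A constant feature maps to ``c``.
    """
    df = cohort.df.copy()
    cols = cohort.clinical_columns
    if params == "fit":
        fit_rows = df.index if train_index is None else df.index[train_index]
        c, d = feature_range
        params = NormalizationParams(
            y_min={col: float(df.loc[fit_rows, col].min()) for col in cols},
            y_max={col: float(df.loc[fit_rows, col].max()) for col in cols},
            c=float(c), d=float(d))
    clipped = 0
    constant = []
    for col in cols:
        lo, hi = params.y_min[col], params.y_max[col]
        if hi > lo:
            scaled = (df[col] - lo) / (hi - lo) * (params.d - params.c) + params.c
        else:
            scaled = pd.Series(params.c, index=df.index)
            constant.append(col)
        out_of_range = (scaled < params.c) | (scaled > params.d)
        clipped += int(out_of_range.sum())
        df[col] = scaled.clip(params.c, params.d)
    out = cohort.copy(df=df)
    out.meta["normalize_log"] = {
        "clipped_cells": clipped, "constant_features": constant,
        "interval": [params.c, params.d]}
    return out, params


def binarize_sensitive(cohort: Cohort,
                       specs: list[SensitiveSpec] | None = None) -> Cohort:
    """Add binary privileged-group columns (1 = privileged).

    Raw sensitive columns are retained for audit and stay excluded from the
    model-facing feature view.
    """
    specs = default_sensitive_specs() if specs is None else specs
    df = cohort.df.copy()
    roles = dict(cohort.roles)
    for spec in specs:
        if spec.attribute not in df.columns:
            raise CohortError(f"sensitive column {spec.attribute!r} not present")
        df[spec.group_column] = spec.binarize(df[spec.attribute])
        roles[spec.group_column] = ROLE_GROUP
    return cohort.copy(df=df, roles=roles)


def exclude_sensitive_from_features(cohort: Cohort) -> pd.DataFrame:
    """Model-facing feature view: clinical columns plus any leak column.

    Sensitive attributes (raw and binarized) never appear here; an injected
    leak column is deliberately retained.
    """
    return cohort.df[cohort.feature_columns].copy()


# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """A stratified 80/20 holdout plus 5 stratified CV folds on the
    training portion.  Indices are positional row indices into the cohort."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_of: np.ndarray        # fold id (0..k-1) per training row, aligned
                               # with train_idx
    n_folds: int
    seed: int
    stratify_keys: tuple[str, ...] = ("label",)

    def folds(self):
        """Yield (fit_rows, val_rows) positional cohort indices per fold."""
        for f in range(self.n_folds):
            yield (self.train_idx[self.fold_of != f],
                   self.train_idx[self.fold_of == f])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "fold_of": self.fold_of.tolist(),
            "n_folds": self.n_folds,
            "seed": self.seed,
            "stratify_keys": list(self.stratify_keys)}, indent=0))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text())
        return cls(train_idx=np.array(d["train_idx"], dtype=int),
                   test_idx=np.array(d["test_idx"], dtype=int),
                   fold_of=np.array(d["fold_of"], dtype=int),
                   n_folds=d["n_folds"], seed=d["seed"],
                   stratify_keys=tuple(d["stratify_keys"]))


def split(cohort: Cohort, seed: int, test_frac: float = 0.20,
          n_folds: int = 5) -> SplitPlan:
    """Stratified-by-label 80/20 holdout with stratified CV folds inside
    the training portion; fully reproducible under ``seed``."""
    y = cohort.label
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, stratify=y, random_state=seed)
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    y_train = y[train_idx]
    counts = np.bincount(y_train, minlength=2)
    if counts.min() < n_folds:
        raise PipelineError(
            f"a class has fewer than {n_folds} training members "
            f"(counts {counts.tolist()})")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.empty(len(train_idx), dtype=int)
    for f, (_, val) in enumerate(skf.split(np.zeros(len(train_idx)), y_train)):
        fold_of[val] = f
    return SplitPlan(train_idx=train_idx, test_idx=test_idx,
                     fold_of=fold_of, n_folds=n_folds, seed=seed)


def prepare(cohort: Cohort, seed: int,
            specs: list[SensitiveSpec] | None = None,
            missing_threshold: float = 0.30,
            fit_scope: str = "train",
            ) -> tuple[Cohort, SplitPlan, NormalizationParams]:
    """Run the full fixed-order preparation and return the prepared cohort,
    the split plan, and the fitted normalization parameters.

    ``fit_scope`` selects whether imputation/normalization statistics come
    from training rows only (``"train"``, default) or all rows (``"all"``).
    """
    if fit_scope not in ("train", "all"):
        raise ValueError("fit_scope must be 'train' or 'all'")
    cohort = clean(cohort)
    cohort = drop_high_missingness(cohort, missing_threshold)
    plan = split(cohort, seed=seed)
    fit_idx = plan.train_idx if fit_scope == "train" else None
    cohort = impute(cohort, train_index=fit_idx)
    cohort, params = minmax_normalize(cohort, train_index=fit_idx)
    cohort = binarize_sensitive(cohort, specs)
    return cohort, plan, params
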