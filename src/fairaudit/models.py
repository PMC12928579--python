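"""Seeded orchestration of the three delegated learners.

Decision tree, random forest and a two-hidden-layer perceptron, configured
with the study's final hyperparameters (tree depth 10, forest of 200 trees
at depth 12 with sqrt features, MLP d->256->128->1 trained with Adam at
lr 1e-3, batch 16).  A small grid bracketing each final value is searched
over the split plan's 5 stratified CV folds; the model is then refitted on
the full training portion.  The perceptron's decision threshold is chosen
on a validation fold to maximize F1.

Learner internals are delegated to scikit-learn.  The perceptron is
sklearn's ``MLPClassifier``; batch normalization, dropout and plateau
learning-rate scheduling have no sklearn equivalent and are documented as
approximation gaps in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, log_loss
from sklearn.model_selection import ParameterGrid
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .preprocess import SplitPlan

__all__ = ["ModelConfig", "TrainedModel", "SchemaError", "train", "predict",
           "DEFAULT_PARAMS", "DEFAULT_GRIDS"]


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the training schema."""


# Final hyperparameters; grids bracket them so the final configuration is
# always reachable by the search.
DEFAULT_PARAMS = {
    "dt": {"max_depth": 10, "min_samples_leaf": 2, "criterion": "gini",
           "class_weight": None},
    "rf": {"n_estimators": 200, "max_depth": 12, "min_samples_split": 4,
           "max_features": "sqrt", "bootstrap": True, "class_weight": None},
    "mlp": {"hidden_layer_sizes": (256, 128), "activation": "relu",
            "solver": "adam", "learning_rate_init": 1e-3, "alpha": 1e-5,
            "batch_size": 16, "max_iter": 100, "early_stopping": True,
            "n_iter_no_change": 10},
}

DEFAULT_GRIDS = {
    "dt": {"max_depth": [5, 10, 15]},
    "rf": {"max_depth": [8, 12, 16]},
    "mlp": {"learning_rate_init": [1e-3]},
}


@dataclass
class ModelConfig:
    """Which learner to train and how to select its hyperparameters.

    ``grid`` maps parameter name to candidate values; ``{}`` disables the
    search and trains the final configuration directly.  ``selection``
    chooses the criterion: mean CV validation log-loss (default) or mean
    training log-loss (the literal lowest-training-loss reading).
    """

    kind: str
    seed: int = 4765416
    selection: str = "cv_loss"
    grid: dict | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in DEFAULT_PARAMS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.selection not in ("cv_loss", "train_loss"):
            raise ValueError("selection must be 'cv_loss' or 'train_loss'")
        unknown = set(self.params) - set(DEFAULT_PARAMS[self.kind])
        if unknown:
            raise ValueError(f"unknown fields for {self.kind}: {sorted(unknown)}")

    def resolved_params(self, overrides: dict | None = None) -> dict:
        p = dict(DEFAULT_PARAMS[self.kind])
        p.update(self.params)
        if overrides:
            p.update(overrides)
        return p

    def to_dict(self) -> dict:
        return {"kind": self.kind, "seed": self.seed,
                "selection": self.selection, "grid": self.grid,
                "params": dict(self.params)}


@dataclass
class TrainedModel:
    """A fitted learner with its configuration echo and training log."""

    estimator: object
    config: ModelConfig
    feature_names: list[str]
    threshold: float | None = None       # mlp only
    training_log: dict = field(default_factory=dict)

    def save_log(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config.to_dict(), "threshold": self.threshold,
             "training_log": self.training_log}, indent=1))


def _build(kind: str, params: dict, seed: int):
    if kind == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    return MLPClassifier(random_state=seed, **params)


def train(features: pd.DataFrame, labels, plan: SplitPlan,
          cfg: ModelConfig) -> TrainedModel:
    """Grid search over the plan's CV folds, then refit on all training rows.

    ``features``/``labels`` cover the whole cohort; only rows in
    ``plan.train_idx`` are ever touched.  The perceptron's decision
    threshold is selected on the first CV fold's validation part to
    maximize F1.
    """
    y = np.asarray(labels).astype(int)
    X = features
    y_train = y[plan.train_idx]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training portion contains a single class")

    grid = DEFAULT_GRIDS[cfg.kind] if cfg.grid is None else cfg.grid
    candidates = list(ParameterGrid(grid)) if grid else [{}]

    log: dict = {"folds": plan.n_folds, "grid_points": []}
    best = None
    if len(candidates) == 1:
        # no competition: skip the CV loop and fit once on the full
        # training portion below
        best = (float("nan"), candidates[0])
        log["grid_points"].append({"params": candidates[0],
                                   "mean_loss": None})
        candidates = []
    for point in candidates:
        params = cfg.resolved_params(point)
        losses = []
        for fit_rows, val_rows in plan.folds():
            if len(np.unique(y[fit_rows])) < 2:
                raise ValueError("degenerate single-class training fold")
            est = _build(cfg.kind, params, cfg.seed)
            est.fit(X.iloc[fit_rows].to_numpy(), y[fit_rows])
            rows = fit_rows if cfg.selection == "train_loss" else val_rows
            proba = est.predict_proba(X.iloc[rows].to_numpy())[:, 1]
            losses.append(log_loss(y[rows], proba, labels=[0, 1]))
        mean_loss = float(np.mean(losses))
        log["grid_points"].append({"params": point, "mean_loss": mean_loss})
        if best is None or mean_loss < best[0]:
            best = (mean_loss, point)
    chosen = best[1]
    log["chosen"] = chosen

    final_params = cfg.resolved_params(chosen)
    estimator = _build(cfg.kind, final_params, cfg.seed)
    estimator.fit(X.iloc[plan.train_idx].to_numpy(), y_train)
    if hasattr(estimator, "n_iter_"):
        log["epochs_run"] = int(np.asarray(estimator.n_iter_).max())

    threshold = None
    if cfg.kind == "mlp":
        fit_rows, val_rows = next(iter(plan.folds()))
        val_est = _build(cfg.kind, final_params, cfg.seed)
        val_est.fit(X.iloc[fit_rows].to_numpy(), y[fit_rows])
        proba = val_est.predict_proba(X.iloc[val_rows].to_numpy())[:, 1]
        threshold = _best_f1_threshold(y[val_rows], proba)
        log["threshold"] = threshold

    return TrainedModel(estimator=estimator, config=cfg,
                        feature_names=list(X.columns),
                        threshold=threshold, training_log=log)


def _best_f1_threshold(y_true, proba) -> float:
    candidates = np.unique(np.concatenate([proba, [0.5]]))
    best_t, best_f1 = 0.5, -1.0
    for t in candidates:
        f1 = f1_score(y_true, (proba >= t).astype(int), zero_division=0)
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t


def predict(model: TrainedModel, features: pd.DataFrame,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Binary predictions and positive-class scores.

    The feature columns must match the training schema exactly, names and
    order; any mismatch raises :class:`SchemaError` listing the missing and
    extra columns.
    """
    got = list(features.columns)
    want = model.feature_names
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise SchemaError(
            f"feature schema mismatch: missing={missing}, extra={extra}, "
            f"order_expected={want}")
    scores = model.estimator.predict_proba(features.to_numpy())[:, 1]
    if model.threshold is not None:
        pred = (scores >= model.threshold).astype(int)
    else:
        pred = model.estimator.predict(features.to_numpy()).astype(int)
    return pred, scores
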