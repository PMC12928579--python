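"""Feature selection: correlation pruning (SULOV-style) followed by
recursive importance ranking from a gradient-boosted tree ensemble.

SULOV ("searching for uncorrelated list of variables") removes, from every
highly correlated pair, the member with lower single-feature relevance
(mutual information with the label).  The survivors are then ranked by a
boosted ensemble's gain importance over several rounds, keeping the top
fraction each round; the final set is the features retained in every round.
Boosting internals are delegated to scikit-learn's gradient boosting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.feature_selection import mutual_info_classif

__all__ = ["SelectionResult", "sulov_filter", "recursive_importance_select",
           "select_features"]


@dataclass
class SelectionResult:
    """Outcome of a selection stage."""

    importances: dict[str, float]                  # relevance/importance scores
    removed_correlated: list[tuple[str, str, float]]  # (removed, kept, |corr|)
    retained: list[str]
    rounds: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "importances": self.importances,
            "removed_correlated": [list(t) for t in self.removed_correlated],
            "retained": self.retained,
            "rounds": self.rounds}, indent=1))


def _mutual_information(X: pd.DataFrame, y, seed: int) -> dict[str, float]:
    mi = mutual_info_classif(X.to_numpy(), np.asarray(y), random_state=seed)
    return dict(zip(X.columns, (float(v) for v in mi)))


def sulov_filter(features: pd.DataFrame, labels, corr_threshold: float = 0.70,
                 seed: int = 0) -> SelectionResult:
    """Greedy removal of correlated, lower-relevance features.

    Among every pair with |Pearson correlation| above ``corr_threshold``,
    the member with lower mutual information with the label is removed,
    highest-correlation pair first.  Relevance ties break toward keeping
    the earlier column; deterministic under a fixed seed.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least two features")
    if features.isna().any().any():
        raise ValueError("features must be fully observed (impute first)")
    cols = list(features.columns)
    relevance = _mutual_information(features, labels, seed)
    corr = features.corr().abs()

    alive = set(cols)
    removed: list[tuple[str, str, float]] = []
    while True:
        best = None
        for i, a in enumerate(cols):
            if a not in alive:
                continue
            for b in cols[i + 1:]:
                if b not in alive:
                    continue
                c = corr.loc[a, b]
                if np.isnan(c) or c <= corr_threshold:
                    continue
                if best is None or c > best[2]:
                    best = (a, b, float(c))
        if best is None:
            break
        a, b, c = best
        # drop the lower-relevance member; tie -> keep the earlier column
        if relevance[a] < relevance[b]:
            drop, keep = a, b
        elif relevance[b] < relevance[a]:
            drop, keep = b, a
        else:
            drop, keep = b, a
        alive.discard(drop)
        removed.append((drop, keep, c))

    retained = [c for c in cols if c in alive]
    return SelectionResult(importances=relevance, removed_correlated=removed,
                           retained=retained, rounds=0)


def _boosted_importances(X: pd.DataFrame, y, seed: int) -> dict[str, float]:
    model = GradientBoostingClassifier(n_estimators=100, max_depth=3,
                                       random_state=seed)
    model.fit(X.to_numpy(), np.asarray(y))
    return dict(zip(X.columns, (float(v) for v in model.feature_importances_)))


def recursive_importance_select(features: pd.DataFrame, labels,
                                rounds: int = 3, keep_frac: float = 0.75,
                                seed: int = 0) -> SelectionResult:
    """Iterative boosted-importance ranking.

    Each round fits the delegated boosted ensemble on the surviving
    features, ranks them by importance, and keeps the top ``keep_frac``
    (importance ties break toward earlier columns).  Iteration stops after
    ``rounds`` or when the set stabilizes; the final set is the features
    retained in every round (with nested keeps this is the last round's
    set).
    """
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError("keep_frac must lie in (0, 1]")
    current = list(features.columns)
    importances: dict[str, float] = {}
    executed = 0
    for _ in range(rounds):
        scores = _boosted_importances(features[current], labels, seed)
        importances = scores
        executed += 1
        k = math.ceil(keep_frac * len(current))
        order = sorted(range(len(current)),
                       key=lambda i: (-scores[current[i]], i))
        kept = sorted(order[:k])
        new = [current[i] for i in kept]
        if new == current:
            break
        current = new
    return SelectionResult(importances=importances, removed_correlated=[],
                           retained=current, rounds=executed)


def select_features(features: pd.DataFrame, labels,
                    corr_threshold: float = 0.70, rounds: int = 3,
                    keep_frac: float = 0.75, seed: int = 0) -> SelectionResult:
    """SULOV correlation pruning followed by recursive importance ranking."""
    stage1 = sulov_filter(features, labels, corr_threshold, seed)
    stage2 = recursive_importance_select(features[stage1.retained], labels,
                                         rounds, keep_frac, seed)
    return SelectionResult(importances=stage2.importances,
                           removed_correlated=stage1.removed_correlated,
                           retained=stage2.retained, rounds=stage2.rounds)
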