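"""Optimized pre-processing fairness mitigation.

Learns a randomized transformation of (features, label) conditioned on the
sensitive group that (i) bounds the group gap in the transformed positive-
label rate, (ii) bounds the expected per-sample distortion, and (iii) keeps
the transformed (features, label) distribution close to the original in
total variation — while minimizing the overall expected distortion.  The
transformation lives on a finite outcome space obtained by quantile-binning
a small number of features, which makes the optimization a linear program
(solved with scipy's HiGHS backend).

The learned map is fitted on training rows only and applied to training
rows only: test data always passes through untransformed, preserving the
pre-processing contract.

Distortion between two outcomes is the Hamming distance over binned
feature coordinates plus a weight (default 2) on label flips, so a label
change costs twice a one-bin feature move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .cohort import Cohort, SensitiveSpec

__all__ = ["DiscretizationScheme", "MitigationMap", "TransformLog",
           "MitigationInfeasibleError", "fit_mitigation", "apply_mitigation"]

SOLVER_TOL = 1e-6


class MitigationInfeasibleError(RuntimeError):
    """The constraint set admits no transformation.

    ``min_feasible_eps`` is the smallest fairness bound (found by bisection,
    resolution 1e-3) at which the program becomes feasible under the same
    distortion and fidelity budgets, or ``None`` if none exists below 1.
    """

    def __init__(self, message: str, min_feasible_eps: float | None):
        super().__init__(message)
        self.min_feasible_eps = min_feasible_eps


@dataclass
class DiscretizationScheme:
    """Quantile binning of the features entering the map.

    ``edges[f]`` holds the interior cut points of feature ``f`` (so
    ``len(edges[f]) + 1`` effective bins after deduplication) and
    ``representatives[f][b]`` the median training value in bin ``b``, used
    to realize a transformed row.
    """

    features: list[str]
    edges: dict[str, np.ndarray]
    representatives: dict[str, np.ndarray]
    n_bins: int

    @classmethod
    def fit(cls, df: pd.DataFrame, features: list[str], n_bins: int = 4,
            ) -> "DiscretizationScheme":
        edges: dict[str, np.ndarray] = {}
        reps: dict[str, np.ndarray] = {}
        for f in features:
            x = df[f].to_numpy(dtype=float)
            qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
            e = np.unique(qs)
            codes = np.searchsorted(e, x, side="right")
            k = len(e) + 1
            rep = np.empty(k)
            overall = float(np.median(x))
            for b in range(k):
                vals = x[codes == b]
                rep[b] = float(np.median(vals)) if vals.size else overall
            edges[f] = e
            reps[f] = rep
        return cls(features=list(features), edges=edges,
                   representatives=reps, n_bins=n_bins)

    def cell_codes(self, df: pd.DataFrame) -> np.ndarray:
        """(n, k) integer bin codes; values outside the fitted range fall
        into the end bins."""
        cols = [np.searchsorted(self.edges[f], df[f].to_numpy(dtype=float),
                                side="right")
                for f in self.features]
        return np.stack(cols, axis=1)

    def n_cells(self) -> int:
        out = 1
        for f in self.features:
            out *= len(self.edges[f]) + 1
        return out


@dataclass
class TransformLog:
    label_flips: dict = field(default_factory=dict)     # per group
    feature_moves: dict = field(default_factory=dict)   # per group
    out_of_support: int = 0
    n_transformed: int = 0


@dataclass
class MitigationMap:
    """The fitted conditional transformation p(x_hat, y_hat | x, y, s)."""

    scheme: DiscretizationScheme
    group_column: str
    outcomes: list[tuple[tuple[int, ...], int]]     # (cell, label)
    sources: dict[int, list[tuple[tuple[int, ...], int]]]  # per group s
    transitions: dict[int, np.ndarray]              # per group, |S_s| x |O|
    source_probs: dict[int, np.ndarray]             # empirical p(x, y | s)
    objective: float
    implied_positive_rate: dict[int, float]         # P(y_hat = 1 | s)
    slacks: dict
    config: dict

    @property
    def implied_label_gap(self) -> float:
        """Transformed-distribution positive-rate gap, |P(1|s=1)-P(1|s=0)|."""
        return abs(self.implied_positive_rate[1] - self.implied_positive_rate[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_column": self.group_column,
            "features": self.scheme.features,
            "edges": {f: e.tolist() for f, e in self.scheme.edges.items()},
            "representatives": {f: r.tolist()
                                for f, r in self.scheme.representatives.items()},
            "outcomes": [[list(c), y] for c, y in self.outcomes],
            "sources": {str(s): [[list(c), y] for c, y in src]
                        for s, src in self.sources.items()},
            "transitions": {str(s): t.tolist()
                            for s, t in self.transitions.items()},
            "objective": self.objective,
            "implied_positive_rate": {str(k): v for k, v in
                                      self.implied_positive_rate.items()},
            "slacks": self.slacks,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload))


def _distortion_matrix(sources, outcomes, label_flip_weight):
    d = np.empty((len(sources), len(outcomes)))
    for i, (ci, yi) in enumerate(sources):
        for j, (cj, yj) in enumerate(outcomes):
            ham = sum(a != b for a, b in zip(ci, cj))
            d[i, j] = ham + label_flip_weight * (yi != yj)
    return d


def _solve_lp(pi, phat, dist, y_is_one, p0, eps, distortion_budget,
              fidelity_budget):
    """Assemble and solve the transformation LP.

    Variables: transitions x[s][i, j] for s in {0, 1}, then |O| auxiliary
    total-variation variables.  Returns (status, transitions, objective).
    """
    n_out = len(y_is_one)
    sizes = {s: phat[s].shape[0] for s in (0, 1)}
    offset = {0: 0, 1: sizes[0] * n_out}
    n_x = (sizes[0] + sizes[1]) * n_out
    n_var = n_x + n_out

    def xcol(s, i, j):
        return offset[s] + i * n_out + j

    c = np.zeros(n_var)
    for s in (0, 1):
        w = pi[s] * phat[s][:, None] * dist[s]
        c[offset[s]:offset[s] + sizes[s] * n_out] = w.ravel()

    rows_eq, cols_eq, vals_eq, b_eq = [], [], [], []
    r = 0
    for s in (0, 1):
        for i in range(sizes[s]):
            for j in range(n_out):
                rows_eq.append(r); cols_eq.append(xcol(s, i, j)); vals_eq.append(1.0)
            b_eq.append(1.0)
            r += 1
    A_eq = sparse.csr_matrix((vals_eq, (rows_eq, cols_eq)), shape=(r, n_var))

    rows, cols, vals, b_ub = [], [], [], []
    r = 0
    # fairness: +/- (R1 - R0) <= eps, R_s = sum_i phat[s][i] * x[s,i,j] * [y_j = 1]
    for sign in (1.0, -1.0):
        for s in (0, 1):
            coef = sign * (1.0 if s == 1 else -1.0)
            for i in range(sizes[s]):
                for j in range(n_out):
                    if y_is_one[j]:
                        rows.append(r); cols.append(xcol(s, i, j))
                        vals.append(coef * phat[s][i])
        b_ub.append(eps)
        r += 1
    # per-source expected distortion
    for s in (0, 1):
        for i in range(sizes[s]):
            for j in range(n_out):
                if dist[s][i, j] != 0.0:
                    rows.append(r); cols.append(xcol(s, i, j))
                    vals.append(dist[s][i, j])
            b_ub.append(distortion_budget)
            r += 1
    # fidelity: |q_j - p0_j| <= t_j, sum t_j <= 2 * fidelity_budget
    for j in range(n_out):
        for sign in (1.0, -1.0):
            for s in (0, 1):
                for i in range(sizes[s]):
                    rows.append(r); cols.append(xcol(s, i, j))
                    vals.append(sign * pi[s] * phat[s][i])
            rows.append(r); cols.append(n_x + j); vals.append(-1.0)
            b_ub.append(sign * p0[j])
            r += 1
    for j in range(n_out):
        rows.append(r); cols.append(n_x + j); vals.append(1.0)
    b_ub.append(2.0 * fidelity_budget)
    r += 1
    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(r, n_var))

    res = linprog(c, A_ub=A_ub, b_ub=np.array(b_ub), A_eq=A_eq,
                  b_eq=np.array(b_eq),
                  bounds=[(0, 1)] * n_x + [(0, None)] * n_out,
                  method="highs")
    if not res.success:
        return res.status, None, None
    transitions = {}
    for s in (0, 1):
        t = res.x[offset[s]:offset[s] + sizes[s] * n_out].reshape(sizes[s], n_out)
        t = np.clip(t, 0.0, None)
        t /= t.sum(axis=1, keepdims=True)
        transitions[s] = t
    return res.status, transitions, float(res.fun)


def fit_mitigation(cohort: Cohort, spec: SensitiveSpec,
                   eps_fairness: float = 0.05,
                   distortion_budget: float = 0.5,
                   fidelity_budget: float = 0.1,
                   scheme: DiscretizationScheme | None = None,
                   features: list[str] | None = None,
                   n_bins: int = 4,
                   n_map_features: int = 3,
                   label_flip_weight: float = 2.0,
                   train_index: np.ndarray | None = None,
                   seed: int = 0) -> MitigationMap:
    """Fit the randomized pre-processing transformation on training rows.

    ``features`` (or the first ``n_map_features`` feature columns) enter
    the discretized map; all other features pass through untouched.  Raises
    :class:`MitigationInfeasibleError` with the bisected minimal feasible
    fairness bound when the constraints cannot be met.
    """
    group_col = spec.group_column
    if group_col not in cohort.df.columns:
        raise ValueError(
            f"group column {group_col!r} missing; run binarize_sensitive first")
    rows = np.arange(cohort.n) if train_index is None else np.asarray(train_index)
    df = cohort.df.iloc[rows]
    if features is None:
        features = cohort.feature_columns[:n_map_features]
    if scheme is None:
        scheme = DiscretizationScheme.fit(df, features, n_bins)

    codes = scheme.cell_codes(df)
    y = cohort.label[rows]
    g = df[group_col].to_numpy(dtype=int)
    if not np.any(g == 0) or not np.any(g == 1):
        raise ValueError("both sensitive groups must be nonempty on train rows")

    cells = [tuple(c) for c in codes]
    observed_cells = sorted(set(cells))
    outcomes = [(c, yy) for c in observed_cells for yy in (0, 1)]
    out_index = {o: j for j, o in enumerate(outcomes)}
    y_is_one = np.array([yy == 1 for _, yy in outcomes])

    sources: dict[int, list] = {}
    phat: dict[int, np.ndarray] = {}
    pi: dict[int, float] = {}
    dist: dict[int, np.ndarray] = {}
    n = len(rows)
    for s in (0, 1):
        mask = g == s
        combos: dict[tuple, int] = {}
        for c, yy in zip(np.array(cells, dtype=object)[mask], y[mask]):
            key = (tuple(c), int(yy))
            combos[key] = combos.get(key, 0) + 1
        src = sorted(combos)
        sources[s] = src
        phat[s] = np.array([combos[k] for k in src], dtype=float)
        pi[s] = phat[s].sum() / n
        phat[s] /= phat[s].sum()
        dist[s] = _distortion_matrix(src, outcomes, label_flip_weight)

    # pooled original (x, y) marginal over the outcome space
    p0 = np.zeros(len(outcomes))
    for s in (0, 1):
        for i, src in enumerate(sources[s]):
            p0[out_index[src]] += pi[s] * phat[s][i]

    status, transitions, objective = _solve_lp(
        pi, phat, dist, y_is_one, p0, eps_fairness,
        distortion_budget, fidelity_budget)
    if transitions is None:
        min_eps = _bisect_min_eps(pi, phat, dist, y_is_one, p0,
                                  eps_fairness, distortion_budget,
                                  fidelity_budget)
        raise MitigationInfeasibleError(
            f"mitigation LP infeasible at eps_fairness={eps_fairness}; "
            f"minimal feasible eps ~ {min_eps}", min_eps)

    implied = {}
    for s in (0, 1):
        implied[s] = float(phat[s] @ transitions[s] @ y_is_one.astype(float))
    gap = abs(implied[1] - implied[0])
    return MitigationMap(
        scheme=scheme, group_column=group_col, outcomes=outcomes,
        sources=sources, transitions=transitions, source_probs=phat,
        objective=objective,
        implied_positive_rate=implied,
        slacks={"fairness": eps_fairness - gap,
                "eps_fairness": eps_fairness,
                "distortion_budget": distortion_budget,
                "fidelity_budget": fidelity_budget},
        config={"eps_fairness": eps_fairness,
                "distortion_budget": distortion_budget,
                "fidelity_budget": fidelity_budget,
                "n_bins": n_bins, "features": list(features),
                "label_flip_weight": label_flip_weight, "seed": seed})


def _bisect_min_eps(pi, phat, dist, y_is_one, p0, eps_lo, distortion_budget,
                    fidelity_budget, tol=1e-3):
    hi = 1.0
    status, t, _ = _solve_lp(pi, phat, dist, y_is_one, p0, hi,
                             distortion_budget, fidelity_budget)
    if t is None:
        return None  # infeasible regardless of the fairness bound
    lo = eps_lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        _, t, _ = _solve_lp(pi, phat, dist, y_is_one, p0, mid,
                            distortion_budget, fidelity_budget)
        if t is None:
            lo = mid
        else:
            hi = mid
    return hi


def apply_mitigation(mmap: MitigationMap, cohort: Cohort, seed: int,
                     rows: np.ndarray | None = None,
                     ) -> tuple[Cohort, TransformLog]:
    """Sample transformed (features, label) for the given rows.

    Only the rows passed (default: all rows of the cohort — the caller is
    responsible for restricting to training rows) are transformed.  A row
    whose (cell, label) combination was unseen for its group during fitting
    is mapped through its nearest observed source (logged); mapped features
    are realized as the target bin's median only when the bin changes, so
    the identity map leaves rows untouched.
    """
    rows = np.arange(cohort.n) if rows is None else np.asarray(rows)
    df = cohort.df.copy()
    scheme = mmap.scheme
    codes = scheme.cell_codes(df.iloc[rows])
    y = cohort.label[rows]
    g = df.iloc[rows][mmap.group_column].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)

    src_index = {s: {src: i for i, src in enumerate(mmap.sources[s])}
                 for s in (0, 1)}
    log = TransformLog(label_flips={0: 0, 1: 0}, feature_moves={0: 0, 1: 0},
                       n_transformed=len(rows))
    label_col = cohort.label_column
    new_labels = df[label_col].to_numpy().copy()

    feat_cols = {f: df.columns.get_loc(f) for f in scheme.features}
    values = {f: df[f].to_numpy(dtype=float).copy() for f in scheme.features}

    for k, row_pos in enumerate(rows):
        s = int(g[k])
        key = (tuple(codes[k]), int(y[k]))
        i = src_index[s].get(key)
        if i is None:
            log.out_of_support += 1
            i = _nearest_source(key, mmap.sources[s])
        probs = mmap.transitions[s][i]
        j = rng.choice(len(mmap.outcomes), p=probs)
        cell_t, y_t = mmap.outcomes[j]
        if y_t != y[k]:
            new_labels[row_pos] = y_t
            log.label_flips[s] += 1
        for fi, f in enumerate(scheme.features):
            if cell_t[fi] != codes[k][fi]:
                values[f][row_pos] = scheme.representatives[f][cell_t[fi]]
                log.feature_moves[s] += 1

    for f in scheme.features:
        df[f] = values[f]
    df[label_col] = new_labels
    out = cohort.copy(df=df)
    out.meta["mitigation_log"] = asdict(log)
    return out, log


def _nearest_source(key, sources):
    cell, y = key
    best, best_d = 0, None
    for i, (c, yy) in enumerate(sources):
        d = sum(a != b for a, b in zip(cell, c)) + 2 * (y != yy)
        if best_d is None or d < best_d:
            best, best_d = i, d
    return best
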