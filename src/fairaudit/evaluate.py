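"""Experiment harness: the full audit grid with repeated seeded runs.

Runs {decision tree, random forest, perceptron} x {race, age, gender} x
{without, with mitigation} x {clean, poisoned, leaked} on synthetic
cohorts, repeating each cell (default 5 times) with fresh seeds and fresh
splits, and aggregates mean +/- SD.  Paired t-tests compare conditions
cell-by-cell, pairing per-repeat values by seed.  Reports render as CSV
tables (rows = metrics, columns = attribute x condition), a JSON summary,
and a short plain-text narrative of the deltas.

Per repeat the pipeline is: generate cohort -> clean -> missingness filter
-> split -> impute (train-fitted) -> normalize (train-fitted) -> binarize
sensitive attributes -> optional leak injection (all partitions, before
feature dropping) -> feature view -> optional selection -> optional label
poisoning (training rows only) -> optional mitigation (fitted and applied
on training rows only) -> train -> evaluate on the untouched test rows.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from . import attack as atk
from . import metrics as fm
from . import mitigate as mit
from . import preprocess as prep
from . import models as mdl
from .cohort import Cohort, SensitiveSpec, default_sensitive_specs
from .synth import CohortConfig, generate_cohort

__all__ = ["ExperimentSpec", "CellResult", "ExperimentResult", "run_grid",
           "run_cell", "paired_tests", "render_report"]

PERFORMANCE_METRICS = ("accuracy", "precision", "recall", "f1", "auroc")
BIAS_METRICS = ("spd", "di", "eod", "aaod")


@dataclass
class ExperimentSpec:
    """Fully determines one audit run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    model_kinds: tuple[str, ...] = ("dt", "rf")
    attributes: tuple[str, ...] = ("race", "age", "gender")
    mitigation: tuple[bool, ...] = (False, True)
    attack_kind: str | None = None          # None | "poison" | "leak"
    poison_rates: tuple[float, ...] = (atk.AttackConfig("poison").poison_rate,)
    leak_alpha: float = 0.90
    repeats: int = 5
    base_seed: int = atk.BASE_SEED
    eps_fairness: float = 0.05
    distortion_budget: float = 0.5
    fidelity_budget: float = 0.1
    feature_selection: bool = False
    grid_search: bool = False
    fit_scope: str = "train"
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        for key in ("model_kinds", "attributes", "mitigation", "poison_rates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)


@dataclass
class CellResult:
    """Per-repeat records and aggregates for one grid cell."""

    key: dict
    repeats: list[dict] = field(default_factory=list)
    error: str | None = None

    def values(self, metric: str) -> list[float]:
        return [r[metric] for r in self.repeats]

    def mean_sd(self, metric: str) -> tuple[float, float, int]:
        return fm.aggregate_defined(self.values(metric))


@dataclass
class ExperimentResult:
    spec_echo: dict
    cells: dict[tuple, CellResult] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def cell(self, model: str, attribute: str, mitigated: bool,
             rate: float | None = None) -> CellResult:
        return self.cells[(model, attribute, mitigated, rate)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": self.spec_echo,
            "failures": self.failures,
            "cells": [{"key": c.key, "repeats": c.repeats, "error": c.error}
                      for c in self.cells.values()],
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def _spec_for(attribute: str) -> SensitiveSpec:
    for s in default_sensitive_specs():
        if s.attribute == attribute:
            return s
    raise ValueError(f"no sensitive spec for attribute {attribute!r}")


def run_cell(spec: ExperimentSpec, model_kind: str, attribute: str,
             mitigated: bool, poison_rate: float | None,
             repeat: int) -> dict:
    """One repeat of one grid cell; returns the metric record."""
    seed = atk.derive_seed(spec.base_seed, 0, repeat)
    t0 = time.perf_counter()

    cfg = CohortConfig(**{**spec.cohort.to_dict(), "seed": seed})
    cfg.feature_specs = spec.cohort.feature_specs
    cohort = generate_cohort(cfg)
    sens = _spec_for(attribute)

    cohort, plan, _ = prep.prepare(
        cohort, seed=seed, fit_scope=spec.fit_scope)
    group_all = cohort.group(sens.group_column)
    y_all = cohort.label.copy()

    test_labels_before = y_all[plan.test_idx].copy()
    attack_log = None

    if spec.attack_kind == "leak":
        leak_cfg = atk.AttackConfig("leak", leak_alpha=spec.leak_alpha,
                                    seed=seed)
        cohort, attack_log = atk.inject_leak_feature(
            cohort, group_all, leak_cfg)

    X = prep.exclude_sensitive_from_features(cohort)
    if spec.feature_selection:
        from .select import select_features

        sel = select_features(X.iloc[plan.train_idx],
                              y_all[plan.train_idx], seed=seed)
        keep = sel.retained + [c for c in X.columns
                               if cohort.roles.get(c) == "leak"]
        X = X[[c for c in X.columns if c in keep]]

    y_model = y_all.copy()
    if spec.attack_kind == "poison" and poison_rate:
        strata = np.char.add(
            y_all[plan.train_idx].astype(str),
            np.char.add("|", group_all[plan.train_idx].astype(str)))
        p_cfg = atk.AttackConfig("poison", poison_rate=poison_rate, seed=seed)
        poisoned, attack_log = atk.poison_labels(
            y_all[plan.train_idx], strata, p_cfg)
        y_model[plan.train_idx] = poisoned

    if mitigated:
        work = cohort.copy()
        work.df[cohort.label_column] = y_model
        mmap = mit.fit_mitigation(
            work, sens, eps_fairness=spec.eps_fairness,
            distortion_budget=spec.distortion_budget,
            fidelity_budget=spec.fidelity_budget,
            train_index=plan.train_idx, seed=seed)
        work, _ = mit.apply_mitigation(mmap, work, seed=seed,
                                       rows=plan.train_idx)
        y_model = work.label.copy()
        for f in mmap.scheme.features:
            if f in X.columns:
                X = X.copy()
                X[f] = work.df[f]

    model_cfg = mdl.ModelConfig(
        kind=model_kind, seed=seed,
        grid=None if spec.grid_search else {})
    model = mdl.train(X, y_model, plan, model_cfg)
    pred, scores = mdl.predict(model, X.iloc[plan.test_idx])

    y_test = y_all[plan.test_idx]
    assert np.array_equal(y_test, test_labels_before), \
        "test labels were tampered with"
    g_test = group_all[plan.test_idx]

    report = fm.bias_report(pred, y_test, g_test)
    rates = fm.group_rates(fm.group_confusion(pred, y_test, g_test))
    try:
        auroc = roc_auc_score(y_test, scores)
    except ValueError:
        auroc = fm.UNDEFINED
    record = {
        "repeat": repeat, "seed": seed,
        "accuracy": accuracy_score(y_test, pred),
        "precision": precision_score(y_test, pred, zero_division=0),
        "recall": recall_score(y_test, pred, zero_division=0),
        "f1": f1_score(y_test, pred, zero_division=0),
        "auroc": auroc,
        "spd": report.spd, "di": report.di, "eod": report.eod,
        "aaod": report.aaod, "aaod_magnitude": report.aaod_magnitude,
        "delta_error": fm.group_loss_disparity(scores, y_test, g_test),
        "rates_privileged": rates.privileged,
        "rates_unprivileged": rates.unprivileged,
        "attack_log": (asdict(attack_log) if attack_log else None),
        "runtime_s": time.perf_counter() - t0,
    }
    if record["attack_log"] and "flipped_rows" in record["attack_log"].get(
            "extra", {}):
        record["attack_log"]["extra"].pop("flipped_rows")
    return record


def run_grid(spec: ExperimentSpec) -> ExperimentResult:
    """Run every cell of the grid; stage errors are recorded per cell and
    the harness continues with the remaining cells."""
    result = ExperimentResult(spec_echo=_spec_echo(spec))
    rates = (spec.poison_rates if spec.attack_kind == "poison" else (None,))
    for model_kind in spec.model_kinds:
        for attribute in spec.attributes:
            for mitigated in spec.mitigation:
                for rate in rates:
                    key = (model_kind, attribute, mitigated, rate)
                    cell = CellResult(key={
                        "model": model_kind, "attribute": attribute,
                        "mitigated": mitigated, "poison_rate": rate})
                    for r in range(spec.repeats):
                        try:
                            cell.repeats.append(run_cell(
                                spec, model_kind, attribute, mitigated,
                                rate, r))
                        except Exception as exc:  # noqa: BLE001
                            cell.error = f"repeat {r}: {exc}"
                            result.failures.append(
                                {"cell": cell.key, "repeat": r,
                                 "error": str(exc)})
                            break
                    result.cells[key] = cell
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_json(out / "experiment_result.json")
    return result


def _spec_echo(spec: ExperimentSpec) -> dict:
    d = asdict(spec)
    d["cohort"] = spec.cohort.to_dict()
    return d


# -- statistics --------------------------------------------------------------

def paired_tests(result: ExperimentResult,
                 pairing: tuple[tuple, tuple],
                 metrics: tuple[str, ...] = PERFORMANCE_METRICS,
                 bh_adjust: bool = False) -> list[dict]:
    """Paired t-tests between two grid cells, pairing repeats by seed.

    All differences equal (zero variance) is reported as a degenerate case
    with p = 1 rather than infinite t, avoiding spurious significance on
    deterministic models.  ``bh_adjust`` adds Benjamini-Hochberg adjusted
    p-values across the requested metrics (off by default).
    """
    cell_a, cell_b = result.cells[pairing[0]], result.cells[pairing[1]]
    if len(cell_a.repeats) != len(cell_b.repeats):
        raise ValueError("paired cells must have equal repeat counts")
    if len(cell_a.repeats) < 2:
        raise ValueError("need at least two paired repeats")
    seeds_a = [r["seed"] for r in cell_a.repeats]
    seeds_b = [r["seed"] for r in cell_b.repeats]
    if seeds_a != seeds_b:
        raise ValueError("pairing requires identical seeds across the pair")

    records = []
    for metric in metrics:
        a = np.asarray(cell_a.values(metric), dtype=float)
        b = np.asarray(cell_b.values(metric), dtype=float)
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            records.append({
                "metric": metric, "t": float("nan"), "p": 1.0,
                "mean_diff": float(diffs.mean()), "degenerate": True,
                "significant": False,
                "pairing": [list(pairing[0]), list(pairing[1])]})
            continue
        t, p = sps.ttest_rel(a, b)
        records.append({
            "metric": metric, "t": float(t), "p": float(p),
            "mean_diff": float(diffs.mean()), "degenerate": False,
            "significant": bool(p < 0.05),
            "pairing": [list(pairing[0]), list(pairing[1])]})
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        ps = [r["p"] for r in records]
        _, adj, _, _ = multipletests(ps, method="fdr_bh")
        for r, q in zip(records, adj):
            r["p_bh"] = float(q)
    return records


# -- reporting ---------------------------------------------------------------

_TABLE_METRICS = ["accuracy", "precision", "recall", "f1", "auroc",
                  "spd", "di", "eod", "aaod"]
_RATE_METRICS = list(fm.RATE_NAMES)


def render_report(result: ExperimentResult, out_dir: str | Path,
                  poison_rate: float | None = None) -> dict[str, Path]:
    """Write CSV tables (metrics x attribute x condition), a JSON summary,
    and a plain-text narrative of the mitigation deltas."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    models = sorted({k[0] for k in result.cells})
    attributes = sorted({k[1] for k in result.cells})
    for model in models:
        rows = {}
        for metric in _TABLE_METRICS + _RATE_METRICS:
            row = {}
            for attribute in attributes:
                for mitigated in (False, True):
                    key = (model, attribute, mitigated, poison_rate)
                    cell = result.cells.get(key)
                    col = f"{attribute}_{'with' if mitigated else 'without'}"
                    if cell is None or not cell.repeats:
                        row[col] = float("nan")
                    elif metric in _RATE_METRICS:
                        vals = [r["rates_unprivileged"][metric]
                                for r in cell.repeats]
                        row[col] = fm.aggregate_defined(vals)[0]
                    else:
                        row[col] = cell.mean_sd(metric)[0]
            rows[metric] = row
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "metric"
        path = out / f"table_{model}.csv"
        table.to_csv(path, float_format="%.4f")
        written[f"table_{model}"] = path

    summary_path = out / "summary.json"
    result.to_json(summary_path)
    written["summary"] = summary_path

    lines = []
    for model in models:
        for attribute in attributes:
            base = result.cells.get((model, attribute, False, poison_rate))
            mitig = result.cells.get((model, attribute, True, poison_rate))
            if not (base and mitig and base.repeats and mitig.repeats):
                continue
            d_acc = (mitig.mean_sd("accuracy")[0]
                     - base.mean_sd("accuracy")[0])
            d_spd = (abs(mitig.mean_sd("spd")[0])
                     - abs(base.mean_sd("spd")[0]))
            lines.append(
                f"{model}/{attribute}: mitigation changed accuracy by "
                f"{d_acc:+.3f} and |SPD| by {d_spd:+.3f}")
    narrative = out / "narrative.txt"
    narrative.write_text("\n".join(lines) + ("\n" if lines else ""))
    written["narrative"] = narrative
    return written
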