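"""Group-wise confusion counts, error/predictive rates, and bias metrics.

All metrics follow the ``unprivileged minus privileged`` sign convention,
so a negative SPD/EOD means the privileged group receives favourable
outcomes more often.  Rates with an empty denominator return the undefined
marker (NaN) rather than a silent zero; aggregation helpers skip undefined
entries and report how many were skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

#: Marker for metrics whose denominator is empty.
UNDEFINED = float("nan")


def is_defined(x: float) -> bool:
    return not math.isnan(x)


def _as_binary(a, name: str) -> np.ndarray:
    arr = np.asarray(a).astype(int)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return arr


def _check_lengths(**vectors):
    lengths = {k: len(v) for k, v in vectors.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"length mismatch: {lengths}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class GroupConfusion:
    """Confusion counts split by privileged (1) / unprivileged (0) group."""

    privileged: ConfusionCounts
    unprivileged: ConfusionCounts


RATE_NAMES = ("TPR", "TNR", "FPR", "FNR", "FDR", "FOR", "PPV", "NPV")


@dataclass(frozen=True)
class GroupRates:
    """The eight error/predictive rates per group; NaN where undefined."""

    privileged: dict[str, float]
    unprivileged: dict[str, float]


def group_confusion(pred, label, group) -> GroupConfusion:
    """Exact per-group TP/TN/FP/FN counts.

    ``group`` is the privileged indicator (1 = privileged).
    """
    pred = _as_binary(pred, "pred")
    label = _as_binary(label, "label")
    group = _as_binary(group, "group")
    _check_lengths(pred=pred, label=label, group=group)
    out = {}
    for g in (1, 0):
        m = group == g
        p, y = pred[m], label[m]
        out[g] = ConfusionCounts(
            tp=int(np.sum((p == 1) & (y == 1))),
            tn=int(np.sum((p == 0) & (y == 0))),
            fp=int(np.sum((p == 1) & (y == 0))),
            fn=int(np.sum((p == 0) & (y == 1))),
        )
    return GroupConfusion(privileged=out[1], unprivileged=out[0])


def _rates(c: ConfusionCounts) -> dict[str, float]:
    def ratio(num, den):
        return num / den if den > 0 else UNDEFINED

    return {
        "TPR": ratio(c.tp, c.tp + c.fn),
        "TNR": ratio(c.tn, c.tn + c.fp),
        "FPR": ratio(c.fp, c.fp + c.tn),
        "FNR": ratio(c.fn, c.fn + c.tp),
        "FDR": ratio(c.fp, c.fp + c.tp),
        "FOR": ratio(c.fn, c.fn + c.tn),
        "PPV": ratio(c.tp, c.tp + c.fp),
        "NPV": ratio(c.tn, c.tn + c.fn),
    }


def group_rates(gc: GroupConfusion) -> GroupRates:
    return GroupRates(privileged=_rates(gc.privileged),
                      unprivileged=_rates(gc.unprivileged))


# -- bias metrics ------------------------------------------------------------

def _positive_rates(pred, group):
    pred = _as_binary(pred, "pred")
    group = _as_binary(group, "group")
    _check_lengths(pred=pred, group=group)
    n_p = int(np.sum(group == 1))
    n_u = int(np.sum(group == 0))
    r_p = pred[group == 1].mean() if n_p else UNDEFINED
    r_u = pred[group == 0].mean() if n_u else UNDEFINED
    return r_u, r_p


def spd(pred, group) -> float:
    """Statistical parity difference: P(pos | unpriv) - P(pos | priv)."""
    r_u, r_p = _positive_rates(pred, group)
    if not (is_defined(r_u) and is_defined(r_p)):
        return UNDEFINED
    return float(r_u - r_p)


def disparate_impact(pred, group) -> float:
    """Ratio P(pos | unpriv) / P(pos | priv); undefined if the privileged
    positive rate is zero or a group is empty."""
    r_u, r_p = _positive_rates(pred, group)
    if not (is_defined(r_u) and is_defined(r_p)) or r_p == 0:
        return UNDEFINED
    return float(r_u / r_p)


def eod(pred, label, group) -> float:
    """Equal opportunity difference: TPR(unpriv) - TPR(priv)."""
    r = group_rates(group_confusion(pred, label, group))
    t_u, t_p = r.unprivileged["TPR"], r.privileged["TPR"]
    if not (is_defined(t_u) and is_defined(t_p)):
        return UNDEFINED
    return float(t_u - t_p)


def aaod(pred, label, group, *, signed: bool = True) -> float:
    """Average absolute odds difference: 0.5 * (|dFPR| + |dTPR|).

    The defining formula is a nonnegative magnitude.  With ``signed=True``
    (default) the magnitude carries the sign of the TPR gap (unprivileged
    minus privileged; falling back to the FPR gap when the TPR gap is zero),
    so that the direction of the odds disparity is preserved in reports.
    """
    r = group_rates(group_confusion(pred, label, group))
    d_tpr = r.unprivileged["TPR"] - r.privileged["TPR"]
    d_fpr = r.unprivileged["FPR"] - r.privileged["FPR"]
    if math.isnan(d_tpr) or math.isnan(d_fpr):
        return UNDEFINED
    mag = 0.5 * (abs(d_fpr) + abs(d_tpr))
    if not signed:
        return float(mag)
    sign = np.sign(d_tpr) if d_tpr != 0 else (np.sign(d_fpr) if d_fpr != 0 else 1.0)
    return float(sign * mag)


def group_loss_disparity(pred_scores, label, group, loss: str = "zero_one") -> float:
    """Absolute gap in mean per-group loss, |E[L | g=1] - E[L | g=0]|.

    This is the error-disparity diagnostic for label leakage: a feature that
    proxies the sensitive attribute shifts the model's error mass between
    groups.  ``loss`` is ``"zero_one"`` (scores thresholded at 0.5) or
    ``"cross_entropy"`` (scores treated as probabilities).
    """
    scores = np.asarray(pred_scores, dtype=float)
    label = _as_binary(label, "label")
    group = _as_binary(group, "group")
    _check_lengths(scores=scores, label=label, group=group)
    if loss == "zero_one":
        losses = ((scores >= 0.5).astype(int) != label).astype(float)
    elif loss == "cross_entropy":
        p = np.clip(scores, 1e-12, 1 - 1e-12)
        losses = -(label * np.log(p) + (1 - label) * np.log(1 - p))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    if not np.any(group == 1) or not np.any(group == 0):
        raise ValueError("both groups must be nonempty")
    return float(abs(losses[group == 1].mean() - losses[group == 0].mean()))


@dataclass
class BiasReport:
    """The four bias metrics for one attribute under one condition."""

    spd: float
    di: float
    eod: float
    aaod: float            # signed, see :func:`aaod`
    aaod_magnitude: float  # the plain nonnegative formula value
    n_privileged: int
    n_unprivileged: int
    convention: dict = field(default_factory=lambda: {
        "sign": "unprivileged - privileged",
        "privileged_code": 1,
    })

    def to_dict(self) -> dict:
        return asdict(self)


def bias_report(pred, label, group, convention_note: dict | None = None) -> BiasReport:
    """Compute SPD, DI, EOD and AAOD in one pass."""
    group_arr = _as_binary(group, "group")
    report = BiasReport(
        spd=spd(pred, group),
        di=disparate_impact(pred, group),
        eod=eod(pred, label, group),
        aaod=aaod(pred, label, group, signed=True),
        aaod_magnitude=aaod(pred, label, group, signed=False),
        n_privileged=int(np.sum(group_arr == 1)),
        n_unprivileged=int(np.sum(group_arr == 0)),
    )
    if convention_note:
        report.convention.update(convention_note)
    return report


def aggregate_defined(values) -> tuple[float, float, int]:
    """Mean and SD over the defined entries; returns (mean, sd, n_skipped)."""
    arr = np.asarray(list(values), dtype=float)
    mask = ~np.isnan(arr)
    kept = arr[mask]
    skipped = int((~mask).sum())
    if kept.size == 0:
        return UNDEFINED, UNDEFINED, skipped
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return float(kept.mean()), sd, skipped
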