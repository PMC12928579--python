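"""Adversarial data manipulations.

Two attacks on the training data of a clinical classifier:

* **Label poisoning** — indiscriminate label flipping (y <- 1 - y) of a
  fixed fraction of *training* labels, selected uniformly within
  class x sensitive-group strata with largest-remainder apportionment so
  the global flip count equals ``round(rate * n)``.  Validation and test
  labels are never touched.
* **Label leakage** — injection of a binary proxy column ``leak_s`` that
  agrees with a sensitive attribute ``s`` with probability alpha
  (default 0.90), applied to *all* partitions (systemic leakage) after
  preprocessing and deliberately retained in the model-facing feature view.

Default configuration: main poisoning rate 5% with a sensitivity sweep at
{0, 5, 10, 15, 20}%, leakage degree 0.90, base random seed 4765416.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, ROLE_LEAK

__all__ = ["AttackConfig", "AttackLog", "poison_labels",
           "inject_leak_feature", "derive_seed", "POISON_RATE_SWEEP",
           "BASE_SEED"]

BASE_SEED = 4765416
POISON_RATE_SWEEP = (0.0, 0.05, 0.10, 0.15, 0.20)


@dataclass(frozen=True)
class AttackConfig:
    """Configuration of one attack instance."""

    kind: str                     # "poison" | "leak"
    poison_rate: float = 0.05
    leak_alpha: float = 0.90
    seed: int = BASE_SEED
    leak_column: str = "leak_s"

    def __post_init__(self):
        if self.kind not in ("poison", "leak"):
            raise ValueError(f"unknown attack kind {self.kind!r}")
        if not 0.0 <= self.poison_rate <= 1.0:
            raise ValueError("poison_rate must lie in [0, 1]")
        if not 0.0 <= self.leak_alpha <= 1.0:
            raise ValueError("leak_alpha must lie in [0, 1]")


@dataclass
class AttackLog:
    """Realized effect of an attack, for audit."""

    kind: str
    seed: int
    realized_rate: float = 0.0
    flips_per_stratum: dict = field(default_factory=dict)
    priors_before: dict = field(default_factory=dict)
    priors_after: dict = field(default_factory=dict)
    shortfall: int = 0
    empirical_agreement: float | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def derive_seed(base_seed: int, fold_index: int = 0, repeat_index: int = 0) -> int:
    """Per-fold, per-repeat seed: base + fold + 1000 * repeat, kept < 2^31."""
    return (base_seed + fold_index + 1000 * repeat_index) % (2**31)


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` across strata proportional to
    ``quotas``; floors first, then +1 to the largest fractional parts
    (ties toward earlier strata)."""
    floors = np.floor(quotas).astype(int)
    remainder = total - floors.sum()
    if remainder > 0:
        frac = quotas - floors
        order = sorted(range(len(quotas)), key=lambda i: (-frac[i], i))
        for i in order[:remainder]:
            floors[i] += 1
    elif remainder < 0:
        frac = quotas - floors
        order = sorted(range(len(quotas)), key=lambda i: (frac[i], i))
        for i in order[:-remainder]:
            floors[i] = max(0, floors[i] - 1)
    return floors


def poison_labels(labels, strata, cfg: AttackConfig,
                  ) -> tuple[np.ndarray, AttackLog]:
    """Flip ``round(rate * n)`` training labels, uniformly within strata.

    ``strata`` assigns each training row to a class x sensitive-group cell;
    flips are apportioned across strata by largest remainder so the global
    realized count is exact.  A stratum smaller than its apportioned flips
    is capped at its size and the shortfall logged, not redistributed.
    """
    if cfg.kind != "poison":
        raise ValueError("config kind must be 'poison'")
    y = np.asarray(labels).astype(int).copy()
    strata = np.asarray(strata)
    if len(strata) != len(y):
        raise ValueError("strata vector must align with labels")
    n = len(y)
    total = int(round(cfg.poison_rate * n))

    keys, inverse = np.unique(strata, return_inverse=True)
    sizes = np.bincount(inverse, minlength=len(keys))
    quotas = cfg.poison_rate * sizes
    counts = _largest_remainder(quotas, total)

    rng = np.random.default_rng(cfg.seed)
    priors_before = {"p_positive": float(y.mean())}
    flips_per_stratum: dict[str, int] = {}
    shortfall = 0
    flipped_rows: list[int] = []
    for k, key in enumerate(keys):
        want = int(counts[k])
        idx = np.flatnonzero(inverse == k)
        take = min(want, len(idx))
        shortfall += want - take
        if take > 0:
            chosen = rng.choice(idx, size=take, replace=False)
            y[chosen] = 1 - y[chosen]
            flipped_rows.extend(chosen.tolist())
        flips_per_stratum[str(key)] = take

    log = AttackLog(
        kind="poison", seed=cfg.seed,
        realized_rate=len(flipped_rows) / n if n else 0.0,
        flips_per_stratum=flips_per_stratum,
        priors_before=priors_before,
        priors_after={"p_positive": float(y.mean())},
        shortfall=shortfall,
        extra={"target_flips": total, "flipped_rows": sorted(flipped_rows)},
    )
    return y, log


def inject_leak_feature(cohort: Cohort, s, cfg: AttackConfig,
                        ) -> tuple[Cohort, AttackLog]:
    """Add the binary proxy column agreeing with ``s`` w.p. ``leak_alpha``.

    Applied to every row (train, validation and test — systemic leakage);
    the column is tagged with the leak role so the sensitive-exclusion
    stage retains it in the model-facing feature view.  ``s`` may be a
    binary vector or the name of a 0/1 column of the cohort.
    """
    if cfg.kind != "leak":
        raise ValueError("config kind must be 'leak'")
    if isinstance(s, str):
        s = cohort.df[s].to_numpy()
    s = np.asarray(s).astype(int)
    if len(s) != cohort.n:
        raise ValueError("sensitive vector must align with the cohort rows")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("sensitive vector must be binary")
    rng = np.random.default_rng(cfg.seed)
    agree = rng.random(len(s)) < cfg.leak_alpha
    leak = np.where(agree, s, 1 - s)

    df = cohort.df.copy()
    df[cfg.leak_column] = leak
    roles = dict(cohort.roles)
    roles[cfg.leak_column] = ROLE_LEAK
    out = cohort.copy(df=df, roles=roles)
    log = AttackLog(kind="leak", seed=cfg.seed,
                    empirical_agreement=float((leak == s).mean()),
                    extra={"alpha": cfg.leak_alpha, "n": int(len(s)),
                           "column": cfg.leak_column})
    out.meta["leak_log"] = asdict(log)
    return out, log
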