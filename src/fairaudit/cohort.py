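"""Core containers: the tabular cohort and sensitive-attribute specifications.

A :class:`Cohort` wraps a single :class:`pandas.DataFrame` holding clinical
features, a binary diagnosis label, and sensitive demographic attributes,
plus a role tag per column.  Roles keep the model-facing feature view and
the fairness-audit view strictly separated: columns tagged ``sensitive`` or
``group`` never enter model training, while an injected ``leak`` column is
deliberately retained in the feature view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# Column roles
ROLE_CLINICAL = "clinical"   # numeric feature used for prediction
ROLE_SENSITIVE = "sensitive" # raw demographic attribute (audit only)
ROLE_GROUP = "group"         # binarized sensitive attribute, 1 = privileged
ROLE_LABEL = "label"         # binary diagnosis, 1 = disease
ROLE_LEAK = "leak"           # adversarial proxy column, retained in features

_VALID_ROLES = {ROLE_CLINICAL, ROLE_SENSITIVE, ROLE_GROUP, ROLE_LABEL, ROLE_LEAK}


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class Cohort:
    """A participant-by-column table with per-column role tags.

    Parameters
    ----------
    df
        One row per participant.  May contain missing cells in clinical
        columns until imputation.
    roles
        Mapping column name -> role, one entry per column of ``df``.
    meta
        Free-form provenance (seed, config echo, stage logs).
    """

    df: pd.DataFrame
    roles: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.df.columns) - set(self.roles)
        extra = set(self.roles) - set(self.df.columns)
        if missing or extra:
            raise CohortError(
                f"roles must cover exactly the columns; missing={sorted(missing)}, "
                f"extra={sorted(extra)}"
            )
        bad = {c: r for c, r in self.roles.items() if r not in _VALID_ROLES}
        if bad:
            raise CohortError(f"unknown roles: {bad}")
        labels = [c for c, r in self.roles.items() if r == ROLE_LABEL]
        if len(labels) != 1:
            raise CohortError(f"expected exactly one label column, got {labels}")
        y = self.df[labels[0]]
        if not y.isin([0, 1]).all():
            raise CohortError("label column must be binary 0/1 with no missing values")

    # -- views ---------------------------------------------------------------

    def columns_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.df.columns if self.roles[c] in roles]

    @property
    def label_column(self) -> str:
        return self.columns_with_role(ROLE_LABEL)[0]

    @property
    def label(self) -> np.ndarray:
        return self.df[self.label_column].to_numpy(dtype=int)

    @property
    def clinical_columns(self) -> list[str]:
        return self.columns_with_role(ROLE_CLINICAL)

    @property
    def feature_columns(self) -> list[str]:
        """Model-facing columns: clinical features plus any leak column."""
        return self.columns_with_role(ROLE_CLINICAL, ROLE_LEAK)

    @property
    def features(self) -> pd.DataFrame:
        return self.df[self.feature_columns]

    @property
    def sensitive_columns(self) -> list[str]:
        return self.columns_with_role(ROLE_SENSITIVE)

    def group(self, column: str) -> np.ndarray:
        """Binary privileged-group indicator for a ``group``-role column."""
        if self.roles.get(column) != ROLE_GROUP:
            raise CohortError(f"{column!r} is not a binarized group column")
        return self.df[column].to_numpy(dtype=int)

    def copy(self, df: pd.DataFrame | None = None,
             roles: dict[str, str] | None = None,
             meta: dict | None = None) -> "Cohort":
        return Cohort(
            df=self.df.copy() if df is None else df,
            roles=dict(self.roles) if roles is None else roles,
            meta=dict(self.meta) if meta is None else meta,
        )

    @property
    def n(self) -> int:
        return len(self.df)

    # -- IO ------------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a ``<path>.schema.json`` sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = {"roles": self.roles, "meta": _jsonable(self.meta)}
        Path(f"{path}.schema.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        sidecar = json.loads(Path(f"{path}.schema.json").read_text())
        df = pd.read_csv(path)
        return cls(df=df, roles=sidecar["roles"], meta=sidecar.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# -- sensitive attributes ----------------------------------------------------

@dataclass(frozen=True)
class SensitiveSpec:
    """Binarization rule for one sensitive attribute.

    ``rule`` is either ``"threshold"`` (values strictly below ``cut`` fall in
    the low bin) or ``"equals"`` (values equal to ``privileged_value`` form
    one bin).  The derived group column codes the privileged bin as 1.

    Attributes
    ----------
    attribute
        Raw column name in the cohort.
    rule
        ``"threshold"`` or ``"equals"``.
    cut
        Threshold for the ``threshold`` rule (years for age).
    privileged_value
        For ``equals``: the raw value of the privileged bin.  For
        ``threshold``: ``"low"`` (below the cut) or ``"high"``.
    """

    attribute: str
    rule: str
    privileged_value: object
    cut: float | None = None

    def __post_init__(self):
        if self.rule not in ("threshold", "equals"):
            raise ValueError(f"unknown binarization rule {self.rule!r}")
        if self.rule == "threshold":
            if self.cut is None:
                raise ValueError("threshold rule requires a cut point")
            if self.privileged_value not in ("low", "high"):
                raise ValueError("threshold privileged_value must be 'low' or 'high'")

    @property
    def group_column(self) -> str:
        return f"grp_{self.attribute}"

    def binarize(self, values: pd.Series) -> np.ndarray:
        """Map raw values to the privileged indicator (1 = privileged)."""
        if values.isna().any():
            bad = values.index[values.isna()].tolist()[:5]
            raise CohortError(
                f"cannot binarize {self.attribute!r}: missing values at rows {bad}"
            )
        if self.rule == "threshold":
            low = values.to_numpy(dtype=float) < self.cut
            return (low if self.privileged_value == "low" else ~low).astype(int)
        return (values == self.privileged_value).to_numpy().astype(int)


def default_sensitive_specs() -> list[SensitiveSpec]:
    """Default binarization of the three audited attributes.

    Age: two bins cut at 60 years, privileged = under 60 (most patients are
    60 or older).  Gender: binary 0/1 with 1 = male, privileged = male.
    Race: White vs Non-White, privileged = White.
    """
    return [
        SensitiveSpec(attribute="age", rule="threshold", cut=60.0,
                      privileged_value="low"),
        SensitiveSpec(attribute="gender", rule="equals", privileged_value=1),
        SensitiveSpec(attribute="race", rule="equals", privileged_value="White"),
    ]
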