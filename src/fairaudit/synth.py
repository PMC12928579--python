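"""Synthetic Parkinson's-like cohort generation.

Emulates the structure of the PPMI baseline cross-section so the whole
audit pipeline is testable without restricted data: 648 PD / 434 HC with a
male-skewed PD group (391 male PD, 202 male HC), ages centred near 64/63
years, a White-skewed race distribution, and class-conditional Gaussian
clinical features whose means match the published baseline summary (smell
identification, semantic fluency, sleep and mood scales, UPDRS parts,
Hoehn & Yahr stage, Schwab & England score, ...).

Class, sex-within-class and race counts are realized by exact allocation —
they match the configuration exactly rather than in expectation.  An
optional planted outcome bias relabels a minimal subset of participants so
that the label base-rate gap between an unprivileged and a privileged group
equals a chosen value, giving downstream mitigation tests a known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    Cohort,
    SensitiveSpec,
    ROLE_CLINICAL,
    ROLE_LABEL,
    ROLE_SENSITIVE,
)

__all__ = [
    "FeatureSpec",
    "CohortConfig",
    "ConfigurationError",
    "generate_cohort",
    "plant_outcome_bias",
    "ppmi_feature_specs",
]


class ConfigurationError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass(frozen=True)
class FeatureSpec:
    """One clinical feature: class-conditional means and a within-group sd."""

    name: str
    mean_pd: float
    mean_hc: float
    sd: float


# Baseline (visit 1) feature summary; sd is the published spread column with
# a floor of 0.1 so every feature keeps nonzero within-group variation.
_PPMI_TABLE = [
    ("education_years",    15.47, 16.95, 1.05),
    ("upsit",               5.66,  7.80, 1.51),
    ("semantic_fluency",   28.43, 30.36, 1.36),
    ("rem_sleep_rbdq",      0.26,  0.22, 0.03),
    ("ess",                 0.82,  0.72, 0.07),
    ("moca",                1.07,  1.03, 0.03),
    ("gds15",               0.36,  0.34, 0.01),
    ("updrs_i",             0.57,  0.44, 0.09),
    ("updrs_ii",            0.49,  0.00, 0.35),
    ("updrs_iii",           3.30,  2.90, 0.28),
    ("hoehn_yahr",          1.66,  0.00, 1.17),
    ("schwab_england",     90.40, 96.90, 4.60),
    ("fss",                 0.78,  0.53, 0.18),
]

_SD_FLOOR = 0.1


def ppmi_feature_specs() -> list[FeatureSpec]:
    """Default clinical feature specifications (baseline visit)."""
    return [FeatureSpec(name, m_pd, m_hc, max(sd, _SD_FLOOR))
            for name, m_pd, m_hc, sd in _PPMI_TABLE]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the published baseline constitution: 648 PD and 434
    HC participants, 391 males among PD and 202 among HC, mean ages
    64.23 / 62.83 years.  Race skew and missingness have no published
    counts; their defaults (90% White, 5% missing cells per feature) mirror
    the reported overrepresentation and a modest observational missingness.
    """

    n_pd: int = 648
    n_hc: int = 434
    male_frac_pd: float = 391 / 648
    male_frac_hc: float = 202 / 434
    age_mean_pd: float = 64.23
    age_mean_hc: float = 62.83
    age_sd: float = 9.0
    age_bounds: tuple[float, float] = (30.0, 95.0)
    race_white_frac: float = 0.9
    feature_specs: list[FeatureSpec] = field(default_factory=ppmi_feature_specs)
    missing_frac: float = 0.05
    bias_strength: float = 0.0
    bias_attribute: str = "gender"
    seed: int = 4765416

    def validate(self) -> None:
        if self.n_pd <= 0:
            raise ConfigurationError("n_pd must be positive")
        if self.n_hc <= 0:
            raise ConfigurationError("n_hc must be positive")
        for name in ("male_frac_pd", "male_frac_hc", "race_white_frac",
                     "missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        for spec in self.feature_specs:
            if spec.sd <= 0:
                raise ConfigurationError(
                    f"feature_specs[{spec.name!r}].sd must be positive")
        if round(self.male_frac_pd * self.n_pd) > self.n_pd:
            raise ConfigurationError("male_frac_pd implies more males than PD rows")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_specs"] = [asdict(s) for s in self.feature_specs]
        return d


def _exact_binary_allocation(n: int, frac: float, rng: np.random.Generator,
                             ) -> np.ndarray:
    """A 0/1 vector with exactly round(frac * n) ones, in random positions."""
    k = int(round(frac * n))
    v = np.zeros(n, dtype=int)
    v[:k] = 1
    rng.shuffle(v)
    return v


def _truncated_normal(n, mean, sd, bounds, rng):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a synthetic cohort under exact demographic allocation.

    Class sizes, male counts within each class, and White counts within each
    class are allocated exactly (``round(frac * n)``), not sampled.  Clinical
    features come from class-conditional Gaussians; ages from truncated
    Gaussians; missing cells are inserted completely at random per feature.
    Two calls with the same configuration produce identical cohorts.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    blocks = []
    for label_value, n, male_frac, age_mean in (
        (1, config.n_pd, config.male_frac_pd, config.age_mean_pd),
        (0, config.n_hc, config.male_frac_hc, config.age_mean_hc),
    ):
        cols: dict[str, np.ndarray] = {}
        for spec in config.feature_specs:
            mean = spec.mean_pd if label_value == 1 else spec.mean_hc
            cols[spec.name] = rng.normal(mean, spec.sd, size=n)
        cols["age"] = _truncated_normal(n, age_mean, config.age_sd,
                                        config.age_bounds, rng)
        cols["gender"] = _exact_binary_allocation(n, male_frac, rng)
        white = _exact_binary_allocation(n, config.race_white_frac, rng)
        cols["race"] = np.where(white == 1, "White", "Non-White")
        cols["diagnosis"] = np.full(n, label_value)
        blocks.append(pd.DataFrame(cols))

    df = pd.concat(blocks, ignore_index=True)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)

    # MCAR missingness, clinical features only
    if config.missing_frac > 0:
        for spec in config.feature_specs:
            mask = rng.random(len(df)) < config.missing_frac
            df.loc[mask, spec.name] = np.nan

    roles = {spec.name: ROLE_CLINICAL for spec in config.feature_specs}
    roles.update(age=ROLE_SENSITIVE, gender=ROLE_SENSITIVE,
                 race=ROLE_SENSITIVE, diagnosis=ROLE_LABEL)
    cohort = Cohort(df=df, roles=roles,
                    meta={"generator": "fairaudit.synth",
                          "config": config.to_dict(), "seed": config.seed})

    if config.bias_strength != 0.0:
        spec = _default_spec_for(config.bias_attribute)
        cohort, log = plant_outcome_bias(cohort, spec, config.bias_strength,
                                         seed=config.seed)
        cohort.meta["planted_bias"] = log
    return cohort


def _default_spec_for(attribute: str) -> SensitiveSpec:
    from .cohort import default_sensitive_specs

    for spec in default_sensitive_specs():
        if spec.attribute == attribute:
            return spec
    raise ConfigurationError(f"no default sensitive spec for {attribute!r}")


def plant_outcome_bias(cohort: Cohort, spec: SensitiveSpec,
                       bias_strength: float, seed: int,
                       resample_features: bool = True,
                       ) -> tuple[Cohort, dict]:
    """Relabel a minimal random subset so the label base-rate gap equals
    ``bias_strength``.

    The gap is P(label=1 | unprivileged) - P(label=1 | privileged) under the
    given binarization.  The total positive count is preserved as closely as
    the group-size parity allows, so the planted disparity is a pure
    between-group shift.  Returns the modified cohort and an attack-style
    log of the flipped row indices.

    With ``resample_features=True`` (default) the clinical features of each
    relabeled row are redrawn from the new class-conditional distribution
    (when the cohort carries its generator configuration), so the planted
    disparity is expressed in the feature distribution and therefore
    *learnable* by a classifier that never sees the sensitive attributes.
    Without resampling the planted gap exists only in the labels and a
    feature-based model cannot reproduce it.  Missing cells stay missing.
    """
    group = spec.binarize(cohort.df[spec.attribute])
    y = cohort.label.copy()
    n_u = int(np.sum(group == 0))
    n_p = int(np.sum(group == 1))
    if n_u == 0 or n_p == 0:
        raise ConfigurationError("both groups must be nonempty to plant bias")
    total_pos = int(y.sum())

    # Target positive counts preserving the total: solve for the unprivileged
    # rate from gap = p_u - p_p with n_u*p_u + n_p*p_p = total_pos.
    p_u_target = (bias_strength * n_p + total_pos) / (n_p + n_u)
    k_u = int(round(p_u_target * n_u))
    k_p = total_pos - k_u
    if not (0 <= k_u <= n_u and 0 <= k_p <= n_p):
        lo = (max(0.0, (total_pos - n_p) / n_u) * (n_p + n_u) - total_pos) / n_p
        hi = (min(1.0, total_pos / n_u) * (n_p + n_u) - total_pos) / n_p
        raise ConfigurationError(
            f"bias_strength {bias_strength} is unattainable; feasible range "
            f"is approximately [{lo:.3f}, {hi:.3f}]")

    rng = np.random.default_rng(seed)
    new_y = y.copy()
    flipped: list[int] = []
    for g, k_target in ((0, k_u), (1, k_p)):
        idx = np.flatnonzero(group == g)
        current = int(y[idx].sum())
        delta = k_target - current
        if delta > 0:
            candidates = idx[y[idx] == 0]
            chosen = rng.choice(candidates, size=delta, replace=False)
            new_y[chosen] = 1
            flipped.extend(chosen.tolist())
        elif delta < 0:
            candidates = idx[y[idx] == 1]
            chosen = rng.choice(candidates, size=-delta, replace=False)
            new_y[chosen] = 0
            flipped.extend(chosen.tolist())

    df = cohort.df.copy()
    df[cohort.label_column] = new_y

    resampled = False
    gen_cfg = cohort.meta.get("config") if isinstance(cohort.meta, dict) else None
    if resample_features and flipped and gen_cfg and "feature_specs" in gen_cfg:
        resampled = True
        for fs in gen_cfg["feature_specs"]:
            name = fs["name"]
            if name not in df.columns:
                continue
            col = df[name].to_numpy(dtype=float)
            for row in flipped:
                if np.isnan(col[row]):
                    continue  # preserve injected missingness
                mean = fs["mean_pd"] if new_y[row] == 1 else fs["mean_hc"]
                col[row] = rng.normal(mean, fs["sd"])
            df[name] = col

    achieved = (new_y[group == 0].mean() - new_y[group == 1].mean())
    log = {
        "kind": "plant_outcome_bias",
        "attribute": spec.attribute,
        "target_gap": float(bias_strength),
        "achieved_gap": float(achieved),
        "flipped_rows": sorted(flipped),
        "n_flipped": len(flipped),
        "features_resampled": resampled,
        "seed": int(seed),
    }
    return cohort.copy(df=df), log
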