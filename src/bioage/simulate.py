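"""Synthetic biomarker cohorts with a latent pace-of-ageing factor.

The generator emulates an age-stratified cross-sectional recruitment
(default 35-74 years, eight 5-year strata per sex) in which every panel
biomarker is a noisy affine readout of chronological age ``A`` and of a
latent, age-independent pace-of-ageing deviation ``P``::

    marker_i = baseline_i + age_slope_i * (A + shift) + pace_loading_i * P_eff + eps_i

with ``eps_i ~ N(0, noise_sd_i^2)`` and ``P ~ N(0, pace_sd^2)`` independent
of ``A``.  ``shift`` is a subgroup-specific latent-age offset (e.g. a
progeroid Down-Syndrome-like group at +5 years, hormone users past
menopause at -2 years) that enters the marker equation only -- the
recorded chronological age is untouched.  Cumulative smoking exposure
adds to the latent pace, ``P_eff = P + smoking_beta * packs``, yielding a
dose-response in downstream age-difference analyses.

External (non-panel) clinical-chemistry markers carry a role label
encoding the driver/bystander dichotomy: "driver" markers load on the
latent pace only, "bystander" markers on chronological age only, "both"
on both, "neither" on neither.

Ground truth (latent pace and latent biological age) is returned
alongside the cohort and is never consumed by any estimation stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerSpec",
    "ExternalMarkerSpec",
    "SimConfig",
    "default_panel",
    "default_external",
    "generate_cohort",
    "inject_subgroup",
    "write_cohort",
    "read_cohort",
]

SUBGROUPS = ("RASIG", "GO", "SGO", "DS")

#: SD of chronological age under uniform sampling on [35, 75).
AGE_SD_UNIFORM = 40.0 / math.sqrt(12.0)

ROLES = ("driver", "bystander", "both", "neither")


@dataclass(frozen=True)
class MarkerSpec:
    """Generative parameters of one panel biomarker.

    ``age_slope`` is the analogue of the per-marker regression slope on
    age (units per year); ``pace_loading`` couples the marker to the
    latent pace (units per latent year); ``baseline`` is the intercept.
    """

    name: str
    age_slope: float
    pace_loading: float
    noise_sd: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("name: must be non-empty")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0 for marker {self.name!r}")


@dataclass(frozen=True)
class ExternalMarkerSpec:
    """Generative parameters of one external (non-panel) marker.

    The role label must be consistent with the loadings: a driver loads
    on the latent pace only, a bystander on chronological age only.
    """

    name: str
    role: str
    ca_loading: float
    pace_loading: float
    noise_sd: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role: {self.role!r} not one of {ROLES}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0 for marker {self.name!r}")
        ca, pl = self.ca_loading, self.pace_loading
        ok = {
            "driver": pl != 0 and ca == 0,
            "bystander": ca != 0 and pl == 0,
            "both": ca != 0 and pl != 0,
            "neither": ca == 0 and pl == 0,
        }[self.role]
        if not ok:
            raise ValueError(
                f"role: {self.name!r} declared {self.role!r} but has "
                f"ca_loading={ca}, pace_loading={pl}"
            )


def _noise_for_target_r(age_slope: float, pace_loading: float,
                        target_r: float, pace_sd: float) -> float:
    """Noise SD giving a population marker-age correlation of target_r.

    corr(marker, A) = a*sd(A) / sqrt(a^2 var(A) + g^2 pace_sd^2 + noise^2)
    under uniform age sampling on the default range.
    """
    sig_a2 = (age_slope * AGE_SD_UNIFORM) ** 2
    noise2 = sig_a2 * (1.0 / target_r**2 - 1.0) - (pace_loading * pace_sd) ** 2
    if noise2 <= 0:
        raise ValueError("target_r unattainable with this pace loading")
    return math.sqrt(noise2)


# (age_slope, pace multiplier, target marker-age correlation).  The pace
# multiplier scales pace_loading relative to age_slope: 1 = the marker
# tracks latent biological age A + P; 0 = pure chronological tracker;
# 2 = pace-sensitive.  Correlations span the ~0.1-0.8 range typical of
# candidate ageing-biomarker panels; signs mixed as in real panels.
_PANEL_TABLE = [
    (0.50, 1.0, 0.80), (0.45, 1.0, 0.77), (0.30, 1.0, 0.74), (-0.60, 1.0, 0.70),
    (0.25, 1.0, 0.66), (0.40, 2.0, 0.62), (-0.35, 1.0, 0.60), (0.20, 1.0, 0.58),
    (0.55, 0.0, 0.55), (-0.45, 1.0, 0.52), (0.15, 1.0, 0.50), (0.60, 1.0, 0.47),
    (-0.25, 2.0, 0.45), (0.35, 1.0, 0.42), (0.10, 0.0, 0.40), (-0.50, 1.0, 0.38),
    (0.30, 1.0, 0.35), (0.22, 1.0, 0.33), (-0.18, 1.0, 0.30), (0.28, 2.0, 0.28),
    (0.12, 1.0, 0.26), (-0.40, 1.0, 0.24), (0.20, 0.0, 0.22), (0.16, 1.0, 0.20),
    (-0.22, 1.0, 0.18), (0.26, 1.0, 0.16), (0.14, 2.0, 0.14), (-0.12, 1.0, 0.12),
    (0.18, 1.0, 0.11), (0.24, 1.0, 0.10), (-0.15, 0.0, 0.09), (0.10, 1.0, 0.08),
]


def default_panel(pace_sd: float = 5.0) -> list[MarkerSpec]:
    """Default 32-marker candidate panel (generic Gaussian markers)."""
    specs = []
    for i, (a, mult, r) in enumerate(_PANEL_TABLE, start=1):
        g = a * mult
        specs.append(MarkerSpec(
            name=f"pm{i:02d}",
            age_slope=a,
            pace_loading=g,
            noise_sd=_noise_for_target_r(a, g, r, pace_sd),
            baseline=10.0 + i,
        ))
    return specs


def default_external(pace_sd: float = 5.0) -> list[ExternalMarkerSpec]:
    """Default external clinical-chemistry markers.

    Drivers (HDL, 25-OH-vitamin D, CD3+CD4+/CD45+ ratio) load on the
    latent pace with negative sign (favourable values in biologically
    younger subjects); bystanders (glucose, HbA1c) track chronological
    age; insulin loads on both.  Loadings are tuned so each marker's
    marginal correlation with its driving variable is about 0.2, the
    weak-effect regime reported for such associations.
    """

    def _noise_for(signal_sd: float, r: float = 0.2) -> float:
        return signal_sd * math.sqrt(1.0 / r**2 - 1.0)

    return [
        ExternalMarkerSpec("hdl", "driver", 0.0, -0.8,
                           _noise_for(0.8 * pace_sd), baseline=55.0),
        ExternalMarkerSpec("vitd", "driver", 0.0, -0.5,
                           _noise_for(0.5 * pace_sd), baseline=30.0),
        ExternalMarkerSpec("cd4_ratio", "driver", 0.0, -0.4,
                           _noise_for(0.4 * pace_sd), baseline=45.0),
        ExternalMarkerSpec("glucose", "bystander", 0.35, 0.0,
                           _noise_for(0.35 * AGE_SD_UNIFORM), baseline=70.75),
        ExternalMarkerSpec("hba1c", "bystander", 0.010, 0.0,
                           _noise_for(0.010 * AGE_SD_UNIFORM), baseline=4.95),
        ExternalMarkerSpec("insulin", "both", 0.04, 0.09, 2.0, baseline=5.8),
    ]


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort.

    Defaults emulate the study conditions the pipeline was designed for:
    eight 5-year strata covering 35-74 years, ~110 subjects per stratum
    per sex, latent pace SD of 5 years, a DS-like progeroid subgroup at
    +5 latent years, hormone use delaying latent age by 2 years in women
    past 50, and a smoking dose-response of 0.002 latent years per
    cumulative pack.
    """

    n_per_stratum: int = 110
    age_range: tuple[int, int] = (35, 74)
    panel_spec: list[MarkerSpec] = field(default_factory=default_panel)
    external_spec: list[ExternalMarkerSpec] = field(default_factory=default_external)
    pace_sd: float = 5.0
    subgroup_shifts: dict[str, float] = field(
        default_factory=lambda: {"DS": 5.0, "hormone_use": -2.0})
    subgroup_fractions: dict[str, float] = field(
        default_factory=lambda: {"GO": 0.10, "SGO": 0.10, "DS": 0.03})
    hormone_use_rate: float = 0.25
    menopause_age: float = 50.0
    smoker_rate: float = 0.30
    packs_logmean: float = math.log(500.0)
    packs_logsd: float = 1.0
    smoking_beta: float = 0.002
    missing_rate: float = 0.02
    outlier_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_stratum < 0:
            raise ValueError("n_per_stratum: must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range: lo must be < hi")
        for rate_name in ("missing_rate", "outlier_rate", "hormone_use_rate",
                          "smoker_rate"):
            r = getattr(self, rate_name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{rate_name}: must be in [0, 1)")
        if self.pace_sd < 0:
            raise ValueError("pace_sd: must be >= 0")
        names = [m.name for m in self.panel_spec] + [m.name for m in self.external_spec]
        if len(set(names)) != len(names):
            raise ValueError("panel_spec/external_spec: duplicate marker names")
        for label in self.subgroup_fractions:
            if label not in SUBGROUPS or label == "RASIG":
                raise ValueError(f"subgroup_fractions: unknown label {label!r}")
        if sum(self.subgroup_fractions.values()) >= 1.0:
            raise ValueError("subgroup_fractions: must sum to < 1")

    @property
    def panel_names(self) -> list[str]:
        return [m.name for m in self.panel_spec]

    @property
    def external_names(self) -> list[str]:
        return [m.name for m in self.external_spec]

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["panel_spec"] = [asdict(m) for m in self.panel_spec]
        d["external_spec"] = [asdict(m) for m in self.external_spec]
        d["age_range"] = list(self.age_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["panel_spec"] = [MarkerSpec(**m) for m in d.get("panel_spec", [])]
        d["external_spec"] = [ExternalMarkerSpec(**m) for m in d.get("external_spec", [])]
        d["age_range"] = tuple(d["age_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _strata(age_range: tuple[int, int]) -> list[tuple[float, float]]:
    """5-year recruitment strata covering [lo, hi] inclusive."""
    lo, hi = age_range
    return [(float(s), float(min(s + 5, hi + 1))) for s in range(lo, hi + 1, 5)]


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort plus its ground truth.

    Returns ``(cohort, truth)``.  The cohort has one row per subject with
    id, sex, age, subgroup, covariates, panel and external marker
    columns; the truth table records each subject's latent pace and
    latent biological age and is keyed by subject id.  Fully
    deterministic given ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    strata = _strata(config.age_range)

    sexes, ages = [], []
    for sex in ("F", "M"):
        for s_lo, s_hi in strata:
            a = rng.uniform(s_lo, s_hi, size=config.n_per_stratum)
            ages.append(a)
            sexes.extend([sex] * config.n_per_stratum)
    age = np.concatenate(ages) if ages else np.empty(0)
    sex = np.asarray(sexes, dtype=object)
    n = age.size

    ids = np.array([f"S{i:05d}" for i in range(1, n + 1)], dtype=object)

    # subgroup assignment
    labels = list(config.subgroup_fractions)
    probs = np.array([config.subgroup_fractions[l] for l in labels])
    p_full = np.concatenate([[1.0 - probs.sum()], probs])
    subgroup = rng.choice(np.array(["RASIG"] + labels, dtype=object),
                          size=n, p=p_full)

    # covariates
    hormone_use = np.where(
        (sex == "F") & (rng.random(n) < config.hormone_use_rate), 1, 0)
    smoker = (rng.random(n) < config.smoker_rate).astype(int)
    packs = np.where(
        smoker == 1,
        rng.lognormal(config.packs_logmean, config.packs_logsd, size=n), 0.0)

    # latent structure
    pace = rng.normal(0.0, config.pace_sd, size=n) if n else np.empty(0)
    pace_eff = pace + config.smoking_beta * packs
    shift = np.zeros(n)
    for label, s in config.subgroup_shifts.items():
        if label == "hormone_use":
            sel = (hormone_use == 1) & (age > config.menopause_age)
        else:
            sel = subgroup == label
        shift[sel] += s

    cohort = pd.DataFrame({
        "id": ids, "sex": sex, "age": age, "subgroup": subgroup,
        "hormone_use": hormone_use, "smoker": smoker, "packs": packs,
    })
    latent_a = age + shift
    for spec in config.panel_spec:
        cohort[spec.name] = (spec.baseline + spec.age_slope * latent_a
                             + spec.pace_loading * pace_eff
                             + rng.normal(0.0, spec.noise_sd, size=n))
    for spec in config.external_spec:
        cohort[spec.name] = (spec.baseline + spec.ca_loading * latent_a
                             + spec.pace_loading * pace_eff
                             + rng.normal(0.0, spec.noise_sd, size=n))

    # outlier injection: replace by Q3 + 10*IQR of the clean column so the
    # IQR fence (k = 1.3) and the [0.01, 0.99] quantile rule both fire
    if n and config.outlier_rate > 0:
        for name in config.panel_names:
            col = cohort[name].to_numpy()
            q1, q3 = np.quantile(col, [0.25, 0.75])
            hit = rng.random(n) < config.outlier_rate
            col[hit] = q3 + 10.0 * (q3 - q1)
            cohort[name] = col

    # missingness, completely at random over marker cells
    if n and config.missing_rate > 0:
        for name in config.panel_names + config.external_names:
            col = cohort[name].to_numpy(dtype=float)
            col[rng.random(n) < config.missing_rate] = np.nan
            cohort[name] = col

    truth = pd.DataFrame({
        "id": ids,
        "pace": pace_eff,
        "shift": shift,
        "latent_age": age + shift + pace_eff,
    })
    return cohort, truth


def inject_subgroup(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    label: str,
    shift_years: float,
    *,
    ids: Sequence[str] | None = None,
    n: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relabel subjects as subgroup ``label`` with a latent-age shift.

    The shift enters each marker through its deterministic age term
    (``age_slope * shift_years`` for panel markers, ``ca_loading *
    shift_years`` for external markers) while the original noise draw is
    kept, so a zero shift is an exact identity and, in the noise-free
    limit, a shifted subject's markers equal those of an unshifted
    subject ``shift_years`` older.  Targets are either explicit ``ids``
    or ``n`` subjects sampled (seeded) from rows not already carrying the
    label.
    """
    if label not in SUBGROUPS:
        raise ValueError(f"label: unknown subgroup {label!r}")
    cohort = cohort.copy()
    truth = truth.copy()
    if ids is None:
        if n is None:
            raise ValueError("provide either ids or n")
        pool = cohort.index[cohort["subgroup"] == "RASIG"]
        if len(pool) < n:
            raise ValueError(f"only {len(pool)} RASIG rows available, need {n}")
        rng = np.random.default_rng(seed)
        idx = pd.Index(rng.choice(pool.to_numpy(), size=n, replace=False))
    else:
        idx = cohort.index[cohort["id"].isin(ids)]
        if len(idx) != len(set(ids)):
            raise ValueError("ids: some subject ids not found")
    if (cohort.loc[idx, "subgroup"] == label).any():
        raise ValueError(f"label {label!r} already assigned to targeted rows")

    cohort.loc[idx, "subgroup"] = label
    for spec in config.panel_spec:
        cohort.loc[idx, spec.name] += spec.age_slope * shift_years
    for spec in config.external_spec:
        cohort.loc[idx, spec.name] += spec.ca_loading * shift_years

    tidx = truth.index[truth["id"].isin(cohort.loc[idx, "id"])]
    truth.loc[tidx, "shift"] += shift_years
    truth.loc[tidx, "latent_age"] += shift_years
    return cohort, truth


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """CSV with header; empty cell = missing value."""
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
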