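"""The bioage score: z-scaled multiple regression of age on markers.

Fitting: each selected marker x_i is z-scored against the training
population (z_i = (x_i - mean_i) / sd_i, sample SD with divisor n-1) and
chronological age A is regressed on the z-scores by ordinary least
squares, giving weights b_1..b_k, intercept c and the multiple R^2.

Scoring: the raw bioage is the fitted conditional expectation of age
given the markers,

    B~ = sum_i b_i * z_i + c .

Because OLS shrinks fitted values toward the mean (the slope of B~ on A
equals R^2), the raw score systematically under-disperses.  A strictly
monotone recalibration restores unit slope against chronological age,

    B = (B~ - mean_age) / r^2 + mean_age ,

where ``mean_age`` is the training-population mean age.  The age
difference AD = B - A is then mean-zero and uncorrelated with A on the
training set; a positive AD is age advancement, a negative AD age delay.

Scaling parameters and coefficients are frozen at training time and are
never refit when scoring external subjects.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ScalingParams",
    "BioAgeModel",
    "fit_scaler",
    "zscore",
    "fit_model",
    "raw_bioage",
    "corrected_bioage",
    "apply_model",
    "save_model",
    "load_model",
]

_FILE_VERSION = "bioage coefficient table v1"


@dataclass(frozen=True, eq=False)
class ScalingParams:
    """Per-marker training mean and sample SD (divisor n-1)."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("ScalingParams: mean/sd marker names differ")
        if (self.sd <= 0).any():
            bad = self.sd.index[self.sd <= 0].tolist()
            raise ValueError(f"ScalingParams: non-positive sd for {bad}")


@dataclass(frozen=True, eq=False)
class BioAgeModel:
    """Frozen scoring artifact."""

    sex: str
    markers: tuple[str, ...]
    scaling: ScalingParams
    weights: pd.Series          # years per z-unit, indexed by marker
    intercept_c: float          # years
    r2: float
    mean_age: float             # training mean age, years
    n_train: int
    weight_se: pd.Series | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if tuple(self.weights.index) != self.markers:
            raise ValueError("BioAgeModel: weights not aligned with markers")
        if tuple(self.scaling.mean.index) != self.markers:
            raise ValueError("BioAgeModel: scaling not aligned with markers")
        if not (0.0 < self.r2 <= 1.0):
            raise ValueError(f"BioAgeModel: r2={self.r2} outside (0, 1]")
        if self.n_train < len(self.markers) + 2:
            raise ValueError("BioAgeModel: n_train too small for the panel")


def fit_scaler(panel: pd.DataFrame) -> ScalingParams:
    """Column means and sample SDs of the training panel."""
    X = panel.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("fit_scaler: complete cases only (missing values found)")
    sd = panel.std(ddof=1)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"fit_scaler: constant columns {bad}")
    return ScalingParams(mean=panel.mean(), sd=sd)


def zscore(panel: pd.DataFrame, scaling: ScalingParams) -> pd.DataFrame:
    missing = [m for m in scaling.mean.index if m not in panel.columns]
    if missing:
        raise KeyError(f"zscore: panel lacks markers {missing}")
    cols = list(scaling.mean.index)
    return (panel[cols] - scaling.mean) / scaling.sd


def fit_model(
    panel: pd.DataFrame,
    age,
    sex: str = "F",
    scaling: ScalingParams | None = None,
) -> BioAgeModel:
    """OLS of age on the z-scaled marker panel."""
    age = np.asarray(age, dtype=float)
    if len(panel) != age.size:
        raise ValueError("fit_model: panel and age lengths differ")
    if len(panel) < panel.shape[1] + 2:
        raise ValueError("fit_model: need n > k + 1 training subjects")
    if scaling is None:
        scaling = fit_scaler(panel)
    Z = zscore(panel, scaling)
    X = sm.add_constant(Z.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fit_model: rank-deficient design (collinear markers)")
    res = sm.OLS(age, X).fit()
    markers = tuple(Z.columns)
    return BioAgeModel(
        sex=sex,
        markers=markers,
        scaling=scaling,
        weights=pd.Series(res.params[1:], index=list(markers)),
        intercept_c=float(res.params[0]),
        r2=float(res.rsquared),
        mean_age=float(age.mean()),
        n_train=int(age.size),
        weight_se=pd.Series(res.bse[1:], index=list(markers)),
    )


def raw_bioage(model: BioAgeModel, marker_values) -> float | pd.Series:
    """B~ = sum_i b_i (x_i - mean_i)/sd_i + c for one or many subjects."""
    if isinstance(marker_values, pd.DataFrame):
        Z = zscore(marker_values, model.scaling)
        return Z @ model.weights + model.intercept_c
    values = pd.Series(marker_values, dtype=float)
    missing = [m for m in model.markers
               if m not in values.index or not np.isfinite(values[m])]
    if missing:
        raise ValueError(f"raw_bioage: missing marker value(s) {missing}")
    z = (values[list(model.markers)] - model.scaling.mean) / model.scaling.sd
    return float(z @ model.weights + model.intercept_c)


def corrected_bioage(model: BioAgeModel, raw):
    """B = (B~ - mean_age)/r^2 + mean_age; strictly increasing in B~."""
    if model.r2 <= 0:
        raise ValueError("corrected_bioage: degenerate model (r2 = 0)")
    return (np.asarray(raw, dtype=float) - model.mean_age) / model.r2 + model.mean_age


def apply_model(model: BioAgeModel, cohort: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort: raw bioage, corrected bioage, age difference.

    Subjects with any missing model marker are flagged (``complete`` is
    False, scores NaN), never silently dropped -- incompleteness counts
    must remain reportable.
    """
    missing_cols = [m for m in model.markers if m not in cohort.columns]
    if missing_cols:
        raise KeyError(f"apply_model: cohort lacks markers {missing_cols}")
    panel = cohort[list(model.markers)].astype(float)
    complete = panel.notna().all(axis=1)
    raw = pd.Series(np.nan, index=cohort.index)
    raw[complete] = raw_bioage(model, panel.loc[complete])
    bio = pd.Series(np.nan, index=cohort.index)
    bio[complete] = corrected_bioage(model, raw[complete])
    out = cohort.drop(columns=list(model.markers)).copy()
    out["raw_bioage"] = raw
    out["bioage"] = bio
    out["age_diff"] = bio - cohort["age"].astype(float)
    out["complete"] = complete
    return out


def save_model(model: BioAgeModel, path: str | Path) -> None:
    """Coefficient table: '#' header block + one CSV row per marker."""
    buf = io.StringIO()
    buf.write(f"# {_FILE_VERSION}\n")
    buf.write(f"# sex,{model.sex}\n")
    buf.write(f"# intercept_c,{float(model.intercept_c)!r}\n")
    buf.write(f"# r2,{float(model.r2)!r}\n")
    buf.write(f"# mean_age,{float(model.mean_age)!r}\n")
    buf.write(f"# n_train,{model.n_train}\n")
    buf.write("name,mean,sd,weight\n")
    for m in model.markers:
        buf.write(f"{m},{float(model.scaling.mean[m])!r},"
                  f"{float(model.scaling.sd[m])!r},"
                  f"{float(model.weights[m])!r}\n")
    Path(path).write_text(buf.getvalue())


def load_model(path: str | Path) -> BioAgeModel:
    """Read a coefficient table; validates every model invariant."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            content = line[1:].strip()
            if "," in content:
                key, _, val = content.partition(",")
                header[key.strip()] = val.strip()
        else:
            body_start = i
            break
    table = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    required = {"name", "mean", "sd", "weight"}
    if not required.issubset(table.columns):
        raise ValueError(f"load_model: columns {sorted(required)} required")
    for key in ("sex", "intercept_c", "r2", "mean_age", "n_train"):
        if key not in header:
            raise ValueError(f"load_model: header field {key!r} missing")
    markers = tuple(table["name"].astype(str))
    scaling = ScalingParams(
        mean=pd.Series(table["mean"].to_numpy(dtype=float), index=list(markers)),
        sd=pd.Series(table["sd"].to_numpy(dtype=float), index=list(markers)),
    )
    return BioAgeModel(
        sex=header["sex"],
        markers=markers,
        scaling=scaling,
        weights=pd.Series(table["weight"].to_numpy(dtype=float), index=list(markers)),
        intercept_c=float(header["intercept_c"]),
        r2=float(header["r2"]),
        mean_age=float(header["mean_age"]),
        n_train=int(header["n_train"]),
    )
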