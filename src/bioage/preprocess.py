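"""Data-hygiene rules applied before model fitting.

Two outlier rules coexist: the IQR fence with k = 1.3 is univariate QC
reporting; the per-marker [0.01, 0.99] empirical-quantile rule is the one
that excludes subjects before fitting.  Quantiles use linear
interpolation over the sorted sample ("type-7", the numpy default).
Filter order is fixed -- complete-case first, then quantile exclusion --
and recorded in the report.  No imputation is ever performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterReport",
    "iqr_outlier_mask",
    "quantile_bounds",
    "quantile_exclusion_mask",
    "complete_case_filter",
    "training_filter",
    "normality_screen",
    "prepare_training",
]


@dataclass
class FilterReport:
    """Accounting of subject exclusions, serialisable as JSON."""

    n_input: int = 0
    n_excluded_subgroup: int = 0
    n_excluded_incomplete: int = 0
    n_excluded_outlier: int = 0
    n_output: int = 0
    excluded_subgroup: list = field(default_factory=list)
    excluded_incomplete: list = field(default_factory=list)
    excluded_outlier: list = field(default_factory=list)
    order: str = "subgroup -> complete_case -> quantile_exclusion"
    quantile_convention: str = "type-7 (linear interpolation)"

    def validate(self) -> None:
        total = (self.n_excluded_subgroup + self.n_excluded_incomplete
                 + self.n_excluded_outlier)
        if self.n_output != self.n_input - total:
            raise ValueError("FilterReport: counts do not sum consistently")

    def to_json(self, path: str | Path) -> None:
        self.validate()
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterReport":
        rep = cls(**json.loads(Path(path).read_text()))
        rep.validate()
        return rep


def iqr_outlier_mask(values, k: float = 1.3) -> np.ndarray:
    """Flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Missing values are never flagged.  Requires at least 4 non-missing
    values for the quartiles to be meaningful.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("iqr_outlier_mask: need >= 4 non-missing values")
    q1, q3 = np.quantile(v[finite], [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = np.zeros_like(v, dtype=bool)
    mask[finite] = (v[finite] < lo) | (v[finite] > hi)
    return mask


def quantile_bounds(panel: pd.DataFrame, lo: float = 0.01,
                    hi: float = 0.99) -> pd.DataFrame:
    """Per-column empirical [lo, hi] quantiles (frozen for reuse).

    Bounds are meant to be computed once on the training table and then
    applied unchanged to any table scored later.
    """
    if lo >= hi:
        raise ValueError("quantile bounds: lo must be < hi")
    rows = {}
    for col in panel.columns:
        v = panel[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 10:
            raise ValueError(f"quantile_bounds: column {col!r} has "
                             f"{v.size} non-missing values, need >= 10")
        rows[col] = np.quantile(v, [lo, hi])
    return pd.DataFrame(rows, index=["lo", "hi"]).T


def quantile_exclusion_mask(panel: pd.DataFrame, lo: float = 0.01,
                            hi: float = 0.99,
                            bounds: pd.DataFrame | None = None) -> pd.Series:
    """Flag subjects with any marker strictly outside its quantile interval.

    The interval is closed: a value equal to a bound is retained.
    Missing values never flag a subject.  Pass precomputed ``bounds`` to
    apply frozen training quantiles.
    """
    if bounds is None:
        bounds = quantile_bounds(panel, lo, hi)
    mask = pd.Series(False, index=panel.index)
    for col in panel.columns:
        b_lo, b_hi = bounds.loc[col, "lo"], bounds.loc[col, "hi"]
        v = panel[col]
        mask |= ((v < b_lo) | (v > b_hi)).fillna(False)
    return mask


def complete_case_filter(cohort: pd.DataFrame,
                         required_columns) -> tuple[pd.DataFrame, FilterReport]:
    """Retain rows with no missing value in ``required_columns``."""
    missing_cols = [c for c in required_columns if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"complete_case_filter: unknown columns {missing_cols}")
    ok = cohort[list(required_columns)].notna().all(axis=1)
    out = cohort.loc[ok]
    rep = FilterReport(
        n_input=len(cohort),
        n_excluded_incomplete=int((~ok).sum()),
        n_output=int(ok.sum()),
        excluded_incomplete=cohort.loc[~ok, "id"].tolist() if "id" in cohort else [],
        order="complete_case",
    )
    return out, rep


def training_filter(cohort: pd.DataFrame, sex: str) -> pd.DataFrame:
    """The learning population: RASIG of the given sex, hormone users
    removed for females (the exclusion is stated for women only)."""
    if sex not in ("F", "M"):
        raise ValueError(f"sex: expected 'F' or 'M', got {sex!r}")
    if "subgroup" not in cohort.columns:
        raise KeyError("training_filter: cohort lacks 'subgroup' column")
    sel = (cohort["subgroup"] == "RASIG") & (cohort["sex"] == sex)
    if sex == "F":
        if "hormone_use" not in cohort.columns:
            raise KeyError("training_filter: cohort lacks 'hormone_use' column")
        sel &= cohort["hormone_use"].fillna(0) != 1
    return cohort.loc[sel]


def normality_screen(values) -> dict:
    """Advisory normality diagnostics (never gates the pipeline).

    D'Agostino-Pearson omnibus test (requires n >= 20) and Shapiro-Wilk
    (n >= 3).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise ValueError("normality_screen: D'Agostino-Pearson requires n >= 20")
    if np.ptp(v) == 0:
        raise ValueError("normality_screen: constant input")
    dag = stats.normaltest(v)
    sha = stats.shapiro(v)
    return {
        "dagostino_stat": float(dag.statistic),
        "dagostino_p": float(dag.pvalue),
        "shapiro_stat": float(sha.statistic),
        "shapiro_p": float(sha.pvalue),
        "n": int(v.size),
    }


def prepare_training(
    cohort: pd.DataFrame,
    sex: str,
    markers,
    lo: float = 0.01,
    hi: float = 0.99,
) -> tuple[pd.DataFrame, FilterReport, pd.DataFrame]:
    """Full training-set hygiene in the fixed order.

    Subgroup/HRT restriction, then complete-case on the marker panel,
    then per-marker [lo, hi] quantile exclusion with bounds computed on
    the complete-case training table (returned frozen for reuse).
    Returns ``(training_table, report, bounds)``.
    """
    markers = list(markers)
    train = training_filter(cohort, sex)
    n_subgroup_excl = len(cohort) - len(train)
    complete, rep_cc = complete_case_filter(train, markers)
    bounds = quantile_bounds(complete[markers], lo, hi)
    out_mask = quantile_exclusion_mask(complete[markers], bounds=bounds)
    out = complete.loc[~out_mask]
    rep = FilterReport(
        n_input=len(cohort),
        n_excluded_subgroup=n_subgroup_excl,
        n_excluded_incomplete=rep_cc.n_excluded_incomplete,
        n_excluded_outlier=int(out_mask.sum()),
        n_output=len(out),
        excluded_subgroup=cohort.loc[~cohort["id"].isin(train["id"]), "id"].tolist(),
        excluded_incomplete=rep_cc.excluded_incomplete,
        excluded_outlier=complete.loc[out_mask, "id"].tolist(),
    )
    rep.validate()
    return out, rep, bounds
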