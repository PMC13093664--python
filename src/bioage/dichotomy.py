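"""Driver-versus-bystander screen of external markers.

For every external clinical-chemistry marker, two independent simple
regressions are fitted per sex: marker on chronological age (CA) and
marker on age difference (AD).  A marker significantly associated with
AD but not CA is a candidate *driver* of the ageing pace; one associated
with CA but not AD a *bystander*; the remaining patterns are "both" and
"neither".  Classification is a pure function of the two zero-slope
p-values against a fixed two-sided alpha (0.05 by default, raw p-values,
no multiplicity correction).

Insulin resistance is summarised by the homeostasis-model assessment
index (Matthews formula), and severely hyperglycaemic subjects
(glucose strictly above 250 mg/dL) are excluded before the screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "homa_index",
    "glucose_exclusion",
    "dual_regression",
    "classify_marker",
    "screen_all",
]

CLASSES = ("CA", "AD", "both", "neither")


@dataclass(frozen=True)
class AssociationResult:
    marker: str
    sex: str
    slope_ca: float
    p_ca: float
    slope_ad: float
    p_ad: float
    n: int
    klass: str | None = None


def homa_index(glucose, insulin):
    """HOMA-IR = glucose [mg/dL] * insulin [uU/mL] / 405 (Matthews)."""
    g = np.asarray(glucose, dtype=float)
    i = np.asarray(insulin, dtype=float)
    if np.any(g[np.isfinite(g)] <= 0):
        raise ValueError("homa_index: glucose must be positive")
    if np.any(i[np.isfinite(i)] < 0):
        raise ValueError("homa_index: insulin must be non-negative")
    out = g * i / 405.0
    return float(out) if out.ndim == 0 else out


def glucose_exclusion(cohort: pd.DataFrame, threshold: float = 250.0,
                      column: str = "glucose") -> tuple[pd.DataFrame, list]:
    """Drop subjects with glucose strictly above ``threshold`` mg/dL.

    A value exactly at the threshold is retained.  Returns the filtered
    cohort and the excluded subject ids.
    """
    if column not in cohort.columns:
        raise KeyError(f"glucose_exclusion: column {column!r} not present")
    high = cohort[column] > threshold
    excluded = cohort.loc[high, "id"].tolist() if "id" in cohort else \
        cohort.index[high].tolist()
    return cohort.loc[~high.fillna(False)], excluded


def dual_regression(marker, ca, ad, name: str = "marker",
                    sex: str = "") -> AssociationResult:
    """Two simple OLS fits of the marker: on CA and, separately, on AD."""
    m = np.asarray(marker, dtype=float)
    a = np.asarray(ca, dtype=float)
    d = np.asarray(ad, dtype=float)
    ok = np.isfinite(m) & np.isfinite(a) & np.isfinite(d)
    m, a, d = m[ok], a[ok], d[ok]
    if m.size < 3:
        raise ValueError(f"dual_regression: need >= 3 complete triples for {name!r}")
    if np.ptp(a) == 0 or np.ptp(d) == 0:
        raise ValueError(f"dual_regression: constant regressor for {name!r}")
    fit_ca = stats.linregress(a, m)
    fit_ad = stats.linregress(d, m)
    return AssociationResult(
        marker=name, sex=sex,
        slope_ca=float(fit_ca.slope), p_ca=float(fit_ca.pvalue),
        slope_ad=float(fit_ad.slope), p_ad=float(fit_ad.pvalue),
        n=int(m.size),
    )


def classify_marker(result: AssociationResult | None = None,
                    alpha: float = 0.05, *,
                    p_ca: float | None = None,
                    p_ad: float | None = None):
    """AD / CA / both / neither from the two p-values at level alpha.

    Accepts either an AssociationResult (returns a copy with ``klass``
    set) or the bare p-values (returns the class label).
    """
    if result is not None:
        p_ca, p_ad = result.p_ca, result.p_ad
    if p_ca is None or p_ad is None or not (np.isfinite(p_ca) and np.isfinite(p_ad)):
        raise ValueError("classify_marker: both p-values required")
    sig_ca, sig_ad = p_ca < alpha, p_ad < alpha
    if sig_ad and not sig_ca:
        klass = "AD"
    elif sig_ca and not sig_ad:
        klass = "CA"
    elif sig_ca and sig_ad:
        klass = "both"
    else:
        klass = "neither"
    return replace(result, klass=klass) if result is not None else klass


def screen_all(
    cohort: pd.DataFrame,
    scored: pd.DataFrame,
    markers,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dichotomy report over all external markers, per sex.

    One row per (marker, sex) with both slopes, p-values, the class and
    boldface flags mirroring a published summary table: the larger
    absolute slope of the CA/AD pair and every significant p-value are
    flagged.  Markers absent from the cohort are skipped with a warning.
    """
    merged = scored[["id", "sex", "age", "age_diff"]].merge(
        cohort[["id"] + [m for m in markers if m in cohort.columns]],
        on="id", how="inner")
    rows = []
    for sex in ("F", "M"):
        sub = merged[merged["sex"] == sex]
        if sub.empty:
            continue
        for m in markers:
            if m not in merged.columns:
                warnings.warn(f"screen_all: marker {m!r} not in cohort, skipped")
                continue
            res = classify_marker(
                dual_regression(sub[m], sub["age"], sub["age_diff"],
                                name=m, sex=sex),
                alpha=alpha)
            row = asdict(res)
            row["bold_ca_slope"] = abs(res.slope_ca) > abs(res.slope_ad)
            row["bold_ad_slope"] = abs(res.slope_ad) > abs(res.slope_ca)
            row["bold_p_ca"] = res.p_ca < alpha
            row["bold_p_ad"] = res.p_ad < alpha
            rows.append(row)
    return pd.DataFrame(rows)
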