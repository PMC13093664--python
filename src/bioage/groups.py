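"""Age-difference contrasts between subgroups.

Effect sizes are Hodges-Lehmann shift estimates: the median of all
pairwise differences x_i - y_j (two-sample) or of the Walsh averages
(x_i + x_j)/2, i <= j (one-sample).  Confidence intervals use the
distribution-free order-statistic construction: the interval endpoints
are the difference-set (or Walsh-set) order statistics at the critical
ranks of the exact Mann-Whitney (resp. Wilcoxon signed-rank) null
distribution, with a normal approximation for large samples.  Every
contrast also reports an unpaired two-sided t-test (pooled variance) and
a Mann-Whitney test; no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastResult",
    "DoseResponseResult",
    "hl_shift_two_sample",
    "hl_one_sample",
    "subgroup_contrast",
    "hormone_split_contrast",
    "dose_response",
]

_EXACT_MAX = 50  # exact null distribution when min sample size <= this


@lru_cache(maxsize=128)
def _mannwhitney_cdf(n: int, m: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the null (no ties).

    Counts are the coefficients of the Gaussian binomial [n+m choose n]_q,
    built by iterated polynomial multiplication/division in float64 (the
    counts reach ~1e40 but the cdf only needs relative accuracy).
    """
    N = n * m
    c = np.zeros(N + 1)
    c[0] = 1.0
    for i in range(1, n + 1):
        k = m + i
        if k <= N:
            c[k:] = c[k:] - c[:-k]          # multiply by (1 - q^(m+i))
        for r in range(min(i, N + 1)):       # divide by (1 - q^i)
            c[r::i] = np.cumsum(c[r::i])
    total = c.sum()
    return np.cumsum(c) / total


@lru_cache(maxsize=128)
def _signedrank_cdf(n: int) -> np.ndarray:
    """CDF of the Wilcoxon signed-rank statistic under the null."""
    M = n * (n + 1) // 2
    c = np.zeros(M + 1)
    c[0] = 1.0
    for i in range(1, n + 1):
        c[i:] = c[i:] + c[:-i]              # multiply by (1 + q^i)
    return np.cumsum(c) / c.sum()


def _critical_rank(cdf: np.ndarray, alpha: float) -> int:
    """Smallest statistic value u with P(U <= u) >= alpha/2, floored at 1."""
    qu = int(np.searchsorted(cdf, alpha / 2.0, side="left"))
    return max(qu, 1)


def hl_shift_two_sample(x, y, level: float = 0.95) -> dict:
    """Hodges-Lehmann shift of x relative to y, with Moses CI.

    Estimate: median of all n*m pairwise differences x_i - y_j.  CI
    endpoints are order statistics of the sorted difference set at the
    Mann-Whitney critical ranks (exact null distribution when
    min(n, m) <= 50, normal approximation otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n, m = x.size, y.size
    if n < 2 or m < 2:
        raise ValueError("hl_shift_two_sample: need >= 2 values per sample")
    if not 0 < level < 1:
        raise ValueError("hl_shift_two_sample: level must be in (0, 1)")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    est = float(np.median(diffs))
    alpha = 1.0 - level
    N = n * m
    if min(n, m) <= _EXACT_MAX:
        qu = _critical_rank(_mannwhitney_cdf(n, m), alpha)
        exact = True
    else:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        qu = int(N / 2.0 - z * np.sqrt(N * (n + m + 1) / 12.0))
        qu = max(qu, 1)
        exact = False
    lo = float(diffs[qu - 1])       # 1-based rank qu
    hi = float(diffs[N - qu])       # 1-based rank N + 1 - qu
    return {"estimate": est, "ci_low": lo, "ci_high": hi,
            "level": level, "exact": exact, "n": n, "m": m}


def hl_one_sample(x, level: float = 0.95) -> dict:
    """Hodges-Lehmann location (pseudo-median) with signed-rank CI."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("hl_one_sample: need >= 2 values")
    if not 0 < level < 1:
        raise ValueError("hl_one_sample: level must be in (0, 1)")
    i, j = np.triu_indices(n)
    walsh = np.sort((x[i] + x[j]) / 2.0)
    est = float(np.median(walsh))
    M = n * (n + 1) // 2
    alpha = 1.0 - level
    if n <= _EXACT_MAX:
        qu = _critical_rank(_signedrank_cdf(n), alpha)
        exact = True
    else:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        qu = int(M / 2.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0))
        qu = max(qu, 1)
        exact = False
    lo = float(walsh[qu - 1])
    hi = float(walsh[M - qu])
    return {"estimate": est, "ci_low": lo, "ci_high": hi,
            "level": level, "exact": exact, "n": n}


@dataclass(frozen=True)
class ContrastResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    hl_estimate: float
    hl_ci_low: float
    hl_ci_high: float
    level: float
    t_p: float
    mw_p: float
    test_used: str = "HL shift; unpaired t (pooled); Mann-Whitney"

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DoseResponseResult:
    slope: float      # AD-years per pack
    intercept: float
    r2: float
    p: float
    n: int


def _age_overlap(ages_a, ages_b):
    lo = max(np.min(ages_a), np.min(ages_b))
    hi = min(np.max(ages_a), np.max(ages_b))
    return lo, hi


def subgroup_contrast(
    scored: pd.DataFrame,
    group_a,
    group_b,
    age_match: bool = True,
    level: float = 0.95,
    label_a: str = "A",
    label_b: str = "B",
) -> ContrastResult:
    """Contrast the age difference of two subject groups.

    ``group_a``/``group_b`` are boolean masks over ``scored``.  With
    ``age_match`` both groups are first restricted to their common
    observed age range, the analogue of excluding out-of-range subjects
    before a progeroid-group comparison.  Incompletely scored subjects
    are ignored.
    """
    ok = scored["age_diff"].notna()
    a = scored.loc[np.asarray(group_a) & ok]
    b = scored.loc[np.asarray(group_b) & ok]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"subgroup_contrast: empty group (n_a={len(a)}, n_b={len(b)})")
    if age_match:
        lo, hi = _age_overlap(a["age"], b["age"])
        a = a[(a["age"] >= lo) & (a["age"] <= hi)]
        b = b[(b["age"] >= lo) & (b["age"] <= hi)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                "subgroup_contrast: group too small after age matching "
                f"(n_a={len(a)}, n_b={len(b)}, window=[{lo:.1f}, {hi:.1f}])")
    ad_a = a["age_diff"].to_numpy(dtype=float)
    ad_b = b["age_diff"].to_numpy(dtype=float)
    hl = hl_shift_two_sample(ad_a, ad_b, level=level)
    if np.ptp(np.concatenate([ad_a, ad_b])) == 0:
        t_p, mw_p = np.nan, np.nan  # undefined variance, documented
    else:
        t_p = float(stats.ttest_ind(ad_a, ad_b, equal_var=True).pvalue)
        mw_p = float(stats.mannwhitneyu(ad_a, ad_b,
                                        alternative="two-sided").pvalue)
    return ContrastResult(
        label_a=label_a, label_b=label_b, n_a=len(ad_a), n_b=len(ad_b),
        hl_estimate=hl["estimate"], hl_ci_low=hl["ci_low"],
        hl_ci_high=hl["ci_high"], level=level, t_p=t_p, mw_p=mw_p,
    )


def hormone_split_contrast(
    scored: pd.DataFrame,
    age_cut: float = 50.0,
    level: float = 0.95,
) -> dict:
    """Hormone users vs non-users, separately below and above ``age_cut``.

    Operates on scored females; an empty stratum yields ``None`` for that
    contrast together with a warning entry, never a hard failure.
    """
    fem = scored[(scored["sex"] == "F") & scored["age_diff"].notna()]
    if "hormone_use" not in fem.columns:
        raise KeyError("hormone_split_contrast: 'hormone_use' column required")
    out: dict = {"below": None, "above": None, "warnings": []}
    for key, stratum in (("below", fem[fem["age"] < age_cut]),
                         ("above", fem[fem["age"] >= age_cut])):
        users = stratum["hormone_use"] == 1
        if users.sum() < 2 or (~users).sum() < 2:
            out["warnings"].append(
                f"{key} age {age_cut:g}: stratum too small "
                f"(users={int(users.sum())}, non-users={int((~users).sum())})")
            continue
        out[key] = subgroup_contrast(
            stratum, users, ~users, age_match=False, level=level,
            label_a=f"hormone users {key} {age_cut:g}",
            label_b=f"non-users {key} {age_cut:g}")
    return out


def dose_response(age_diff, exposure) -> DoseResponseResult:
    """OLS of age difference on cumulative exposure (packs)."""
    ad = np.asarray(age_diff, dtype=float)
    ex = np.asarray(exposure, dtype=float)
    ok = np.isfinite(ad) & np.isfinite(ex)
    ad, ex = ad[ok], ex[ok]
    if ad.size < 3:
        raise ValueError("dose_response: need >= 3 complete pairs")
    if np.ptp(ex) == 0:
        raise ValueError("dose_response: constant exposure")
    fit = stats.linregress(ex, ad)
    return DoseResponseResult(slope=float(fit.slope),
                              intercept=float(fit.intercept),
                              r2=float(fit.rvalue ** 2),
                              p=float(fit.pvalue), n=int(ad.size))
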