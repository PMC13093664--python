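"""Per-marker association with chronological age and preselection.

Each candidate marker is summarised by its Pearson correlation (rp),
Spearman rank correlation (rnp, mid-ranks for ties), and the
least-squares line of the marker on age (slope a, intercept c).
Screening is always run on a sex-filtered table; the preselection ranks
by |rnp| (configurable to |rp|) and keeps the top k candidates for the
subset search.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MarkerStats", "marker_age_stats", "preselect_top_k", "screen_panel"]


@dataclass(frozen=True)
class MarkerStats:
    name: str
    n: int
    rp: float
    rnp: float
    slope_a: float
    intercept_c: float


def marker_age_stats(marker, age, name: str = "marker") -> MarkerStats:
    """Correlations and regression line of one marker against age.

    Pairwise-complete: rows where either value is missing are dropped.
    """
    m = np.asarray(marker, dtype=float)
    a = np.asarray(age, dtype=float)
    if m.shape != a.shape:
        raise ValueError("marker_age_stats: length mismatch")
    ok = np.isfinite(m) & np.isfinite(a)
    m, a = m[ok], a[ok]
    if m.size < 3:
        raise ValueError(f"marker_age_stats: need >= 3 complete pairs for {name!r}")
    if np.ptp(m) == 0 or np.ptp(a) == 0:
        raise ValueError(f"marker_age_stats: constant input for {name!r}, "
                         "correlation undefined")
    rp = stats.pearsonr(m, a).statistic
    rnp = stats.spearmanr(m, a).statistic
    fit = stats.linregress(a, m)  # marker as response
    return MarkerStats(name=name, n=int(m.size), rp=float(rp), rnp=float(rnp),
                       slope_a=float(fit.slope), intercept_c=float(fit.intercept))


def preselect_top_k(stats_list, k: int = 30, by: str = "rnp") -> list[str]:
    """Top-k marker names by absolute age correlation, descending.

    Ties broken by larger n, then lexical name, for determinism.
    """
    if by not in ("rnp", "rp"):
        raise ValueError(f"preselect_top_k: by must be 'rnp' or 'rp', got {by!r}")
    stats_list = list(stats_list)
    if k > len(stats_list):
        raise ValueError(f"preselect_top_k: k={k} exceeds {len(stats_list)} markers")
    ranked = sorted(stats_list,
                    key=lambda s: (-abs(getattr(s, by)), -s.n, s.name))
    return [s.name for s in ranked[:k]]


def screen_panel(cohort: pd.DataFrame, markers, age_col: str = "age") -> pd.DataFrame:
    """Screen every marker column against age; one row per marker.

    The output mirrors a published panel-overview table: name, count and
    both correlation coefficients plus the per-marker regression line.
    """
    rows = [asdict(marker_age_stats(cohort[m], cohort[age_col], name=m))
            for m in markers]
    return pd.DataFrame(rows)
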