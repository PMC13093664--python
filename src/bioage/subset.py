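"""Best-subset regression: which k markers jointly model age best.

The criterion is the maximum coefficient of determination (R^2) of the
ordinary least-squares fit of age on the selected markers, at a fixed
subset size -- no penalised criteria.  The branch-and-bound search uses
the Furnival-Wilson bound (the R^2 attainable by any subset is at most
the R^2 of its superset) and is guaranteed to return the global optimum;
exhaustive enumeration is available as an oracle and a greedy forward
pass as a documented heuristic for large candidate sets.  Ties in R^2
are broken toward the lexically smallest subset of marker names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SubsetResult", "best_subset"]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SubsetResult:
    selected: tuple[str, ...]
    r2: float
    method: str
    nodes_visited: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


class _Workspace:
    """Centered, standardised cross-products for fast subset R^2."""

    def __init__(self, panel: pd.DataFrame, age: np.ndarray):
        self.names = list(panel.columns)
        X = panel.to_numpy(dtype=float)
        y = np.asarray(age, dtype=float)
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise ValueError("best_subset: complete cases only (missing values found)")
        X = X - X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [n for n, s in zip(self.names, sd) if s == 0]
            raise ValueError(f"best_subset: constant columns {bad}")
        X = X / sd
        y = y - y.mean()
        self.S = X.T @ X
        self.c = X.T @ y
        self.tss = float(y @ y)
        if self.tss == 0:
            raise ValueError("best_subset: age is constant")
        self.evals = 0

    def r2(self, idx: tuple[int, ...]) -> float:
        ii = np.asarray(idx)
        S = self.S[np.ix_(ii, ii)]
        c = self.c[ii]
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            L = None
        # near-zero pivots betray collinearity even when the
        # factorisation numerically "succeeds"
        if L is None or np.any(np.diag(L) ** 2 < 1e-10 * np.diag(S)):
            bad = [self.names[i] for i in idx]
            raise np.linalg.LinAlgError(
                f"best_subset: collinear columns among {bad}") from None
        z = np.linalg.solve(L, c)
        return float(z @ z) / self.tss


def _names_of(ws: _Workspace, idx) -> tuple[str, ...]:
    return tuple(sorted(ws.names[i] for i in idx))


def _exhaustive(ws: _Workspace, size: int) -> tuple[tuple[int, ...], float, int]:
    best_idx, best_r2, best_names = None, -np.inf, None
    n_leaf = 0
    order = np.argsort(np.array(ws.names))  # lexical iteration => ties resolve small
    for idx in combinations(order.tolist(), size):
        r2 = ws.r2(idx)
        n_leaf += 1
        names = _names_of(ws, idx)
        if r2 > best_r2 + _TIE_TOL or (r2 > best_r2 - _TIE_TOL
                                       and best_names is not None
                                       and names < best_names):
            best_idx, best_r2, best_names = idx, max(r2, best_r2), names
    return best_idx, best_r2, n_leaf


def _forward(ws: _Workspace, size: int) -> tuple[tuple[int, ...], float, int]:
    chosen: list[int] = []
    n_eval = 0
    p = len(ws.names)
    for _ in range(size):
        best_j, best_r2, best_name = None, -np.inf, None
        for j in range(p):
            if j in chosen:
                continue
            r2 = ws.r2(tuple(chosen) + (j,))
            n_eval += 1
            name = ws.names[j]
            if r2 > best_r2 + _TIE_TOL or (r2 > best_r2 - _TIE_TOL
                                           and best_name is not None
                                           and name < best_name):
                best_j, best_r2, best_name = j, max(r2, best_r2), name
        chosen.append(best_j)
    return tuple(chosen), ws.r2(tuple(chosen)), n_eval


def _branch_and_bound(ws: _Workspace, size: int) -> tuple[tuple[int, ...], float, int]:
    # Search order: strongest marginal correlation first, so good
    # solutions are found early and the bound prunes aggressively.
    marginal = np.abs(ws.c) / np.sqrt(np.diag(ws.S))
    order = sorted(range(len(ws.names)), key=lambda j: (-marginal[j], ws.names[j]))

    # warm start from the greedy forward path
    fwd_idx, fwd_r2, _ = _forward(ws, size)
    state = {
        "best_r2": fwd_r2,
        "best_idx": fwd_idx,
        "best_names": _names_of(ws, fwd_idx),
        "leaves": 0,
    }

    def consider(idx: tuple[int, ...]) -> None:
        r2 = ws.r2(idx)
        state["leaves"] += 1
        names = _names_of(ws, idx)
        if (r2 > state["best_r2"] + _TIE_TOL
                or (r2 > state["best_r2"] - _TIE_TOL and names < state["best_names"])):
            state["best_r2"] = max(r2, state["best_r2"])
            state["best_idx"] = idx
            state["best_names"] = names

    def dfs(included: tuple[int, ...], start: int) -> None:
        if len(included) == size:
            consider(included)
            return
        rem = order[start:]
        if len(included) + len(rem) < size:
            return
        if len(included) + len(rem) == size:
            consider(included + tuple(rem))
            return
        # Furnival-Wilson bound: no subset below this node can beat the
        # R^2 of (included + all remaining candidates).
        bound = ws.r2(included + tuple(rem))
        if bound < state["best_r2"] - _TIE_TOL:
            return
        dfs(included + (order[start],), start + 1)
        dfs(included, start + 1)

    dfs((), 0)
    return state["best_idx"], state["best_r2"], state["leaves"]


def best_subset(
    panel: pd.DataFrame,
    age,
    size: int = 10,
    method: str = "auto",
    *,
    bnb_threshold: int = 40,
    exhaustive_limit: int = 20000,
) -> SubsetResult:
    """Select the ``size`` markers maximising the OLS R^2 against age.

    ``method`` is one of ``auto``, ``branch_and_bound``, ``exhaustive``
    or ``forward``.  ``auto`` enumerates exhaustively when the number of
    subsets is small, uses branch-and-bound up to ``bnb_threshold``
    candidates, and falls back to greedy forward selection beyond that
    (heuristic; no optimality guarantee).  ``nodes_visited`` counts
    full-size subsets evaluated and never exceeds the exhaustive count.
    """
    ws = _Workspace(panel, np.asarray(age, dtype=float))
    p = len(ws.names)
    if size < 1 or size > p:
        raise ValueError(f"best_subset: size={size} out of range for p={p}")

    if method == "auto":
        if comb(p, size) <= exhaustive_limit:
            method = "exhaustive"
        elif p <= bnb_threshold:
            method = "branch_and_bound"
        else:
            method = "forward"

    if method == "exhaustive":
        idx, r2, nodes = _exhaustive(ws, size)
    elif method == "branch_and_bound":
        idx, r2, nodes = _branch_and_bound(ws, size)
    elif method == "forward":
        idx, r2, nodes = _forward(ws, size)
    else:
        raise ValueError(f"best_subset: unknown method {method!r}")
    return SubsetResult(selected=_names_of(ws, idx), r2=r2, method=method,
                        nodes_visited=nodes)
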