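"""Interval-wise variable selection on the winning histogram: iPLS and
iSPA-PLS.

After the GA has fixed the best subimage subset, its concatenated histogram
can still carry color levels unrelated to the response.  The feature axis
is cut into contiguous equal-width intervals; iPLS fits one PLS-LOOCV model
per interval and ranks them by RMSECV against the full-histogram baseline,
while iSPA-PLS uses the successive projections algorithm on per-interval
representative vectors to propose minimally collinear interval
combinations, scores every candidate combination by PLS-LOOCV, and returns
the global best.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError
from .pls import loocv_curve, pick_lv

__all__ = [
    "IntervalPartition",
    "IntervalModelTable",
    "ISPAResult",
    "make_intervals",
    "ipls",
    "ispa_pls",
]


@dataclass(frozen=True)
class IntervalPartition:
    """Contiguous, covering, half-open intervals over the feature axis."""

    boundaries: tuple[int, ...]  # n_intervals + 1 offsets, 0 .. J_feat

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    @property
    def n_features(self) -> int:
        return self.boundaries[-1]

    def interval_slice(self, k: int) -> slice:
        """Half-open column slice of 0-based interval k."""
        if not (0 <= k < self.n_intervals):
            raise DomainError(f"interval {k} outside [0, {self.n_intervals})")
        return slice(self.boundaries[k], self.boundaries[k + 1])

    def columns(self, ks: Sequence[int]) -> np.ndarray:
        """Sorted unique column indices of a set of intervals."""
        idx = []
        for k in sorted(set(int(k) for k in ks)):
            s = self.interval_slice(k)
            idx.extend(range(s.start, s.stop))
        return np.asarray(idx, dtype=int)


def make_intervals(n_features: int, n_intervals: int) -> IntervalPartition:
    """Equidistant partition via floor boundaries; sizes differ by <= 1."""
    if not (1 <= n_intervals <= n_features):
        raise DomainError(
            f"n_intervals = {n_intervals} outside [1, J_feat = {n_features}]"
        )
    bounds = tuple(i * n_features // n_intervals for i in range(n_intervals + 1))
    return IntervalPartition(boundaries=bounds)


def _score_columns(
    X: np.ndarray, y: np.ndarray, cols: np.ndarray, lv_max: int, lv_tol: float
) -> tuple[float, int]:
    """(RMSECV, n_lv) of a PLS-LOOCV model on a column subset; inf when the
    subset is degenerate."""
    Xs = X[:, cols]
    keep = np.ptp(Xs, axis=0) > 0
    Xs = Xs[:, keep]
    if Xs.shape[1] == 0:
        return float("inf"), 0
    lv_hi = min(lv_max, X.shape[0] - 2, Xs.shape[1])
    try:
        curve, _ = loocv_curve(Xs, y, lv_hi)
    except DegenerateInputError:
        return float("inf"), 0
    n_lv = pick_lv(curve, tol=lv_tol)
    return float(curve[n_lv - 1]), n_lv


@dataclass(frozen=True)
class IntervalModelTable:
    """Per-interval PLS-LOOCV results plus the full-histogram baseline."""

    table: pd.DataFrame  # columns: interval, start, stop, rmsecv, n_lv, usable, rank
    baseline_rmsecv: float
    baseline_n_lv: int

    @property
    def best_interval(self) -> int:
        """0-based index of the usable interval with minimal RMSECV."""
        usable = self.table[self.table["usable"]]
        if usable.empty:
            raise DegenerateInputError("no usable interval")
        return int(usable.sort_values(["rmsecv", "interval"]).iloc[0]["interval"])


def ipls(
    X: np.ndarray,
    y: np.ndarray,
    partition: IntervalPartition,
    lv_max: int = 5,
    lv_tol: float = 0.0,
) -> IntervalModelTable:
    """One PLS-LOOCV model per interval, ranked by RMSECV.

    Degenerate intervals (zero variance in every column) are recorded as
    unusable rather than failing the whole table.  The full-histogram model
    is included as the baseline every interval competes against.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if partition.n_features != X.shape[1]:
        raise DomainError(
            f"partition covers {partition.n_features} features, X has {X.shape[1]}"
        )
    rows = []
    for k in range(partition.n_intervals):
        s = partition.interval_slice(k)
        rmsecv, n_lv = _score_columns(X, y, np.arange(s.start, s.stop), lv_max, lv_tol)
        rows.append(
            {
                "interval": k,
                "start": s.start,
                "stop": s.stop,
                "rmsecv": rmsecv,
                "n_lv": n_lv,
                "usable": np.isfinite(rmsecv),
            }
        )
    table = pd.DataFrame(rows)
    table["rank"] = table["rmsecv"].rank(method="first").astype(int)
    base_rmsecv, base_lv = _score_columns(
        X, y, np.arange(X.shape[1]), lv_max, lv_tol
    )
    return IntervalModelTable(
        table=table, baseline_rmsecv=base_rmsecv, baseline_n_lv=base_lv
    )


@dataclass(frozen=True)
class ISPAResult:
    """Best interval combination found by iSPA-PLS."""

    intervals: tuple[int, ...]  # 0-based, sorted
    rmsecv: float
    n_lv: int
    candidates: pd.DataFrame  # all scored combinations


def _spa_chain(R: np.ndarray, start: int, max_len: int) -> list[int]:
    """Successive projections chain of interval representatives.

    R is (I, n_intervals); starting from ``start`` each step picks the
    representative with the largest norm after projection onto the
    orthogonal complement of the span of the chain so far.  The chain
    truncates if every remaining projected representative is numerically
    zero (rank deficiency).
    """
    n = R.shape[1]
    chain = [start]
    P = R.copy()
    v = P[:, start].copy()
    for _ in range(max_len - 1):
        nv = np.linalg.norm(v)
        if nv <= 1e-12:
            break
        v = v / nv
        P = P - np.outer(v, v @ P)
        norms = np.linalg.norm(P, axis=0)
        norms[chain] = -1.0
        pick = int(np.argmax(norms))
        if norms[pick] <= 1e-12:
            break
        chain.append(pick)
        v = P[:, pick].copy()
    return chain


def ispa_pls(
    X: np.ndarray,
    y: np.ndarray,
    partition: IntervalPartition,
    max_intervals: int,
    lv_max: int = 5,
    lv_tol: float = 0.0,
) -> ISPAResult:
    """Successive-projections interval selection scored by PLS-LOOCV.

    Each interval is represented by its column-mean vector over samples
    (an I-vector).  From every starting interval a projection chain of up
    to ``max_intervals`` representatives is built; every chain prefix is a
    candidate combination, scored on its pooled columns.  The global
    minimum-RMSECV combination wins; ties break toward fewer intervals,
    then lexicographically.  Deterministic for fixed inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if partition.n_features != X.shape[1]:
        raise DomainError(
            f"partition covers {partition.n_features} features, X has {X.shape[1]}"
        )
    if not (1 <= max_intervals <= partition.n_intervals):
        raise DomainError(
            f"max_intervals = {max_intervals} outside [1, {partition.n_intervals}]"
        )
    # representatives: column-mean profile of each interval, mean-centred
    # across samples so the projections see shape, not offset
    R = np.column_stack(
        [
            X[:, partition.interval_slice(k)].mean(axis=1)
            for k in range(partition.n_intervals)
        ]
    )
    R = R - R.mean(axis=0, keepdims=True)
    candidates: set[tuple[int, ...]] = set()
    for start in range(partition.n_intervals):
        chain = _spa_chain(R, start, max_intervals)
        for plen in range(1, len(chain) + 1):
            candidates.add(tuple(sorted(chain[:plen])))
    rows = []
    for combo in sorted(candidates, key=lambda c: (len(c), c)):
        rmsecv, n_lv = _score_columns(X, y, partition.columns(combo), lv_max, lv_tol)
        rows.append(
            {
                "intervals": combo,
                "n_intervals": len(combo),
                "rmsecv": rmsecv,
                "n_lv": n_lv,
            }
        )
    cand_df = pd.DataFrame(rows)
    finite = cand_df[np.isfinite(cand_df["rmsecv"])]
    if finite.empty:
        raise DegenerateInputError("no scorable interval combination")
    best = finite.sort_values(
        ["rmsecv", "n_intervals", "intervals"], kind="stable"
    ).iloc[0]
    return ISPAResult(
        intervals=tuple(best["intervals"]),
        rmsecv=float(best["rmsecv"]),
        n_lv=int(best["n_lv"]),
        candidates=cand_df,
    )
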