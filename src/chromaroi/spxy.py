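"""SPXY calibration/prediction splitting.

SPXY is Kennard-Stone sample selection on a joint distance that weighs the
predictor space and the response space equally:

    d(i, j) = dx(i, j) / max dx  +  dy(i, j) / max dy

with dx, dy Euclidean distances in X and y.  The first two calibration
samples are the maximum-joint-distance pair; each further sample maximises
its minimum joint distance to the already-chosen set.  Extremes of both
spaces land in calibration, so the prediction set is interpolative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import DegenerateInputError, DomainError

__all__ = ["SplitResult", "joint_distance_matrix", "spxy"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction index sets covering all samples.

    Indices are 0-based row positions; ``calibration`` preserves SPXY
    selection order, ``prediction`` is ascending.
    """

    calibration: tuple[int, ...]
    prediction: tuple[int, ...]

    @property
    def n_cal(self) -> int:
        return len(self.calibration)

    @property
    def n_pred(self) -> int:
        return len(self.prediction)


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Symmetric I x I joint X-y distance matrix with zero diagonal."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise DomainError("X rows and y length differ")
    if X.shape[0] < 2:
        raise DomainError("need at least 2 samples")
    dx = squareform(pdist(X, metric="euclidean"))
    dy = squareform(pdist(y[:, None], metric="euclidean"))
    if dx.max() <= 0.0:
        raise DegenerateInputError("all samples identical in X")
    if dy.max() <= 0.0:
        raise DegenerateInputError("all samples identical in y")
    return dx / dx.max() + dy / dy.max()


def spxy(X: np.ndarray, y: np.ndarray, n_cal: int) -> SplitResult:
    """Select ``n_cal`` calibration samples by SPXY; the rest predict.

    Deterministic: the seed pair is the (lowest-index) maximum-distance
    pair, and ties in the max-min step break toward the lowest sample
    index.
    """
    d = joint_distance_matrix(X, y)
    I = d.shape[0]
    if not (2 <= n_cal <= I):
        raise DomainError(f"n_cal = {n_cal} outside [2, {I}]")
    # argmax scans row-major, so the first maximal entry has the lowest
    # (i, j) pair — the declared tie-break.
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    chosen = [int(min(i, j)), int(max(i, j))]
    remaining = [k for k in range(I) if k not in chosen]
    min_d = np.minimum(d[chosen[0]], d[chosen[1]])
    while len(chosen) < n_cal:
        cand = np.array(remaining)
        pick = int(cand[np.argmax(min_d[cand])])
        chosen.append(pick)
        remaining.remove(pick)
        min_d = np.minimum(min_d, d[pick])
    return SplitResult(calibration=tuple(chosen), prediction=tuple(sorted(remaining)))
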