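"""PLS1 regression, leave-one-out cross-validation and figures of merit.

The calibration model is single-response partial least squares fitted by
NIPALS on column-mean-centred predictors and a mean-centred response
(optionally autoscaled).  Model quality is judged by the root mean square
error of leave-one-out cross-validation (RMSECV, in response units — here
years of wine age), the root mean square error of prediction on an
independent set (RMSEP), the relative error of prediction REP = RMSE /
mean(y), the coefficient of determination R², and a one-sample Student-t
test of the prediction bias against zero (one-sided critical value at the
requested confidence, n - 1 degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError, ShapeError

__all__ = [
    "PLSModel",
    "MeritReport",
    "fit_pls",
    "predict",
    "loocv",
    "loocv_curve",
    "select_lv",
    "pick_lv",
    "figures_of_merit",
    "bias_t_test",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model: weights W, X-loadings P, y-loadings q, centring."""

    W: np.ndarray          # (J, A) X-weights, unit norm
    P: np.ndarray          # (J, A) X-loadings
    q: np.ndarray          # (A,) y-loadings
    x_mean: np.ndarray     # (J,)
    y_mean: float
    x_scale: np.ndarray    # (J,) 1.0 unless autoscaled

    @property
    def n_lv(self) -> int:
        return self.W.shape[1]

    @property
    def coef(self) -> np.ndarray:
        """Regression vector b in the centred/scaled space:
        b = W (PᵀW)⁻¹ q."""
        return _coef_from_wpq(self.W, self.P, self.q)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)


def _coef_from_wpq(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    A = W.shape[1]
    # PᵀW is unit upper triangular for NIPALS; solve rather than invert.
    return W @ np.linalg.solve(P.T @ W, q[:A])


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on pre-centred data; may truncate when X or y deflates
    to numerical zero.  Returns (W, P, q) with the achieved component count."""
    X = Xc.copy()
    y = yc.copy()
    J = X.shape[1]
    W = np.empty((J, n_lv))
    P = np.empty((J, n_lv))
    q = np.empty(n_lv)
    a = 0
    for a in range(n_lv):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= _EPS:
            break
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt <= _EPS:
            break
        p = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a] = w, p, qa
        a += 1
    return W[:, :a], P[:, :a], q[:a]


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    autoscale: bool = False,
) -> PLSModel:
    """Fit PLS1 with ``n_lv`` latent variables by NIPALS.

    X is column-mean-centred and y mean-centred (autoscaling optional);
    the fit is deterministic for fixed input.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ShapeError(f"X {X.shape} and y {y.shape} are inconsistent")
    I, J = X.shape
    if I < 2:
        raise DomainError("need at least 2 samples")
    if not (1 <= n_lv <= min(I - 1, J)):
        raise DomainError(
            f"n_lv = {n_lv} outside [1, min(I-1, J) = {min(I - 1, J)}]"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DomainError("X and y must be finite")
    if np.ptp(y) <= _EPS:
        raise DegenerateInputError("response y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    if autoscale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale <= _EPS] = 1.0
    else:
        x_scale = np.ones(J)
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean
    W, P, q = _nipals(Xc, yc, n_lv)
    if W.shape[1] == 0:
        raise DegenerateInputError("X carries no usable variance")
    return PLSModel(W=W, P=P, q=q, x_mean=x_mean, y_mean=y_mean, x_scale=x_scale)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict responses for new rows laid out like the training columns."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ShapeError(
            f"X_new has {X_new.shape[1]} columns, model expects "
            f"{model.x_mean.shape[0]}"
        )
    Xc = (X_new - model.x_mean) / model.x_scale
    return model.y_mean + Xc @ model.coef


def loocv_curve(
    X: np.ndarray,
    y: np.ndarray,
    lv_max: int,
    autoscale: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """RMSECV for every component count 1..lv_max in one LOOCV pass.

    NIPALS components are nested, so each leave-one-out refit at ``lv_max``
    components yields the held-out prediction for every smaller count as a
    by-product.  Returns ``(rmsecv, preds)`` with ``rmsecv`` of shape
    ``(lv_max,)`` and ``preds`` of shape ``(I, lv_max)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    I = X.shape[0]
    if I < 3:
        raise DomainError("LOOCV needs at least 3 samples")
    if not (1 <= lv_max <= min(I - 2, X.shape[1])):
        raise DomainError(
            f"lv_max = {lv_max} outside [1, min(I-2, J) = {min(I - 2, X.shape[1])}]"
        )
    if np.ptp(y) <= _EPS:
        raise DegenerateInputError("response y has zero variance")
    preds = np.empty((I, lv_max))
    idx = np.arange(I)
    for i in range(I):
        keep = idx != i
        model = fit_pls(X[keep], y[keep], lv_max, autoscale=autoscale)
        xc = (X[i] - model.x_mean) / model.x_scale
        a_fit = model.n_lv  # may be < lv_max if deflation truncated
        for a in range(1, lv_max + 1):
            aa = min(a, a_fit)
            b = _coef_from_wpq(model.W[:, :aa], model.P[:, :aa], model.q[:aa])
            preds[i, a - 1] = model.y_mean + xc @ b
    resid = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(resid**2, axis=0))
    return rmsecv, preds


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    autoscale: bool = False,
) -> tuple[float, np.ndarray]:
    """Leave-one-out cross-validation at a fixed component count.

    For each sample i the model is refitted on the remaining I - 1 samples
    and sample i predicted; RMSECV = sqrt(mean((ŷᵢ - yᵢ)²)).
    """
    _, preds = loocv_curve(X, y, n_lv, autoscale=autoscale)
    p = preds[:, n_lv - 1]
    y1 = np.asarray(y, dtype=np.float64).ravel()
    return float(np.sqrt(np.mean((p - y1) ** 2))), p


def pick_lv(rmsecv_curve: np.ndarray, tol: float = 0.0) -> int:
    """Parsimonious component choice from an RMSECV curve.

    Returns the smallest component count whose RMSECV is within a relative
    ``tol`` of the curve minimum (tol = 0 demands the minimum itself); ties
    break toward fewer components.
    """
    curve = np.asarray(rmsecv_curve, dtype=np.float64)
    best = float(np.min(curve))
    ok = np.nonzero(curve <= best * (1.0 + tol) + _EPS)[0]
    return int(ok[0]) + 1


def select_lv(
    X: np.ndarray,
    y: np.ndarray,
    lv_max: int,
    tol: float = 0.0,
    autoscale: bool = False,
) -> int:
    """Choose the latent-variable count by LOOCV over 1..lv_max with the
    parsimony rule of :func:`pick_lv`."""
    curve, _ = loocv_curve(X, y, lv_max, autoscale=autoscale)
    return pick_lv(curve, tol=tol)


def figures_of_merit(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """RMSE, REP and R² of a prediction set.

    rep = rmse / mean(y_true) (dimensionless ratio);
    r2 = 1 - Σe² / Σ(y - ȳ)².
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ShapeError("y_true and y_pred must share length >= 2")
    e = y_pred - y_true
    rmse = float(np.sqrt(np.mean(e**2)))
    ybar = float(np.mean(y_true))
    if abs(ybar) <= _EPS:
        raise DegenerateInputError("mean(y_true) = 0: REP undefined")
    ss_tot = float(np.sum((y_true - ybar) ** 2))
    r2 = 1.0 - float(np.sum(e**2)) / ss_tot if ss_tot > _EPS else float("nan")
    return {"rmse": rmse, "rep": rmse / ybar, "r2": r2}


def bias_t_test(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    confidence: float = 0.95,
) -> dict:
    """One-sample Student-t test of the prediction bias against zero.

    With residuals eᵢ = ŷᵢ - yᵢ: bias = mean(e), SDV the sample standard
    deviation of e (n - 1 denominator), t_cal = |bias| √n / SDV, and t_crit
    the one-sided t quantile at the given confidence with n - 1 degrees of
    freedom.  Bias is significant iff t_cal > t_crit.
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ShapeError("y_true and y_pred must share length >= 2")
    e = y_pred - y_true
    n = e.size
    bias = float(np.mean(e))
    sdv = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    if sdv <= _EPS:
        raise DegenerateInputError("residuals have zero spread")
    t_cal = abs(bias) * np.sqrt(n) / sdv
    t_crit = float(stats.t.ppf(confidence, df=n - 1))
    return {
        "bias": bias,
        "t_cal": float(t_cal),
        "t_crit": t_crit,
        "significant": bool(t_cal > t_crit),
    }


@dataclass(frozen=True)
class MeritReport:
    """Figures of merit of one calibration/prediction model pair."""

    model_name: str
    n_lv: int
    rmsecv: float
    rep_cv: float
    r2_cv: float
    rmsep: float | None = None
    rep: float | None = None
    r2: float | None = None
    bias: float | None = None
    t_cal: float | None = None
    t_crit: float | None = None
    bias_significant: bool | None = None

    CSV_COLUMNS = (
        "model", "n_lv", "rmsecv", "rep_cv", "r2_cv",
        "rmsep", "rep", "r2", "bias", "t_cal", "t_crit", "bias_significant",
    )

    def to_row(self) -> dict:
        return {
            "model": self.model_name,
            "n_lv": self.n_lv,
            "rmsecv": self.rmsecv,
            "rep_cv": self.rep_cv,
            "r2_cv": self.r2_cv,
            "rmsep": self.rmsep,
            "rep": self.rep,
            "r2": self.r2,
            "bias": self.bias,
            "t_cal": self.t_cal,
            "t_crit": self.t_crit,
            "bias_significant": self.bias_significant,
        }

    def to_text(self) -> str:
        lines = [f"model: {self.model_name}"]
        for key, val in self.to_row().items():
            if key == "model" or val is None:
                continue
            if isinstance(val, float):
                lines.append(f"{key}: {val:.6g}")
            else:
                lines.append(f"{key}: {val}")
        return "\n".join(lines)
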