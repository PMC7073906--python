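"""Partial least squares regression (NIPALS PLS1), LOOCV model selection and
the standard chemometric performance metrics.

The estimator follows the scikit-learn contract (``fit``/``predict``/
``score``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) and additionally exposes the full coefficient *path*: because
NIPALS components are nested, one fit with ``A`` latent variables yields the
regression-coefficient vector of every truncated model with ``a <= A``
components.  Leave-one-out cross-validation exploits this, fitting once per
fold rather than once per fold per component count.

Metrics: R^2 = 1 - SS_res/SS_tot, RMSE = sqrt(mean squared error), and the
residual predictive deviation RPD = SD(reference y, n-1) / RMSE; models with
R^2 >= 0.70 and RPD >= 2.0 are conventionally deemed effective for meat
quality prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PLSRegressionNIPALS",
    "ModelReport",
    "fit_plsr",
    "loocv_select",
    "loocv_predictions",
    "evaluate",
]


class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """PLS1 regression via the NIPALS algorithm with mean centering.

    Parameters
    ----------
    n_components : int
        Number of latent variables (LVs) to extract.

    Attributes
    ----------
    x_weights_ : ndarray, (bands, A)
        Deflated-X weight vectors w_a (unit norm).
    x_loadings_ : ndarray, (bands, A)
        X loadings p_a.
    y_loadings_ : ndarray, (A,)
        y loadings q_a.
    x_scores_ : ndarray, (n, A)
        Training scores t_a.
    x_rotations_ : ndarray, (bands, A)
        R = W (P'W)^-1 mapping centered X to scores.
    coef_path_ : ndarray, (bands, A)
        Column a-1 holds the coefficient vector of the a-component model.
    coef_ : ndarray, (bands,)
        Coefficients of the full ``n_components_`` model (original X space).
    intercept_ : float
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        n, b = X.shape
        if len(y) != n:
            raise ValueError("X and y have different sample counts")
        if np.ptp(y) == 0:
            raise ValueError("y is constant; PLSR response must vary")
        max_a = min(n - 1, b)
        if not 1 <= self.n_components <= max_a:
            raise ValueError(
                f"n_components must be in [1, min(samples-1, bands)] = [1, {max_a}], "
                f"got {self.n_components}"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_

        A = self.n_components
        W = np.zeros((b, A))
        P = np.zeros((b, A))
        q = np.zeros(A)
        T = np.zeros((n, A))
        a_done = 0
        for a in range(A):
            w = Xc.T @ yc
            wn = np.linalg.norm(w)
            if wn < 1e-14:  # residual X carries no covariance with y left
                break
            w /= wn
            t = Xc @ w
            tt = float(t @ t)
            if tt < 1e-14:
                break
            p = Xc.T @ t / tt
            qa = float(yc @ t) / tt
            Xc = Xc - np.outer(t, p)
            yc = yc - qa * t
            W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
            a_done = a + 1
        if a_done == 0:
            raise ValueError("no PLS component could be extracted (X'y is zero)")
        W, P, q, T = W[:, :a_done], P[:, :a_done], q[:a_done], T[:, :a_done]

        # P'W is unit upper triangular in NIPALS; R_a = W_a (P_a'W_a)^-1 and
        # the leading-column structure makes every truncation share R's columns.
        U = np.triu(P.T @ W)
        R = solve_triangular(U, W.T, lower=False, trans="T").T  # W @ U^-1
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T
        self.x_rotations_ = R
        self.coef_path_ = np.cumsum(R * q, axis=1)
        self.n_components_ = a_done
        if a_done < A:
            warnings.warn(
                f"only {a_done} of {A} requested components could be extracted",
                stacklevel=2,
            )
        self.coef_ = self.coef_path_[:, -1]
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        self.n_features_in_ = b
        return self

    def predict(self, X, n_components: int | None = None):
        """Predict y; ``n_components`` truncates to a smaller nested model."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if n_components is None:
            coef = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValueError(
                    f"n_components must be in [1, {self.n_components_}]"
                )
            coef = self.coef_path_[:, n_components - 1]
        intercept = self.y_mean_ - float(self.x_mean_ @ coef)
        return X @ coef + intercept

    def transform(self, X):
        """Project spectra onto the latent-variable scores."""
        check_is_fitted(self, "x_rotations_")
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.x_rotations_

    def predict_from_scores(self, X):
        """Prediction via the score space (equals ``predict`` to ~1e-8)."""
        return self.transform(X) @ self.y_loadings_ + self.y_mean_


def fit_plsr(X, y, n_lv: int) -> PLSRegressionNIPALS:
    """Fit a PLSR model with ``n_lv`` latent variables."""
    return PLSRegressionNIPALS(n_components=n_lv).fit(X, y)


def loocv_predictions(X, y, max_lv: int) -> np.ndarray:
    """Leave-one-out predictions, shape (n, max_lv): column a-1 holds the
    held-out predictions of the a-component model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    preds = np.empty((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = PLSRegressionNIPALS(n_components=max_lv).fit(X[keep], y[keep])
        xi = X[i]
        coefs = model.coef_path_  # (bands, A_done)
        yhat = xi @ coefs + (model.y_mean_ - model.x_mean_ @ coefs)
        if model.n_components_ < max_lv:  # padded with the deepest model
            yhat = np.concatenate(
                [yhat, np.full(max_lv - model.n_components_, yhat[-1])]
            )
        preds[i] = yhat
    return preds


def loocv_select(X, y, max_lv: int = 20) -> tuple[int, np.ndarray]:
    """Choose the LV count minimising RMSECV under leave-one-out CV.

    Returns ``(optimal n_lv, RMSECV curve)`` where the curve's a-th entry is
    the RMSECV of the a-component model.  Ties go to the fewest LVs.  If
    ``max_lv`` is infeasible for the fold size it is clipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV selection needs at least 3 samples")
    feasible = min(n - 2, X.shape[1])
    if max_lv > feasible:
        warnings.warn(
            f"max_lv={max_lv} infeasible for {n} samples / {X.shape[1]} bands; "
            f"clipped to {feasible}",
            stacklevel=2,
        )
        max_lv = feasible
    preds = loocv_predictions(X, y, max_lv)
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    return int(np.argmin(rmsecv)) + 1, rmsecv


@dataclass
class ModelReport:
    """Performance summary, one row of a comparison table."""

    pretreatment: str
    n_lv: int
    r2_c: float
    rmsec: float
    r2_cv: float
    rmsecv: float
    r2_p: float
    rmsep: float
    rpd: float

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(y, yhat, reference_sd: float | None = None) -> dict[str, float]:
    """R^2, RMSE and RPD of predictions against reference values.

    ``reference_sd`` defaults to the n-1 standard deviation of ``y`` (the
    evaluated set's own reference values), the convention used for RPD.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat have different shapes")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("reference values are constant; R^2 undefined")
    ss_res = float(((y - yhat) ** 2).sum())
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if reference_sd is None:
        reference_sd = float(np.std(y, ddof=1))
    return {
        "r2": 1.0 - ss_res / ss_tot,
        "rmse": rmse,
        "rpd": float(reference_sd / rmse) if rmse > 0 else float("inf"),
    }
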