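"""Multivariate calibration core: NIPALS partial least squares, principal
component regression, and multivariate (pseudoinverse) linear regression.

The PLS model is the bilinear decomposition

    X = T P' + E        Y = U Q' + F

where T and U are score matrices, P and Q loading matrices, and E, F the
residuals. Factors are extracted one at a time by NIPALS: alternating weight
and score updates maximise the covariance between X- and Y-scores, after
which both matrices are deflated by the fitted rank-one term. The regression
coefficient matrix is B = W (P'W)^-1 Q', so prediction is a single affine
map on mean-centred spectra.

X is centred but not autoscaled (spectra share units); Y is centred. One
analyte is modelled at a time by default (PLS1); multi-response PLS2 works
through the same routine by passing a multi-column Y.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .datasets import FermspecError


class FitError(FermspecError, ValueError):
    pass


def _as_xy(X, Y):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise FitError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
    return X, Y


@dataclass
class PLSRModel:
    """Fitted NIPALS PLS model with full score/loading structure."""

    x_scores: np.ndarray       # T (n, k)
    x_loadings: np.ndarray     # P (p, k)
    y_scores: np.ndarray       # U (n, k)
    y_loadings: np.ndarray     # Q (m, k)
    x_weights: np.ndarray      # W (p, k)
    x_residuals: np.ndarray    # E (n, p)
    y_residuals: np.ndarray    # F (n, m)
    coefficients: np.ndarray   # B (p, m)
    x_mean: np.ndarray
    y_mean: np.ndarray
    n_factors: int
    meta: dict[str, Any] = field(default_factory=dict)

    kind = "plsr"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


@dataclass
class LinearModel:
    """Affine regression model (PCR or MLR): yhat = (x - x_mean) B + y_mean."""

    kind: str                  # "pcr" | "mlr"
    coefficients: np.ndarray   # B (p, m)
    x_mean: np.ndarray
    y_mean: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def fit_plsr(
    X: np.ndarray,
    Y: np.ndarray,
    n_factors: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSRModel:
    """Fit a PLS model with ``n_factors`` latent variables by NIPALS.

    The inner loop initialises the Y-score u to the largest-variance column
    of the (deflated) Y and iterates until the weight vector changes by less
    than ``tol`` in relative 2-norm; a loop hitting ``max_iter`` raises a
    warning. Deterministic for fixed inputs.
    """
    X, Y = _as_xy(X, Y)
    n, p = X.shape
    m = Y.shape[1]
    if n < 2:
        raise FitError("need at least two samples")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise FitError(
            f"n_factors must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean

    T = np.empty((n, n_factors))
    U = np.empty((n, n_factors))
    W = np.empty((p, n_factors))
    P = np.empty((p, n_factors))
    Q = np.empty((m, n_factors))
    eps = np.finfo(float).eps

    for k in range(n_factors):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.linalg.norm(u) < eps * 100:
            raise FitError(f"factor {k + 1}: Y residual is numerically zero")
        w_old = None
        for _ in range(max_iter):
            w = E.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm < eps * 100:
                raise FitError(f"factor {k + 1}: weight vector underflow "
                               "(rank-deficient X residual)")
            w /= w_norm
            t = E @ w
            tt = t @ t
            if tt < eps * 100:
                raise FitError(f"factor {k + 1}: score norm underflow")
            q = F.T @ t / tt
            qq = q @ q
            u = F @ q / qq if qq > 0 else t.copy()
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
        else:
            warnings.warn(
                f"NIPALS factor {k + 1} did not converge in {max_iter} "
                "iterations", RuntimeWarning, stacklevel=2,
            )
        p_vec = E.T @ t / tt
        E = E - np.outer(t, p_vec)
        F = F - np.outer(t, q)
        T[:, k], U[:, k], W[:, k], P[:, k], Q[:, k] = t, u, w, p_vec, q

    B = W @ np.linalg.solve(P.T @ W, Q.T)
    return PLSRModel(
        x_scores=T, x_loadings=P, y_scores=U, y_loadings=Q, x_weights=W,
        x_residuals=E, y_residuals=F, coefficients=B,
        x_mean=x_mean, y_mean=y_mean, n_factors=n_factors,
        meta={"algorithm": "nipals", "mode": "pls1" if m == 1 else "pls2",
              "tol": tol},
    )


def predict(model: PLSRModel | LinearModel, X: np.ndarray) -> np.ndarray:
    """Row-wise affine prediction: yhat = (x - x_mean) B + y_mean."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = model.coefficients.shape[0]
    if X.shape[1] != p:
        raise FitError(
            f"model expects {p} wavelengths, got {X.shape[1]}"
        )
    out = (X - model.x_mean) @ model.coefficients + model.y_mean
    if not np.all(np.isfinite(out)):
        raise FitError("non-finite prediction; check inputs")
    return out


def fit_pcr(X: np.ndarray, Y: np.ndarray, n_components: int) -> LinearModel:
    """Principal component regression: regress centred Y on the leading
    principal-component scores of centred X, mapped back to wavelength
    space."""
    X, Y = _as_xy(X, Y)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise FitError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    xc = X - x_mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = n_components
    if s[k - 1] < np.finfo(float).eps * 100 * max(n, p):
        raise FitError(f"component {k}: singular value underflow")
    scores = u[:, :k] * s[:k]
    gamma = (u[:, :k].T @ (Y - y_mean)) / s[:k, None]
    B = vt[:k].T @ gamma
    return LinearModel("pcr", B, x_mean, y_mean,
                       meta={"n_components": k, "singular_values": s[:k]})


def fit_mlr(X: np.ndarray, Y: np.ndarray) -> LinearModel:
    """Minimum-norm least squares (pseudoinverse) on centred data.

    When p >= n the normal equations are underdetermined and this returns
    the minimum-norm interpolator of the calibration data; a warning flags
    that regime since it generalises poorly for spectra.
    """
    X, Y = _as_xy(X, Y)
    n, p = X.shape
    if p >= n:
        warnings.warn(
            f"MLR with p={p} >= n={n}: returning the minimum-norm "
            "interpolator", RuntimeWarning, stacklevel=2,
        )
    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    B = np.linalg.pinv(X - x_mean) @ (Y - y_mean)
    return LinearModel("mlr", B, x_mean, y_mean)


def regression_coefficients(
    model: PLSRModel | LinearModel,
    wavelengths: np.ndarray,
    analytes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-wavelength regression coefficient profile, one column per analyte
    (for coefficient-versus-wavelength plots)."""
    B = getattr(model, "coefficients", None)
    if B is None:
        raise FitError("model has no coefficients; fit it first")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size != B.shape[0]:
        raise FitError(
            f"model has {B.shape[0]} coefficients but {wavelengths.size} "
            "wavelength labels were given"
        )
    if analytes is None:
        analytes = [f"y{j}" for j in range(B.shape[1])]
    return pd.DataFrame(B, index=pd.Index(wavelengths, name="wavelength_nm"),
                        columns=analytes)
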