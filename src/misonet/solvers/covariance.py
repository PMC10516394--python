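"""Covariance-form Lasso estimators for designs with missing entries.

Both CoCoLasso and HMLasso avoid imputation by rewriting the Lasso in
terms of second moments. The pairwise moment matrix

    S_pair[j,k] = (1/n_jk) * sum over rows where X_j and X_k are both
                  observed of X_ij * X_ik

(and the analogous cross-moment vector rho_pair between each column and
the response) is generally indefinite, so it is replaced by its nearest
positive semidefinite surrogate Sigma before solving

    min_beta 1/2 beta' Sigma beta - rho_pair' beta + lam ||beta||_1.

CoCoLasso projects under the elementwise max norm; HMLasso minimises the
observation-rate weighted Frobenius norm ||W o (Sigma - S_pair)||_F^2 with
W = R^alpha, R[j,k] = n_jk / n, which down-weights poorly co-observed
entries. Both projections run ADMM with an eigenvalue-clipping step.

The 1/2 factor on the quadratic term makes the estimator collapse exactly
to the residual-form Lasso on complete standardized data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..datamodel import FitResult
from ._kernels import cd_quad_l1
from .standardize import SolverError, standardize

logger = logging.getLogger(__name__)


@dataclass
class CovarianceEstimate:
    """Pairwise second moments with observation-rate bookkeeping."""

    S_pair: np.ndarray  # (p, p)
    rho_pair: np.ndarray  # (p,)
    n_jk: np.ndarray  # (p, p) co-observation counts
    R: np.ndarray  # n_jk / n
    Z: np.ndarray  # mean-imputed (zero-filled standardized) design
    S_imp: np.ndarray  # R o S_pair, the moment matrix of Z
    y_sq_mean: float  # mean of y^2 over observed responses
    W: np.ndarray | None = None
    alpha_weight: float | None = None
    Sigma: np.ndarray | None = None


def pairwise_moments(X: np.ndarray, y: np.ndarray) -> CovarianceEstimate:
    """Second moments over co-observed rows; X should be standardized.

    A column observed in zero rows is an error; a pair with no co-observed
    rows gets moment 0 with a warning. rho_pair uses rows where the column
    and the response are both observed (responses are themselves omics
    features and may be missing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    obs = ~np.isnan(X)
    n_col = obs.sum(axis=0)
    if (n_col == 0).any():
        j = int(np.argmax(n_col == 0))
        raise SolverError(f"column {j} observed in 0 rows")
    Xz = np.nan_to_num(X, nan=0.0)
    M = obs.astype(float)
    n_jk = M.T @ M
    if (n_jk == 0).any():
        logger.warning("%d feature pairs share no co-observed rows; moments set to 0",
                       int((n_jk == 0).sum()) // 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(n_jk > 0, (Xz.T @ Xz) / np.maximum(n_jk, 1), 0.0)
    y_obs = ~np.isnan(y)
    yz = np.nan_to_num(y, nan=0.0)
    n_jy = M.T @ y_obs.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(n_jy > 0, (Xz.T @ yz) / np.maximum(n_jy, 1), 0.0)
    y_sq_mean = float(np.mean(yz[y_obs] ** 2)) if y_obs.any() else 0.0
    R = n_jk / n
    return CovarianceEstimate(S, rho, n_jk, R, Xz, R * S, y_sq_mean)


# ------------------------------------------------------------- projections


def _project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of a flat vector onto the l1 ball of given radius."""
    if radius <= 0:
        return np.zeros_like(v)
    a = np.abs(v)
    if a.sum() <= radius:
        return v.copy()
    u = np.sort(a)[::-1]
    css = np.cumsum(u)
    idx = np.arange(1, len(u) + 1)
    cond = u - (css - radius) / idx > 0
    k = idx[cond][-1]
    tau = (css[k - 1] - radius) / k
    return np.sign(v) * np.maximum(a - tau, 0.0)


def _prox_maxnorm(V: np.ndarray, t: float) -> np.ndarray:
    """prox of t * elementwise max-norm (Moreau: subtract l1-ball projection)."""
    flat = V.ravel()
    return (flat - _project_l1_ball(flat, t)).reshape(V.shape)


def _psd_clip(A: np.ndarray) -> np.ndarray:
    A = (A + A.T) / 2
    w, V = np.linalg.eigh(A)
    w = np.maximum(w, 0.0)
    out = (V * w) @ V.T
    return (out + out.T) / 2


def psd_project_maxnorm(
    S_pair: np.ndarray,
    tol: float = 1e-7,
    rho: float = 1.0,
    max_iter: int = 2000,
) -> np.ndarray:
    """Nearest-PSD surrogate under the elementwise max norm, via ADMM."""
    S = (np.asarray(S_pair, float) + np.asarray(S_pair, float).T) / 2
    Y = S.copy()
    U = np.zeros_like(S)
    X = S.copy()
    for _ in range(max_iter):
        X = _psd_clip(Y - U)
        Y_prev = Y
        Y = S + _prox_maxnorm(X + U - S, 1.0 / rho)
        U = U + X - Y
        r_prim = np.linalg.norm(X - Y)
        r_dual = rho * np.linalg.norm(Y - Y_prev)
        if r_prim < tol and r_dual < tol:
            return X
    raise SolverError(
        f"max-norm PSD projection: ADMM hit {max_iter} iterations "
        f"(primal {r_prim:.2e}, dual {r_dual:.2e})"
    )


def psd_project_weighted_frobenius(
    S_pair: np.ndarray,
    W: np.ndarray | None = None,
    tol: float = 1e-7,
    rho: float = 1.0,
    max_iter: int = 2000,
) -> np.ndarray:
    """Minimize ||W o (Sigma - S_pair)||_F^2 over PSD Sigma, via ADMM.

    With W = 1 this is the unweighted Frobenius projection, whose closed
    form is eigenvalue clipping (used as the internal correctness oracle).
    """
    S = (np.asarray(S_pair, float) + np.asarray(S_pair, float).T) / 2
    if W is None:
        W = np.ones_like(S)
    W2 = np.asarray(W, float) ** 2
    Z = S.copy()
    U = np.zeros_like(S)
    denom = 2 * W2 + rho
    for _ in range(max_iter):
        Sigma = (2 * W2 * S + rho * (Z - U)) / denom
        Z_prev = Z
        Z = _psd_clip(Sigma + U)
        U = U + Sigma - Z
        r_prim = np.linalg.norm(Sigma - Z)
        r_dual = rho * np.linalg.norm(Z - Z_prev)
        if r_prim < tol and r_dual < tol:
            return Z
    raise SolverError(
        f"weighted-Frobenius PSD projection: ADMM hit {max_iter} iterations "
        f"(primal {r_prim:.2e}, dual {r_dual:.2e})"
    )


# ---------------------------------------------------------------- the fit


def covariance_objective(Sigma: np.ndarray, rho_pair: np.ndarray, beta: np.ndarray, lam: float) -> float:
    return 0.5 * float(beta @ Sigma @ beta) - float(rho_pair @ beta) + lam * float(np.abs(beta).sum())


def covariance_lasso_fit(
    Sigma: np.ndarray,
    rho_pair: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> np.ndarray:
    """Coordinate descent on 1/2 b'Sigma b - rho'b + lam ||b||_1."""
    p = len(rho_pair)
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    status = cd_quad_l1(
        np.ascontiguousarray(Sigma, dtype=float),
        np.ascontiguousarray(rho_pair, dtype=float),
        float(lam), np.ones(p), beta, tol, max_iter,
    )
    if status < 0:
        raise SolverError(f"covariance-form Lasso did not converge in {max_iter} iterations")
    return beta


class _CovCvKernel:
    """CV kernel: moments + PSD projection per training fold, CD down the path."""

    def __init__(self, Xs: np.ndarray, ys: np.ndarray, mode: str, alpha_weight: float | None = None):
        self.Xs = Xs
        self.ys = ys
        self.mode = mode  # "maxnorm" | "weighted"
        self.alpha_weight = alpha_weight

    def _rows(self, rows):
        if rows is None:
            return self.Xs, self.ys
        return self.Xs[rows], self.ys[rows]

    def moments(self, rows):
        X, y = self._rows(rows)
        return pairwise_moments(X, y)

    def project(self, est: CovarianceEstimate) -> np.ndarray:
        if self.mode == "maxnorm":
            return psd_project_maxnorm(est.S_pair)
        W = est.R ** self.alpha_weight
        return psd_project_weighted_frobenius(est.S_pair, W)

    def lambda_max(self, rows=None) -> float:
        est = self.moments(rows)
        return float(np.abs(est.rho_pair).max()) if len(est.rho_pair) else 0.0

    def fit_path(self, rows, lambdas):
        est = self.moments(rows)
        Sigma = self.project(est)
        out, warm = [], None
        for lam in lambdas:
            warm = covariance_lasso_fit(Sigma, est.rho_pair, float(lam), beta0=warm)
            out.append(warm.copy())
        return out

    def val_error(self, beta, rows) -> float:
        est = self.moments(rows)
        return float(beta @ est.S_pair @ beta - 2 * est.rho_pair @ beta + est.y_sq_mean)


def _cov_fit_result(
    Xs, ys, record, est, Sigma, lam, response, feature_names, extra
) -> FitResult:
    beta_std = covariance_lasso_fit(Sigma, est.rho_pair, lam)
    # performance against the mean-imputed design Z (zeros in standardized scale)
    y_obs = ~np.isnan(ys)
    pred = est.Z @ beta_std
    resid = ys[y_obs] - pred[y_obs]
    sst = float(np.sum(ys[y_obs] ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    rmse = float(np.sqrt(np.mean(resid**2))) if y_obs.any() else 0.0
    beta_raw, intercept = record.back_transform(beta_std)
    if feature_names is None:
        feature_names = [str(j) for j in range(len(beta_raw))]
    coefs = {f: float(b) for f, b in zip(feature_names, beta_raw)}
    return FitResult(response, coefs, intercept, min(r2, 1.0), rmse, lam, extra)


def cocolasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    cv,
    response: str = "",
    feature_names: list[str] | None = None,
) -> FitResult:
    """CoCoLasso: pairwise moments, max-norm PSD projection, CV'd l1 path."""
    from .cv import cv_lambda_path

    Xs, ys, record = standardize(X, y)
    kernel = _CovCvKernel(Xs, ys, "maxnorm")
    _, _, lam = cv_lambda_path(kernel, len(ys), cv)
    est = kernel.moments(None)
    Sigma = kernel.project(est)
    est.Sigma = Sigma
    names = None if feature_names is None else [feature_names[j] for j in range(len(feature_names))]
    res = _cov_fit_result(Xs, ys, record, est, Sigma, lam, response, names, {})
    return res


def hmlasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    cv,
    response: str = "",
    feature_names: list[str] | None = None,
) -> FitResult:
    """HMLasso: CoCoLasso with W = R^alpha weighted-Frobenius projection.

    The weight power alpha is selected jointly with lambda by CV over the
    configured grid (default 0.5..2.0 in steps of 0.5).
    """
    from .cv import cv_lambda_path

    Xs, ys, record = standardize(X, y)
    best = None
    for alpha in cv.alpha_weight_grid:
        kernel = _CovCvKernel(Xs, ys, "weighted", alpha_weight=alpha)
        _, errs, lam = cv_lambda_path(kernel, len(ys), cv)
        score = float(errs.min())
        if best is None or score < best[0]:
            best = (score, alpha, lam)
    _, alpha, lam = best
    kernel = _CovCvKernel(Xs, ys, "weighted", alpha_weight=alpha)
    est = kernel.moments(None)
    est.alpha_weight = alpha
    est.W = est.R**alpha
    Sigma = kernel.project(est)
    est.Sigma = Sigma
    return _cov_fit_result(
        Xs, ys, record, est, Sigma, lam, response, feature_names, {"alpha_weight": alpha}
    )
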