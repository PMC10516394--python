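"""Stacked and grouped (adaptive) Lasso over multiply imputed datasets.

Stacked: the D completed copies are concatenated row-wise with uniform
observation weights o_i = 1/D, giving one pooled coefficient vector

    min_beta 1/(2 n D) sum_d ||y_d - X_d beta||_2^2
             + lam * sum_j w_j |beta_j|

Grouped: one coefficient vector per copy, but each covariate's D
coefficients form a single group, so selection is identical across copies

    min_{beta_1..beta_D} 1/(2 n) sum_d ||y_d - X_d beta_d||_2^2
             + lam * sum_j w_j sqrt(sum_d beta_{d,j}^2)

Adaptive weights w_j relax shrinkage on covariates with strong initial
estimates: w_j = (|beta0_j| + 1/n)^(-gamma) (stacked) or
(||beta0_{.,j}||_2 + 1/(nD))^(-gamma) (grouped), where beta0 comes from the
corresponding non-adaptive fit and gamma = ceil(2v/(1-v)) + 1 with
v = log(p)/log(n) (stacked) or v = log(pD)/log(nD) (grouped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import cd_group_quad, cd_quad_l1
from .standardize import SolverError


def adaptive_gamma(p_eff: int, n_eff: int) -> int:
    """gamma = ceil(2v/(1-v)) + 1 with v = log(p_eff)/log(n_eff); needs v < 1."""
    if p_eff < 1 or n_eff <= 1:
        raise SolverError("adaptive_gamma needs p_eff >= 1 and n_eff > 1")
    v = math.log(p_eff) / math.log(n_eff) if p_eff > 1 else 0.0
    if v >= 1:
        raise SolverError(f"adaptive gamma undefined for v = {v:.3f} >= 1 (p >= n)")
    # guard the ceiling against float noise (e.g. 1.0000000000000002 -> 2)
    return int(math.ceil(round(2 * v / (1 - v), 12))) + 1


# ---------------------------------------------------------------- stacked


def stacked_objective(
    X_list: list[np.ndarray],
    y_list: list[np.ndarray],
    beta: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    n = len(y_list[0])
    D = len(X_list)
    w = np.ones(len(beta)) if weights is None else weights
    rss = sum(float(np.sum((y - X @ beta) ** 2)) for X, y in zip(X_list, y_list))
    return rss / (2 * n * D) + lam * float(w @ np.abs(beta))


def stacked_lambda_max(
    X_list: list[np.ndarray],
    y_list: list[np.ndarray],
    weights: np.ndarray | None = None,
) -> float:
    n, D = len(y_list[0]), len(X_list)
    grad = sum(X.T @ y for X, y in zip(X_list, y_list)) / (n * D)
    w = np.ones(len(grad)) if weights is None else weights
    with np.errstate(divide="ignore"):
        vals = np.where(w > 0, np.abs(grad) / w, np.inf)
    return float(vals.max()) if len(vals) else 0.0


def stacked_lasso_fit(
    X_list: list[np.ndarray],
    y_list: list[np.ndarray],
    lam: float,
    adaptive: bool = False,
    weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> np.ndarray:
    """Coordinate descent on the stacked weighted l1 objective.

    With ``adaptive=True`` and no explicit ``weights``, initial estimates
    come from a non-adaptive fit at the same lambda.
    """
    D = len(X_list)
    n, p = X_list[0].shape
    if weights is None:
        if adaptive:
            b_init = stacked_lasso_fit(X_list, y_list, lam, adaptive=False, tol=tol)
            gamma = adaptive_gamma(p, n)
            weights = (np.abs(b_init) + 1.0 / n) ** (-gamma)
        else:
            weights = np.ones(p)
    N = n * D
    G = sum(X.T @ X for X in X_list) / N
    c = sum(X.T @ y for X, y in zip(X_list, y_list)) / N
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    status = cd_quad_l1(
        np.ascontiguousarray(G), np.ascontiguousarray(c), float(lam),
        np.asarray(weights, dtype=float), beta, tol, max_iter,
    )
    if status < 0:
        raise SolverError(f"stacked Lasso did not converge in {max_iter} iterations")
    return beta


# ---------------------------------------------------------------- grouped


@dataclass
class GroupedFit:
    """Per-imputation coefficients sharing a single support."""

    betas: np.ndarray  # (D, p)
    lam: float = 0.0
    weights: np.ndarray | None = None

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(np.any(self.betas != 0.0, axis=0))

    def pooled(self) -> np.ndarray:
        """Rubin-style pooled estimate: the mean coefficient across copies."""
        return self.betas.mean(axis=0)


def grouped_objective(
    X_list: list[np.ndarray],
    y_list: list[np.ndarray],
    betas: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
) -> float:
    n = len(y_list[0])
    p = betas.shape[1]
    w = np.ones(p) if weights is None else weights
    rss = sum(float(np.sum((y - X @ b) ** 2)) for X, y, b in zip(X_list, y_list, betas))
    group_norms = np.linalg.norm(betas, axis=0)
    return rss / (2 * n) + lam * float(w @ group_norms)


def grouped_lambda_max(
    X_list: list[np.ndarray],
    y_list: list[np.ndarray],
    weights: np.ndarray | None = None,
) -> float:
    n = len(y_list[0])
    G = np.stack([X.T @ y / n for X, y in zip(X_list, y_list)])  # (D, p)
    norms = np.linalg.norm(G, axis=0)
    w = np.ones(len(norms)) if weights is None else weights
    with np.errstate(divide="ignore"):
        vals = np.where(w > 0, norms / w, np.inf)
    return float(vals.max()) if len(vals) else 0.0


def grouped_lasso_fit(
    X_list: list[np.ndarray],
    y_list: list[np.ndarray],
    lam: float,
    adaptive: bool = False,
    weights: np.ndarray | None = None,
    betas0: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100000,
) -> GroupedFit:
    """Group coordinate descent; group j = the D coefficients of covariate j.

    Group soft-thresholding guarantees the shared-support invariant exactly:
    a covariate is either zero in every copy or selected in all of them.
    """
    D = len(X_list)
    n, p = X_list[0].shape
    if weights is None:
        if adaptive:
            init = grouped_lasso_fit(X_list, y_list, lam, adaptive=False, tol=tol)
            gamma = adaptive_gamma(p * D, n * D)
            weights = (np.linalg.norm(init.betas, axis=0) + 1.0 / (n * D)) ** (-gamma)
        else:
            weights = np.ones(p)
    betas = np.zeros((D, p)) if betas0 is None else betas0.copy()
    Gs = np.stack([np.ascontiguousarray(X.T @ X / n) for X in X_list])
    cs = np.stack([X.T @ y / n for X, y in zip(X_list, y_list)])
    status = cd_group_quad(
        Gs, cs, float(lam), np.asarray(weights, dtype=float), betas, tol, max_iter
    )
    if status < 0:
        raise SolverError(f"grouped Lasso did not converge in {max_iter} iterations")
    return GroupedFit(betas, lam, weights)


# ---------------------------------------------------------------- CV kernels


class _MultiImpKernel:
    """Shared CV plumbing: folds index the original n samples of every copy."""

    def __init__(self, X_list, y_list, weights=None):
        self.X_list = X_list
        self.y_list = y_list
        self.weights = weights

    def _sub(self, rows):
        if rows is None:
            return self.X_list, self.y_list
        return [X[rows] for X in self.X_list], [y[rows] for y in self.y_list]


class StackedCvKernel(_MultiImpKernel):
    def lambda_max(self, rows=None):
        Xs, ys = self._sub(rows)
        return stacked_lambda_max(Xs, ys, self.weights)

    def fit_path(self, rows, lambdas):
        Xs, ys = self._sub(rows)
        out, warm = [], None
        for lam in lambdas:
            warm = stacked_lasso_fit(Xs, ys, float(lam), weights=self.weights, beta0=warm)
            out.append(warm.copy())
        return out

    def val_error(self, beta, rows):
        Xs, ys = self._sub(rows)
        D, nv = len(Xs), len(rows)
        return sum(float(np.sum((y - X @ beta) ** 2)) for X, y in zip(Xs, ys)) / (D * nv)


class GroupedCvKernel(_MultiImpKernel):
    def lambda_max(self, rows=None):
        Xs, ys = self._sub(rows)
        return grouped_lambda_max(Xs, ys, self.weights)

    def fit_path(self, rows, lambdas):
        Xs, ys = self._sub(rows)
        out, warm = [], None
        for lam in lambdas:
            fit = grouped_lasso_fit(Xs, ys, float(lam), weights=self.weights, betas0=warm)
            warm = fit.betas
            out.append(fit)
        return out

    def val_error(self, fit: GroupedFit, rows):
        Xs, ys = self._sub(rows)
        D, nv = len(Xs), len(rows)
        return sum(
            float(np.sum((y - X @ b) ** 2)) for X, y, b in zip(Xs, ys, fit.betas)
        ) / (D * nv)


def stacked_cv_fit(X_list, y_list, cfg, adaptive: bool = False):
    """CV the stacked Lasso; for the adaptive variant, weights come from the
    CV-selected non-adaptive fit and the path is re-cross-validated."""
    from .cv import cv_lambda_path

    n, p = X_list[0].shape
    kernel = StackedCvKernel(X_list, y_list)
    _, _, lam = cv_lambda_path(kernel, n, cfg)
    beta = stacked_lasso_fit(X_list, y_list, lam)
    if not adaptive:
        return beta, lam, None
    gamma = adaptive_gamma(p, n)
    weights = (np.abs(beta) + 1.0 / n) ** (-gamma)
    kernel = StackedCvKernel(X_list, y_list, weights)
    _, _, lam2 = cv_lambda_path(kernel, n, cfg)
    beta2 = stacked_lasso_fit(X_list, y_list, lam2, weights=weights)
    return beta2, lam2, weights


def grouped_cv_fit(X_list, y_list, cfg, adaptive: bool = False):
    from .cv import cv_lambda_path

    D = len(X_list)
    n, p = X_list[0].shape
    kernel = GroupedCvKernel(X_list, y_list)
    _, _, lam = cv_lambda_path(kernel, n, cfg)
    fit = grouped_lasso_fit(X_list, y_list, lam)
    if not adaptive:
        return fit, lam, None
    gamma = adaptive_gamma(p * D, n * D)
    weights = (np.linalg.norm(fit.betas, axis=0) + 1.0 / (n * D)) ** (-gamma)
    kernel = GroupedCvKernel(X_list, y_list, weights)
    _, _, lam2 = cv_lambda_path(kernel, n, cfg)
    fit2 = grouped_lasso_fit(X_list, y_list, lam2, weights=weights)
    return fit2, lam2, weights
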