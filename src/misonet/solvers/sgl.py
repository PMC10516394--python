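"""Sparse-group Lasso by block coordinate proximal descent.

Objective (groups l = 1..m are the omics layers of a model spec):

    min_beta 1/2 ||y - sum_l X_l beta_l||_2^2
             + (1 - alpha) * lam * sum_l sqrt(p_l) ||beta_l||_2
             + alpha * lam * ||beta||_1

alpha = 1 recovers the Lasso, alpha = 0 the group Lasso. The solver cycles
over groups; a group is zeroed when the soft-thresholded gradient condition
holds, otherwise it runs proximal-gradient steps within the block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ._kernels import cd_sgl
from .standardize import SolverError, soft_threshold


@dataclass
class SparseGroupProblem:
    """A complete-data sparse-group design: y, per-group submatrices, penalty."""

    y: np.ndarray
    X_groups: list[tuple[str, np.ndarray]]
    alpha_mix: float = 0.5
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_mix <= 1:
            raise ValueError("alpha_mix must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        n = len(self.y)
        for label, X in self.X_groups:
            if X.shape[0] != n:
                raise ValueError(f"group {label!r} has {X.shape[0]} rows, expected {n}")
            if np.isnan(X).any():
                raise ValueError(f"group {label!r} contains NaN; SGL needs a complete design")

    @property
    def p_l(self) -> list[int]:
        return [X.shape[1] for _, X in self.X_groups]

    def design(self) -> np.ndarray:
        return np.hstack([X for _, X in self.X_groups])


def _group_slices(p_l: list[int]) -> list[slice]:
    out, start = [], 0
    for p in p_l:
        out.append(slice(start, start + p))
        start += p
    return out


def sgl_objective(prob: SparseGroupProblem, beta: np.ndarray) -> float:
    X = prob.design()
    r = prob.y - X @ beta
    val = 0.5 * float(r @ r) + prob.alpha_mix * prob.lam * float(np.abs(beta).sum())
    for sl, p in zip(_group_slices(prob.p_l), prob.p_l):
        val += (1 - prob.alpha_mix) * prob.lam * np.sqrt(p) * float(np.linalg.norm(beta[sl]))
    return val


def _group_zero_lambda(c: np.ndarray, alpha: float, p: int) -> float:
    """Smallest lam zeroing a group with gradient c = X_l' y."""
    if alpha == 0:
        return float(np.linalg.norm(c) / np.sqrt(p))
    if alpha == 1:
        return float(np.abs(c).max()) if c.size else 0.0
    hi = float(np.abs(c).max()) / alpha + 1e-12
    if hi <= 0:
        return 0.0

    def g(lam: float) -> float:
        return float(np.linalg.norm(soft_threshold(c, alpha * lam))) - (1 - alpha) * lam * np.sqrt(p)

    if g(1e-14) <= 0:
        return 0.0
    return float(brentq(g, 1e-14, hi, xtol=1e-12, rtol=1e-12))


def sgl_lambda_max(y: np.ndarray, X_groups: list[tuple[str, np.ndarray]], alpha: float) -> float:
    """Smallest lambda at which the all-zero solution is stationary."""
    return max(
        _group_zero_lambda(X.T @ y, alpha, X.shape[1]) for _, X in X_groups
    )


def sparse_group_lasso_fit(
    prob: SparseGroupProblem,
    beta0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 20000,
) -> np.ndarray:
    """Minimize the sparse-group objective; returns the coefficient vector.

    Raises SolverError (with the iteration count) on non-convergence.
    """
    lam, alpha = prob.lam, prob.alpha_mix
    Xs = [X for _, X in prob.X_groups]
    p_l = prob.p_l
    slices = _group_slices(p_l)
    p_tot = sum(p_l)
    y = prob.y
    if lam == 0:
        X = prob.design()
        if p_tot == 0:
            return np.zeros(0)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return beta
    beta = np.zeros(p_tot) if beta0 is None else beta0.copy()
    X = prob.design()
    G = np.ascontiguousarray(X.T @ X)
    c = X.T @ y
    gstart = np.array([sl.start for sl in slices], dtype=np.int64)
    glen = np.array(p_l, dtype=np.int64)
    # per-block Lipschitz constants (largest eigenvalue of each diagonal block)
    Lg = np.array([
        max(float(np.linalg.eigvalsh(G[sl, sl]).max()), 1e-12) for sl in slices
    ])
    sqrt_pl = np.sqrt(np.array(p_l, dtype=float))
    status = cd_sgl(G, c, gstart, glen, Lg, sqrt_pl, float(alpha), float(lam), beta, tol, max_iter)
    if status < 0:
        raise SolverError(f"sparse-group Lasso did not converge in {max_iter} iterations")
    return beta


class SglCvKernel:
    """CV kernel for the sparse-group Lasso on a complete standardized design."""

    def __init__(self, y: np.ndarray, X_groups: list[tuple[str, np.ndarray]], alpha: float):
        self.y = y
        self.X_groups = X_groups
        self.alpha = alpha

    def _sub(self, rows: np.ndarray | None) -> tuple[np.ndarray, list[tuple[str, np.ndarray]]]:
        if rows is None:
            return self.y, self.X_groups
        return self.y[rows], [(l, X[rows]) for l, X in self.X_groups]

    def lambda_max(self, rows: np.ndarray | None = None) -> float:
        y, Xg = self._sub(rows)
        return sgl_lambda_max(y, Xg, self.alpha)

    def fit_path(self, rows: np.ndarray | None, lambdas: np.ndarray) -> list[np.ndarray]:
        y, Xg = self._sub(rows)
        out, warm = [], None
        for lam in lambdas:
            prob = SparseGroupProblem(y, Xg, self.alpha, float(lam))
            warm = sparse_group_lasso_fit(prob, beta0=warm)
            out.append(warm.copy())
        return out

    def val_error(self, beta: np.ndarray, rows: np.ndarray) -> float:
        y, Xg = self._sub(rows)
        X = np.hstack([M for _, M in Xg])
        r = y - X @ beta
        return float(r @ r) / len(y)


def sgl_cv_fit(
    y: np.ndarray,
    X_groups: list[tuple[str, np.ndarray]],
    alpha: float,
    cfg,
) -> tuple[np.ndarray, float]:
    """5-fold CV over the lambda path; returns (beta at chosen lambda, lambda)."""
    from .cv import cv_lambda_path

    kernel = SglCvKernel(y, X_groups, alpha)
    _, _, lam = cv_lambda_path(kernel, len(y), cfg)
    beta = sparse_group_lasso_fit(SparseGroupProblem(y, X_groups, alpha, lam))
    return beta, lam
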