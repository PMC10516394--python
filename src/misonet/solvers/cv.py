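"""Shared cross-validation protocol: geometric lambda path + k-fold CV.

Every estimator exposes a small "kernel" with three capabilities: the
stationarity bound ``lambda_max`` (smallest lambda giving the all-zero
solution), a warm-started path fit on a row subset, and a held-out error.
The grid runs geometrically from lambda_max down to
lambda_max * lambda_min_ratio; lambda_max is taken over the full data and
all training folds so the largest grid point yields an empty model in every
fit. Ties in CV error resolve to the larger lambda (sparser model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np


@dataclass
class CvConfig:
    n_folds: int = 5
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    alpha_weight_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


class CvKernel(Protocol):
    def lambda_max(self, rows: np.ndarray | None = None) -> float: ...

    def fit_path(self, rows: np.ndarray | None, lambdas: np.ndarray) -> list: ...

    def val_error(self, model, rows: np.ndarray) -> float: ...


def lambda_grid(lam_max: float, n_lambda: int, ratio: float) -> np.ndarray:
    """Strictly decreasing geometric grid from lam_max to lam_max * ratio."""
    if lam_max <= 0:
        # degenerate problem (e.g. y uncorrelated with everything); still
        # return a usable grid around a tiny positive value
        lam_max = 1e-8
    return lam_max * np.power(ratio, np.linspace(0.0, 1.0, n_lambda))


def make_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle split of range(n) into n_folds validation index sets."""
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def cv_lambda_path(
    kernel: CvKernel, n_samples: int, cfg: CvConfig
) -> tuple[np.ndarray, np.ndarray, float]:
    """Run the k-fold lambda-path CV and return (grid, mean errors, chosen)."""
    folds = make_folds(n_samples, cfg.n_folds, cfg.seed)
    all_rows = np.arange(n_samples)
    train_sets = [np.setdiff1d(all_rows, val) for val in folds]
    lam_max = kernel.lambda_max(None)
    for tr in train_sets:
        lam_max = max(lam_max, kernel.lambda_max(tr))
    grid = lambda_grid(lam_max, cfg.n_lambda, cfg.lambda_min_ratio)
    errors = np.zeros((cfg.n_folds, cfg.n_lambda))
    for f, (tr, val) in enumerate(zip(train_sets, folds)):
        models = kernel.fit_path(tr, grid)
        errors[f] = [kernel.val_error(m, val) for m in models]
    mean_err = errors.mean(axis=0)
    chosen = float(grid[int(np.argmin(mean_err))])  # first index = largest lambda
    return grid, mean_err, chosen
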