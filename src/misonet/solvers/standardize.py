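"""Column standardization with missing-data support and back-transform."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Raised on solver failures (non-convergence, degenerate input)."""


@dataclass
class StandardizationRecord:
    """Scaling applied to (X, y); allows mapping coefficients back.

    Columns are centred and scaled to unit population SD using observed
    entries only; y is centred (not scaled). ``kept`` lists the column
    indices that survived (zero-variance columns are dropped).
    """

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    kept: np.ndarray  # indices into the original columns

    def back_transform(self, beta_std: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (beta on the raw scale over original columns, intercept)."""
        p_orig = len(self.x_mean)
        beta = np.zeros(p_orig)
        beta[self.kept] = beta_std / self.x_sd[self.kept]
        intercept = self.y_mean - float(beta[self.kept] @ self.x_mean[self.kept])
        return beta, intercept


def standardize(
    X: np.ndarray, y: np.ndarray, min_sd: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, StandardizationRecord]:
    """Centre/scale X columns and centre y using observed entries only.

    NaNs are preserved in place. Zero-variance columns are dropped with a
    warning and recorded so back-transformed coefficient vectors keep the
    original column count (dropped columns get coefficient 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs <= 1).any():
        j = int(np.argmax(n_obs <= 1))
        raise SolverError(f"column {j} has {n_obs[j]} observed values; need > 1")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=0)
    kept = np.flatnonzero(sd > min_sd)
    if len(kept) < X.shape[1]:
        logger.warning("dropping %d zero-variance columns", X.shape[1] - len(kept))
    Xs = (X[:, kept] - mean[kept]) / sd[kept]
    y_mean = float(np.nanmean(y))
    ys = y - y_mean
    return Xs, ys, StandardizationRecord(mean, sd, y_mean, kept)


def soft_threshold(z: np.ndarray | float, t: np.ndarray | float):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)
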