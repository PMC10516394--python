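"""Single kNN imputation and network-guided multiple imputation (ngMICE).

kNN imputation works in feature space, per omics layer: a missing cell is
filled with the unweighted mean of the k nearest features (Euclidean
distance over co-observed samples, scaled by the number of co-observed
samples). Features missing more than ``rowmax`` fall back to the
per-sample mean; samples missing at least ``colmax`` of their features are
excluded from distance computation; feature sets larger than ``maxp`` are
recursively bisected by 2-means clustering before imputation.

ngMICE is multiple imputation by chained equations whose predictor set for
each incomplete feature is restricted to its prior-network neighbours
(correlation-filtered, with a top-k fallback), making MICE tractable on
omics-scale feature counts. Draws use predictive mean matching, so imputed
values always belong to the target's observed support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import MultiOmicsDataset, OmicsMatrix, PriorNetwork

logger = logging.getLogger(__name__)


class ImputationError(RuntimeError):
    pass


@dataclass
class KnnConfig:
    k: int = 10
    rowmax: float = 0.5  # max missing fraction per feature before mean fallback
    colmax: float = 0.8  # samples at/above this missingness are excluded from distances
    maxp: int = 1500  # largest feature block imputed without recursive splitting
    split: str = "kmeans"  # "kmeans" | "chunk"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rowmax <= 1 or not 0 < self.colmax <= 1:
            raise ValueError("rowmax and colmax must be in (0, 1]")
        if self.k < 1 or self.maxp < 1:
            raise ValueError("k and maxp must be positive")


@dataclass
class NgMiceConfig:
    D: int = 5
    r_threshold: float = 0.1
    k_top: int = 5
    n_iterations: int = 5
    n_donors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 1 or self.k_top < 1:
            raise ValueError("D and k_top must be >= 1")
        if not 0 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [0, 1]")


@dataclass
class ImputationSet:
    """D completed copies of a dataset; observed entries identical in all."""

    completed: list[MultiOmicsDataset]
    method: str
    seed: int

    @property
    def D(self) -> int:
        return len(self.completed)


# ------------------------------------------------------------------- kNN


def _pairwise_feature_dist2(vals: np.ndarray) -> np.ndarray:
    """Mean squared difference between feature columns over co-observed rows."""
    M = (~np.isnan(vals)).astype(float)
    Xz = np.nan_to_num(vals, nan=0.0)
    sq = Xz**2
    t1 = sq.T @ M  # sum of x_j^2 over co-observed rows
    cross = Xz.T @ Xz
    n_co = M.T @ M
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(n_co > 0, (t1 + t1.T - 2 * cross) / np.maximum(n_co, 1), np.inf)
    np.fill_diagonal(d2, np.inf)
    return d2


def _knn_fill_block(vals: np.ndarray, cols: np.ndarray, cfg: KnnConfig,
                    eligible_rows: np.ndarray, row_means: np.ndarray) -> None:
    """Impute missing cells of vals[:, cols] in place using kNN within the block."""
    sub = vals[np.ix_(eligible_rows, cols)]
    d2 = _pairwise_feature_dist2(sub)
    order = np.argsort(d2, axis=1, kind="stable")
    block = vals[:, cols]
    mask = ~np.isnan(block)
    miss_frac = 1.0 - mask.mean(axis=0)
    col_means = np.nanmean(np.where(mask, block, np.nan), axis=0)
    for jj in range(len(cols)):
        missing_rows = np.flatnonzero(~mask[:, jj])
        if missing_rows.size == 0:
            continue
        if miss_frac[jj] > cfg.rowmax:
            # too sparse a feature: per-sample mean over observed features
            for i in missing_rows:
                v = row_means[i]
                vals[i, cols[jj]] = v if np.isfinite(v) else col_means[jj]
            continue
        neighbours = [c for c in order[jj] if np.isfinite(d2[jj, c])]
        for i in missing_rows:
            donors = []
            for c in neighbours:
                if mask[i, c]:
                    donors.append(block[i, c])
                    if len(donors) == cfg.k:
                        break
            if donors:
                vals[i, cols[jj]] = float(np.mean(donors))
            elif np.isfinite(row_means[i]):
                vals[i, cols[jj]] = row_means[i]
            elif np.isfinite(col_means[jj]):
                vals[i, cols[jj]] = col_means[jj]
            else:
                raise ImputationError(
                    f"cannot impute column {cols[jj]}: sample {i} has every feature "
                    "missing and the feature has no observed values"
                )


def _split_features(vals: np.ndarray, cols: np.ndarray, cfg: KnnConfig, depth: int) -> list[np.ndarray]:
    if len(cols) <= cfg.maxp:
        return [cols]
    if cfg.split == "chunk":
        mid = len(cols) // 2
        halves = [cols[:mid], cols[mid:]]
    else:
        from sklearn.cluster import KMeans

        sub = vals[:, cols]
        filled = np.where(np.isnan(sub), np.nanmean(sub, axis=0), sub).T
        km = KMeans(n_clusters=2, n_init=1, random_state=cfg.seed + depth).fit(filled)
        a = cols[km.labels_ == 0]
        b = cols[km.labels_ == 1]
        if len(a) == 0 or len(b) == 0:  # degenerate clustering
            mid = len(cols) // 2
            halves = [cols[:mid], cols[mid:]]
        else:
            halves = [a, b]
    out: list[np.ndarray] = []
    for h in halves:
        out.extend(_split_features(vals, h, cfg, depth + 1))
    return out


def knn_impute(matrix: OmicsMatrix, cfg: KnnConfig | None = None) -> OmicsMatrix:
    """Feature-space k-nearest-neighbour imputation of one layer."""
    cfg = cfg or KnnConfig()
    vals = matrix.values.to_numpy(dtype=float).copy()
    if not np.isnan(vals).any():
        return matrix.copy()
    if matrix.n_features < cfg.k + 1:
        raise ImputationError(
            f"kNN imputation needs at least k+1={cfg.k + 1} features, got {matrix.n_features}"
        )
    mask = ~np.isnan(vals)
    sample_miss = 1.0 - mask.mean(axis=1)
    eligible_rows = np.flatnonzero(sample_miss < cfg.colmax)
    if eligible_rows.size == 0:
        eligible_rows = np.arange(vals.shape[0])
    n_obs_row = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        row_means = np.where(
            n_obs_row > 0, np.nansum(np.where(mask, vals, 0.0), axis=1) / np.maximum(n_obs_row, 1), np.nan
        )
    for cols in _split_features(vals, np.arange(vals.shape[1]), cfg, 0):
        _knn_fill_block(vals, cols, cfg, eligible_rows, row_means)
    if matrix.layer == "methylation":
        vals = np.clip(vals, 0.0, 1.0)
    return OmicsMatrix(
        matrix.layer, pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns)
    )


def knn_impute_dataset(ds: MultiOmicsDataset, cfg: KnnConfig | None = None) -> MultiOmicsDataset:
    """Apply kNN imputation separately to each omics layer (and covariates).

    k is capped at n_features - 1 for layers smaller than k + 1 features.
    """
    cfg = cfg or KnnConfig()

    def per_layer(m: OmicsMatrix) -> OmicsMatrix:
        k = min(cfg.k, max(m.n_features - 1, 1))
        if k < cfg.k:
            logger.debug("layer %r: capping k at %d (only %d features)", m.layer, k, m.n_features)
        return knn_impute(m, replace(cfg, k=k))

    layers = {name: per_layer(m) for name, m in ds.layers.items()}
    cov = ds.covariates
    if cov is not None and not cov.mask.all().all():
        cov = per_layer(cov)
    elif cov is not None:
        cov = cov.copy()
    return MultiOmicsDataset(layers, cov)


# ----------------------------------------------------------------- ngMICE


def _stack_dataset(ds: MultiOmicsDataset) -> pd.DataFrame:
    frames = [m.values for m in ds.all_matrices()]
    return pd.concat(frames, axis=1)


def _unstack_dataset(ds: MultiOmicsDataset, df: pd.DataFrame) -> MultiOmicsDataset:
    layers = {
        name: OmicsMatrix(name, df[m.values.columns].copy())
        for name, m in ds.layers.items()
    }
    cov = None
    if ds.covariates is not None:
        cov = OmicsMatrix("covariate", df[ds.covariates.values.columns].copy())
    return MultiOmicsDataset(layers, cov)


def ngmice_predictor_sets(
    dataset: MultiOmicsDataset,
    prior: PriorNetwork,
    cfg: NgMiceConfig | None = None,
) -> dict[str, list[str]]:
    """Predictor sets for every incomplete feature.

    Start from the feature's prior neighbours; keep those whose pairwise-
    complete |Pearson r| meets the threshold; if fewer than k_top survive,
    use the k_top most correlated features over the whole dataset instead.
    """
    cfg = cfg or NgMiceConfig()
    df = _stack_dataset(dataset)
    features = list(df.columns)
    idx = {f: j for j, f in enumerate(features)}
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        sds = np.nanstd(vals, axis=0)
    # pairwise-complete correlation matrix
    corr = pd.DataFrame(vals, columns=features).corr(min_periods=2).to_numpy()
    out: dict[str, list[str]] = {}
    for f in features:
        j = idx[f]
        if not np.isnan(vals[:, j]).any():
            continue
        if sds[j] == 0 or np.isnan(sds[j]):
            logger.warning("feature %r has zero variance; cannot build predictors", f)
            continue
        cand: list[tuple[float, int]] = []
        for nb in prior.neighbours(f):
            if nb not in idx:
                continue
            cj = idx[nb]
            if sds[cj] == 0 or np.isnan(sds[cj]):
                logger.warning("skipping zero-variance candidate %r for %r", nb, f)
                continue
            r = corr[j, cj]
            if np.isfinite(r) and abs(r) >= cfg.r_threshold:
                cand.append((abs(r), cj))
        if len(cand) < cfg.k_top:
            with np.errstate(invalid="ignore"):
                r_all = np.abs(corr[j])
            r_all[j] = -np.inf
            r_all[~np.isfinite(r_all)] = -np.inf
            top = np.argsort(-r_all, kind="stable")[: cfg.k_top]
            out[f] = [features[t] for t in top if np.isfinite(r_all[t])]
        else:
            cand.sort(key=lambda t: (-t[0], t[1]))
            out[f] = [features[c] for _, c in cand]
    return out


def _pmm_sweep(
    data: np.ndarray,
    obs_mask: np.ndarray,
    targets: list[int],
    pred_idx: dict[int, np.ndarray],
    rng: np.random.Generator,
    n_donors: int,
) -> None:
    """One chained-equations sweep with predictive mean matching, in place."""
    for j in targets:
        obs = obs_mask[:, j]
        mis = ~obs
        P = pred_idx[j]
        Xo = data[np.ix_(obs, P)]
        Xm = data[np.ix_(mis, P)]
        yo = data[obs, j]
        A = np.column_stack([np.ones(Xo.shape[0]), Xo])
        # tiny ridge keeps near-collinear predictor sets stable
        coef = np.linalg.solve(A.T @ A + 1e-8 * np.eye(A.shape[1]), A.T @ yo)
        fit_obs = A @ coef
        fit_mis = np.column_stack([np.ones(Xm.shape[0]), Xm]) @ coef
        for row, fv in zip(np.flatnonzero(mis), fit_mis):
            d = np.abs(fit_obs - fv)
            donors = np.argsort(d, kind="stable")[:n_donors]
            pick = donors[rng.integers(0, len(donors))]
            data[row, j] = yo[pick]


def ngmice_impute(
    dataset: MultiOmicsDataset,
    prior: PriorNetwork,
    cfg: NgMiceConfig | None = None,
) -> ImputationSet:
    """D chained-equation runs with prior-restricted predictor sets.

    Each run initializes missing cells with random draws from the feature's
    observed values, then performs ``n_iterations`` sweeps in fixed feature
    order, refitting each incomplete feature on its predictor set and
    filling missing cells by predictive mean matching (5 donors).
    Methylation imputations are clipped to [0, 1]. Deterministic given seed.
    """
    cfg = cfg or NgMiceConfig()
    df = _stack_dataset(dataset)
    features = list(df.columns)
    idx = {f: j for j, f in enumerate(features)}
    template = df.to_numpy(dtype=float)
    obs_mask = ~np.isnan(template)
    if obs_mask.all():
        return ImputationSet([dataset.copy() for _ in range(cfg.D)], "ngmice", cfg.seed)
    psets = ngmice_predictor_sets(dataset, prior, cfg)
    targets = []
    pred_idx: dict[int, np.ndarray] = {}
    meth_cols = set()
    if "methylation" in dataset.layers:
        meth_cols = {idx[f] for f in dataset.layers["methylation"].feature_ids}
    for j, f in enumerate(features):
        if obs_mask[:, j].all():
            continue
        preds = psets.get(f, [])
        if not preds:
            raise ImputationError(f"feature {f!r} has missing values but an empty predictor set")
        targets.append(j)
        pred_idx[j] = np.array([idx[p] for p in preds])
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.D)
    completed: list[MultiOmicsDataset] = []
    for d in range(cfg.D):
        rng = np.random.default_rng(seeds[d])
        data = template.copy()
        for j in targets:
            obs_vals = template[obs_mask[:, j], j]
            mis = np.flatnonzero(~obs_mask[:, j])
            data[mis, j] = rng.choice(obs_vals, size=len(mis), replace=True)
        for _ in range(cfg.n_iterations):
            _pmm_sweep(data, obs_mask, targets, pred_idx, rng, cfg.n_donors)
        for j in targets:
            if j in meth_cols:
                mis = ~obs_mask[:, j]
                data[mis, j] = np.clip(data[mis, j], 0.0, 1.0)
        out_df = pd.DataFrame(data, index=df.index, columns=features)
        completed.append(_unstack_dataset(dataset, out_df))
    return ImputationSet(completed, "ngmice", cfg.seed)
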