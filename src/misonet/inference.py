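"""Per-response model fitting, network assembly and stability selection.

Each expression feature is regressed on its prior-restricted predictors
with one of seven back-ends; all models with a nonzero coefficient and
R^2 above the assembly threshold contribute edges to the multi-omics
network. Stability selection repeats the whole inference with distinct
derived seeds and averages coefficients and R^2 before assembly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np

from .datamodel import (
    FitResult,
    ModelSpec,
    MultiOmicsDataset,
    MultiOmicsNetwork,
    NetworkEdge,
    PriorNetwork,
)
from .impute import (
    ImputationError,
    ImputationSet,
    KnnConfig,
    NgMiceConfig,
    knn_impute_dataset,
    ngmice_impute,
)
from .solvers import CvConfig, sgl_cv_fit, stacked_cv_fit, grouped_cv_fit
from .solvers.covariance import cocolasso_fit, hmlasso_fit
from .solvers.standardize import SolverError, standardize

logger = logging.getLogger(__name__)

METHODS = ("knnSGLasso", "SLasso", "SALasso", "GLasso", "GALasso", "CoCoLasso", "HMLasso")

#: Default lambda.min.ratio per estimator family.
_LAMBDA_MIN_RATIO = {
    "knnSGLasso": 1e-2,
    "SLasso": 1e-4,
    "SALasso": 1e-4,
    "GLasso": 1e-4,
    "GALasso": 1e-4,
    "CoCoLasso": 1e-1,
    "HMLasso": 1e-1,
}


def derive_seed(base: int, *parts) -> int:
    """Stable per-task seed below 2**31, independent of execution order."""
    h = zlib.crc32(("|".join(str(p) for p in parts)).encode())
    return (int(base) * 1_000_003 + h) % (2**31 - 1)


def _default_cv(method: str, seed: int) -> CvConfig:
    return CvConfig(lambda_min_ratio=_LAMBDA_MIN_RATIO[method], seed=seed)


def _spec_design(ds: MultiOmicsDataset, spec: ModelSpec) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Return (X, feature names, group label per column, y) for one spec."""
    cols, labels = [], []
    for label, feats in spec.predictor_groups:
        for f in feats:
            cols.append(ds.column(f).to_numpy(dtype=float))
            labels.append(label)
    names = [f for _, feats in spec.predictor_groups for f in feats]
    X = np.column_stack(cols) if cols else np.empty((ds.n_samples, 0))
    y = ds.column(spec.response).to_numpy(dtype=float)
    return X, names, labels, y


def _grouped_design(Xs: np.ndarray, labels: list[str]) -> list[tuple[str, np.ndarray]]:
    groups: list[tuple[str, np.ndarray]] = []
    order = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    for lab in order:
        idx = [j for j, l in enumerate(labels) if l == lab]
        groups.append((lab, Xs[:, idx]))
    return groups


def _r2_rmse(y: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = y - pred
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return min(r2, 1.0), float(np.sqrt(np.mean(resid**2)))


def _fit_sgl(ds_complete, spec, alpha_mix, cv) -> FitResult:
    X, names, labels, y = _spec_design(ds_complete, spec)
    Xs, ys, record = standardize(X, y)
    kept_labels = [labels[j] for j in record.kept]
    groups = _grouped_design(Xs, kept_labels)
    beta_std, lam = sgl_cv_fit(ys, groups, alpha_mix, cv)
    # sgl groups reorder columns label-block-wise; map back
    col_order = [j for lab in dict.fromkeys(kept_labels) for j, l in enumerate(kept_labels) if l == lab]
    beta_unordered = np.zeros(len(kept_labels))
    beta_unordered[col_order] = beta_std
    beta_raw, intercept = record.back_transform(beta_unordered)
    pred = intercept + X @ beta_raw
    r2, rmse = _r2_rmse(y, pred)
    coefs = {f: float(b) for f, b in zip(names, beta_raw)}
    return FitResult(spec.response, coefs, intercept, r2, rmse, lam, {"alpha_mix": alpha_mix})


def _fit_multi_imputed(imp: ImputationSet, spec, method, cv) -> FitResult:
    names = spec.predictors
    X_list, y_list = [], []
    for ds_d in imp.completed:
        X, _, _, y = _spec_design(ds_d, spec)
        X_list.append(X)
        y_list.append(y)
    # pooled standardization across the stacked copies
    X_stack = np.vstack(X_list)
    y_stack = np.concatenate(y_list)
    _, _, record = standardize(X_stack, y_stack)
    kept = record.kept
    Xs_list = [(X[:, kept] - record.x_mean[kept]) / record.x_sd[kept] for X in X_list]
    ys_list = [y - record.y_mean for y in y_list]
    adaptive = method in ("SALasso", "GALasso")
    if method in ("SLasso", "SALasso"):
        beta_std, lam, _ = stacked_cv_fit(Xs_list, ys_list, cv, adaptive=adaptive)
        betas_std = np.tile(beta_std, (imp.D, 1))
    else:
        fit, lam, _ = grouped_cv_fit(Xs_list, ys_list, cv, adaptive=adaptive)
        betas_std = fit.betas
        beta_std = fit.pooled()
    beta_raw, intercept = record.back_transform(beta_std)
    r2s, rmses = [], []
    for d, (X, y) in enumerate(zip(Xs_list, ys_list)):
        pred = X @ betas_std[d]
        r2, rmse = _r2_rmse(y, pred)
        r2s.append(r2)
        rmses.append(rmse)
    coefs = {f: float(b) for f, b in zip(names, beta_raw)}
    return FitResult(
        spec.response, coefs, intercept, float(np.mean(r2s)), float(np.mean(rmses)), lam,
        {"D": imp.D, "adaptive": adaptive},
    )


def _fit_covariance(ds, spec, method, cv) -> FitResult:
    X, names, _, y = _spec_design(ds, spec)
    observed = (~np.isnan(X)).sum(axis=0)
    usable = [j for j in range(X.shape[1]) if observed[j] > 1]
    if len(usable) < X.shape[1]:
        logger.warning("%s %r: dropping %d predictors with <2 observed values",
                       method, spec.response, X.shape[1] - len(usable))
    X = X[:, usable]
    kept_names = [names[j] for j in usable]
    fit_fn = cocolasso_fit if method == "CoCoLasso" else hmlasso_fit
    res = fit_fn(X, y, cv, response=spec.response, feature_names=kept_names)
    coefs = {f: 0.0 for f in names}
    coefs.update(res.coefficients)
    return replace(res, coefficients=coefs)


def fit_all_models(
    ds: MultiOmicsDataset,
    specs: list[ModelSpec],
    method: str,
    seed: int = 0,
    prior: PriorNetwork | None = None,
    imputation_set: ImputationSet | None = None,
    knn: KnnConfig | None = None,
    ngmice: NgMiceConfig | None = None,
    alpha_mix: float = 0.5,
    lambda_min_ratio: float | None = None,
) -> list[FitResult]:
    """Fit one sparse model per spec with the chosen back-end.

    knnSGLasso imputes each layer first (features failing the imputation
    eligibility rule are dropped from specs); the stacked/grouped variants
    share one ngMICE imputation set; CoCoLasso/HMLasso work directly on the
    incomplete data. Results are deterministic given the seed and do not
    depend on the order in which specs are fitted.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    def cv_for(spec: ModelSpec) -> CvConfig:
        cfg = _default_cv(method, derive_seed(seed, method, spec.response))
        if lambda_min_ratio is not None:
            cfg = replace(cfg, lambda_min_ratio=lambda_min_ratio)
        return cfg

    feature_obs = {}
    for m in ds.all_matrices():
        frac = m.mask.mean(axis=0)
        for f in m.feature_ids:
            feature_obs[f] = float(frac[f])

    work_specs = specs
    if method == "knnSGLasso":
        knn = knn or KnnConfig()
        eligible = {f for f, frac in feature_obs.items() if 1.0 - frac <= knn.rowmax and frac > 0}
        dropped = {f for f in feature_obs if f not in eligible}
        if dropped:
            logger.warning("knnSGLasso: %d features fail imputation eligibility and are dropped",
                           len(dropped))
        work_specs = []
        for s in specs:
            if s.response not in eligible:
                continue
            groups = [(lab, [f for f in feats if f in eligible]) for lab, feats in s.predictor_groups]
            groups = [(lab, feats) for lab, feats in groups if feats]
            if any(lab != "covariate" for lab, _ in groups):
                work_specs.append(ModelSpec(s.response, groups))
        ds_complete = knn_impute_dataset(ds, knn)
    elif method in ("SLasso", "SALasso", "GLasso", "GALasso"):
        if imputation_set is None:
            if prior is None:
                raise ValueError(f"{method} needs a prior network or a precomputed imputation set")
            ngmice = ngmice or NgMiceConfig()
            ngmice = replace(ngmice, seed=derive_seed(seed, method, "ngmice"))
            imputation_set = ngmice_impute(ds, prior, ngmice)

    results: list[FitResult] = []
    for spec in work_specs:
        if feature_obs.get(spec.response, 0.0) == 0.0:
            logger.warning("response %r fully missing; model skipped", spec.response)
            continue
        try:
            if method == "knnSGLasso":
                results.append(_fit_sgl(ds_complete, spec, alpha_mix, cv_for(spec)))
            elif method in ("SLasso", "SALasso", "GLasso", "GALasso"):
                results.append(_fit_multi_imputed(imputation_set, spec, method, cv_for(spec)))
            else:
                results.append(_fit_covariance(ds, spec, method, cv_for(spec)))
        except (SolverError, ImputationError, np.linalg.LinAlgError) as exc:
            logger.warning("model for %r failed (%s); skipped", spec.response, exc)
    return results


def assemble_network(
    fits: list[FitResult],
    r2_threshold: float = 0.1,
    layer_of: dict[str, str] | None = None,
    include_covariates: bool = False,
) -> MultiOmicsNetwork:
    """Edges for every nonzero coefficient of a model with R^2 > threshold."""
    layer_of = layer_of or {}
    edges: list[NetworkEdge] = []
    for fit in fits:
        if not fit.r2 > r2_threshold:
            continue
        for pred, coef in fit.coefficients.items():
            if coef == 0.0:
                continue
            if not include_covariates and layer_of.get(pred) == "covariate":
                continue
            edges.append(NetworkEdge(fit.response, pred, float(coef), float(fit.r2)))
    return MultiOmicsNetwork(edges, layer_of)


def stability_selection(
    ds: MultiOmicsDataset,
    specs: list[ModelSpec],
    method: str,
    n_repeats: int = 100,
    seed: int = 0,
    r2_threshold: float = 0.1,
    max_failure_fraction: float = 0.1,
    **fit_kwargs,
) -> MultiOmicsNetwork:
    """Average coefficients and R^2 over repeated fits, then assemble.

    Each repeat uses a distinct derived seed (changing CV folds and any
    imputation randomness). A predictor absent from a repeat contributes a
    zero coefficient; more than ``max_failure_fraction`` failed repeats is
    an error.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    coef_sum: dict[str, dict[str, float]] = {s.response: {p: 0.0 for p in s.predictors} for s in specs}
    r2_sum: dict[str, float] = {s.response: 0.0 for s in specs}
    failures = 0
    for rep in range(n_repeats):
        rep_seed = derive_seed(seed, "stability", rep)
        try:
            fits = fit_all_models(ds, specs, method, seed=rep_seed, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - repeat-level robustness
            failures += 1
            logger.warning("stability repeat %d failed: %s", rep, exc)
            continue
        for fit in fits:
            acc = coef_sum.get(fit.response)
            if acc is None:
                continue
            for pred, coef in fit.coefficients.items():
                if pred in acc:
                    acc[pred] += coef
            r2_sum[fit.response] += fit.r2
    if failures > max_failure_fraction * n_repeats:
        raise SolverError(f"{failures}/{n_repeats} stability repeats failed")
    n_ok = n_repeats - failures
    avg_fits = [
        FitResult(
            resp,
            {p: v / n_ok for p, v in acc.items()},
            0.0,
            min(r2_sum[resp] / n_ok, 1.0),
            0.0,
            0.0,
        )
        for resp, acc in coef_sum.items()
    ]
    layer_of = ds.feature_index()
    return assemble_network(avg_fits, r2_threshold, layer_of)
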