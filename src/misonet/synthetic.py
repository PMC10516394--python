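"""Synthetic triple-omics data with known regulatory structure.

Generates transcriptomics / CNV / methylation datasets whose expression
layer follows linear cross-layer effects over a heavy-tailed prior network,
plus age/sex covariates, and applies the benchmark perturbations: random
entry missingness (single- or multi-layer), block-wise layer missingness,
feature-specific Gaussian noise, and sample downsampling.

Presets mirror the two layer-dimension regimes of interest at desk scale:
``imbalanced`` (many genes, few CNVs; 500/30/80) and ``balanced``
(200/200/200).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import MultiOmicsDataset, OmicsMatrix, PriorNetwork

logger = logging.getLogger(__name__)

PRESETS = {
    "imbalanced": dict(n_genes=500, n_cnv=30, n_meth=80),
    "balanced": dict(n_genes=200, n_cnv=200, n_meth=200),
}

#: Fraction of prior links that carry a true effect; the remainder are
#: decoy prior edges with no effect, as generic interactome priors contain
#: many links irrelevant to any one expression dataset.
DEFAULT_EFFECT_PROB = 0.7
DEFAULT_EFFECT_RANGE = (0.3, 1.0)
DEFAULT_NOISE_SD_RANGE = (0.3, 0.8)


@dataclass
class GroundTruth:
    """A prior network plus the subset of links that truly carry effects."""

    prior: PriorNetwork
    true_edges: set[tuple[str, str, float]]  # (response gene, predictor, effect)
    noise_sd: dict[str, float]

    def true_edge_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((r, p))) for r, p, _ in self.true_edges}


@dataclass
class MissingnessScenario:
    """One benchmark perturbation: kind, missing fraction m, noise scale a."""

    kind: str  # single_random | multi_random | block | downsample
    m: float = 0.0
    noise_scale: float = 0.0
    target_layers: list[str] = field(default_factory=lambda: ["expression"])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("single_random", "multi_random", "block", "downsample"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0 <= self.m <= 0.5:
            raise ValueError("missing fraction m must be in [0, 0.5]")
        if self.noise_scale < 0:
            raise ValueError("noise scale a must be >= 0")


def generate_ground_truth(
    n_genes: int,
    n_cnv: int,
    n_meth: int,
    mean_degree: float,
    seed: int,
    effect_prob: float = DEFAULT_EFFECT_PROB,
    effect_range: tuple[float, float] = DEFAULT_EFFECT_RANGE,
    noise_sd_range: tuple[float, float] = DEFAULT_NOISE_SD_RANGE,
) -> GroundTruth:
    """Sample a prior with heavy-tailed gene degrees and its true effects.

    Gene-gene links are drawn with endpoint probabilities proportional to
    Pareto-distributed propensities (hub genes). Every CNV and methylation
    feature is mapped to exactly one gene. Each prior link carries a true
    effect with probability ``effect_prob``; effect magnitudes are uniform
    on ``effect_range`` with random sign, acting on standardized predictors.
    Effects between genes point from the lower-index to the higher-index
    gene so the structural model is acyclic.
    """
    if min(n_genes, n_cnv, n_meth) < 1:
        raise ValueError("all feature counts must be >= 1")
    if mean_degree >= n_genes:
        raise ValueError("mean_degree must be < n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    cnvs = [f"cnv{i}" for i in range(n_cnv)]
    meths = [f"me{i}" for i in range(n_meth)]
    layer_of = {g: "expression" for g in genes}
    layer_of.update({c: "cnv" for c in cnvs})
    layer_of.update({m: "methylation" for m in meths})

    # heavy-tailed degree propensities
    w = rng.pareto(2.0, n_genes) + 1.0
    p = w / w.sum()
    n_edges_target = int(round(n_genes * mean_degree / 2))
    edges: set[tuple[str, str]] = set()
    guard = 0
    while len(edges) < n_edges_target and guard < 50 * n_edges_target:
        i, j = rng.choice(n_genes, size=2, p=p)
        guard += 1
        if i == j:
            continue
        a, b = (genes[i], genes[j]) if i < j else (genes[j], genes[i])
        edges.add((a, b))

    # map each CNV / methylation feature to one gene
    cnv_gene = rng.integers(0, n_genes, n_cnv)
    meth_gene = rng.integers(0, n_genes, n_meth)
    for c, gi in zip(cnvs, cnv_gene):
        edges.add(tuple(sorted((c, genes[gi]))))
    for m_, gi in zip(meths, meth_gene):
        edges.add(tuple(sorted((m_, genes[gi]))))

    prior = PriorNetwork(edges, layer_of)

    lo, hi = effect_range
    true_edges: set[tuple[str, str, float]] = set()
    gene_index = {g: i for i, g in enumerate(genes)}
    for a, b in sorted(prior.edges):
        if rng.random() >= effect_prob:
            continue
        size = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
        la, lb = layer_of[a], layer_of[b]
        if la == "expression" and lb == "expression":
            # predictor = lower index, response = higher index (acyclic)
            pred, resp = (a, b) if gene_index[a] < gene_index[b] else (b, a)
        elif la == "expression":
            resp, pred = a, b
        else:
            resp, pred = b, a
        true_edges.add((resp, pred, float(size)))

    noise_sd = {g: float(rng.uniform(*noise_sd_range)) for g in genes}
    return GroundTruth(prior, true_edges, noise_sd)


def simulate_dataset(gt: GroundTruth, n_samples: int, seed: int) -> MultiOmicsDataset:
    """Draw a complete dataset from the ground-truth structural model.

    CNVs are standard normal; methylation beta values arise from a logistic
    transform of a Gaussian latent (so they stay in (0, 1)); expression is
    a linear combination of the standardized true predictors plus
    N(0, sigma_g^2) gene noise. Covariates age and sex are simulated and
    carried in their own layer.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    rng = np.random.default_rng(seed)
    layer_of = gt.prior.layer_of
    genes = sorted((f for f, l in layer_of.items() if l == "expression"),
                   key=lambda g: int(g[1:]))
    cnvs = sorted((f for f, l in layer_of.items() if l == "cnv"),
                  key=lambda c: int(c[3:]))
    meths = sorted((f for f, l in layer_of.items() if l == "methylation"),
                   key=lambda m: int(m[2:]))
    samples = [f"s{i}" for i in range(n_samples)]

    cnv_vals = rng.normal(0.0, 1.0, (n_samples, len(cnvs)))
    meth_latent = rng.normal(0.0, 1.0, (n_samples, len(meths)))
    meth_vals = 1.0 / (1.0 + np.exp(-meth_latent))

    columns: dict[str, np.ndarray] = {}
    for c, col in zip(cnvs, cnv_vals.T):
        columns[c] = col
    for m_, col in zip(meths, meth_vals.T):
        columns[m_] = col

    by_response: dict[str, list[tuple[str, float]]] = {}
    for resp, pred, eff in gt.true_edges:
        by_response.setdefault(resp, []).append((pred, eff))

    def _z(col: np.ndarray) -> np.ndarray:
        sd = col.std(ddof=0)
        return (col - col.mean()) / sd if sd > 0 else col - col.mean()

    expr_vals = np.empty((n_samples, len(genes)))
    for j, g in enumerate(genes):
        mu = np.zeros(n_samples)
        for pred, eff in sorted(by_response.get(g, [])):
            mu = mu + eff * _z(columns[pred])
        col = mu + rng.normal(0.0, gt.noise_sd[g], n_samples)
        expr_vals[:, j] = col
        columns[g] = col

    age = rng.normal(60.0, 10.0, n_samples)
    sex = rng.integers(0, 2, n_samples).astype(float)

    layers = {
        "expression": OmicsMatrix("expression", pd.DataFrame(expr_vals, index=samples, columns=genes)),
        "cnv": OmicsMatrix("cnv", pd.DataFrame(cnv_vals, index=samples, columns=cnvs)),
        "methylation": OmicsMatrix("methylation", pd.DataFrame(meth_vals, index=samples, columns=meths)),
    }
    cov = OmicsMatrix("covariate", pd.DataFrame({"age": age, "sex": sex}, index=samples))
    return MultiOmicsDataset(layers, cov)


def inject_random_missingness(
    ds: MultiOmicsDataset, layers: Sequence[str], m: float, seed: int
) -> MultiOmicsDataset:
    """Set exactly round(m * n_entries) entries missing per targeted layer."""
    if not 0 <= m <= 1:
        raise ValueError("m must be in [0, 1]")
    out = ds.copy()
    rng = np.random.default_rng(seed)
    for name in layers:
        mat = out.layers[name]
        vals = mat.values.to_numpy()
        n_remove = int(round(m * vals.size))
        if n_remove == 0:
            continue
        observed = np.flatnonzero(~np.isnan(vals).ravel())
        if n_remove > observed.size:
            raise ValueError(
                f"layer {name!r}: cannot remove {n_remove} entries, only {observed.size} observed"
            )
        chosen = rng.choice(observed, size=n_remove, replace=False)
        flat = vals.ravel()
        flat[chosen] = np.nan
        out.layers[name] = OmicsMatrix(
            name, pd.DataFrame(flat.reshape(vals.shape), index=mat.values.index, columns=mat.values.columns)
        )
    return out


def inject_block_missingness(ds: MultiOmicsDataset, m: float, seed: int) -> MultiOmicsDataset:
    """Blank whole layers for floor(m*n) samples per layer, keeping >= 2 layers each.

    Samples are assigned round-robin over a seeded shuffle, alternating
    layers, so that no sample loses more than (n_layers - 2) layers. If the
    constraint makes the requested per-layer count infeasible, the
    achievable count is used and the shortfall logged.
    """
    names = list(ds.layers)
    if len(names) < 2:
        raise ValueError("block missingness needs >= 2 omics layers")
    if not 0 <= m <= 1:
        raise ValueError("m must be in [0, 1]")
    out = ds.copy()
    n = ds.n_samples
    target = int(np.floor(m * n))
    if target == 0:
        return out
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n))
    max_loss = len(names) - 2
    loss = np.zeros(n, dtype=int)
    blocked: dict[str, set[int]] = {name: set() for name in names}
    cursors = {name: 0 for name in names}
    progress = True
    while progress:
        progress = False
        for name in names:
            if len(blocked[name]) >= target:
                continue
            # advance this layer's cursor to the next eligible sample
            while cursors[name] < n:
                s = order[cursors[name]]
                cursors[name] += 1
                if s not in blocked[name] and loss[s] < max_loss:
                    blocked[name].add(s)
                    loss[s] += 1
                    progress = True
                    break
    for name in names:
        short = target - len(blocked[name])
        if short > 0:
            logger.warning(
                "block missingness: layer %r blocked for %d of requested %d samples "
                "(>=2-layers constraint)", name, len(blocked[name]), target
            )
        mat = out.layers[name]
        vals = mat.values.to_numpy().copy()
        vals[sorted(blocked[name]), :] = np.nan
        out.layers[name] = OmicsMatrix(
            name, pd.DataFrame(vals, index=mat.values.index, columns=mat.values.columns)
        )
    return out


def inject_noise(
    ds: MultiOmicsDataset,
    a: float,
    seed: int,
    sd_map: Mapping[str, float] | None = None,
) -> MultiOmicsDataset:
    """Add independent N(0, a * sigma_g^2) noise to every observed entry.

    sigma_g defaults to each feature's sample SD over observed entries;
    methylation values are clipped back to [0, 1]. Masks are unchanged.
    """
    if a < 0:
        raise ValueError("noise scale a must be >= 0")
    out = ds.copy()
    if a == 0:
        return out
    rng = np.random.default_rng(seed)
    for name, mat in out.layers.items():
        vals = mat.values.to_numpy().copy()
        for j, feat in enumerate(mat.values.columns):
            col = vals[:, j]
            obs = ~np.isnan(col)
            if sd_map is not None and feat in sd_map:
                sd = float(sd_map[feat])
            else:
                sd = float(np.nanstd(col, ddof=1)) if obs.sum() > 1 else 0.0
            if sd == 0:
                continue
            col[obs] = col[obs] + rng.normal(0.0, np.sqrt(a) * sd, obs.sum())
        if name == "methylation":
            vals = np.clip(vals, 0.0, 1.0)
        out.layers[name] = OmicsMatrix(
            name, pd.DataFrame(vals, index=mat.values.index, columns=mat.values.columns)
        )
    return out


def downsample(ds: MultiOmicsDataset, keep_fraction: float, seed: int) -> MultiOmicsDataset:
    """Retain round(keep_fraction * n) samples, consistently across layers."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = ds.n_samples
    n_keep = int(round(keep_fraction * n))
    if n_keep < 3:
        raise ValueError(f"downsampling to {n_keep} samples (< 3) not allowed")
    if n_keep == n:
        return ds.copy()
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n_keep, replace=False))
    layers = {
        name: OmicsMatrix(name, mat.values.iloc[keep])
        for name, mat in ds.layers.items()
    }
    cov = OmicsMatrix("covariate", ds.covariates.values.iloc[keep]) if ds.covariates is not None else None
    return MultiOmicsDataset(layers, cov)


def apply_scenario(ds: MultiOmicsDataset, scenario: MissingnessScenario) -> MultiOmicsDataset:
    """Apply one benchmark perturbation (missingness/downsampling, then noise)."""
    seed = scenario.seed
    if scenario.kind == "single_random":
        out = inject_random_missingness(ds, scenario.target_layers, scenario.m, seed)
    elif scenario.kind == "multi_random":
        out = ds
        for i, name in enumerate(ds.layers):
            out = inject_random_missingness(out, [name], scenario.m, seed + i)
    elif scenario.kind == "block":
        out = inject_block_missingness(ds, scenario.m, seed)
    elif scenario.kind == "downsample":
        out = downsample(ds, 1.0 - scenario.m, seed)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(scenario.kind)
    if scenario.noise_scale > 0:
        out = inject_noise(out, scenario.noise_scale, seed + 10_000)
    return out
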