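"""Core data containers for prior-guided multi-omics network inference.

The framework models each expression feature as a response in a sparse
regression whose candidate predictors are restricted by a prior-knowledge
network (gene-gene links plus CNV/methylation features mapped to genes).
These containers hold the layered omics matrices with explicit missingness
masks, the prior, the per-response model specifications derived from it,
and the fitted results that are later assembled into a multi-omics graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised layer labels. Methylation values are beta values in [0, 1].
LAYERS = ("expression", "cnv", "methylation", "covariate")

#: Order in which predictor groups appear in a ModelSpec.
GROUP_ORDER = ("expression", "cnv", "methylation", "covariate")


class DataModelError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataModelError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class OmicsMatrix:
    """A samples x features matrix for one omics layer.

    Missing entries are NaN in ``values``; ``mask`` is True where observed.
    """

    layer: str
    values: pd.DataFrame  # float, NaN = missing

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise DataModelError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        _check_unique(list(self.values.index), "sample id")
        _check_unique(list(self.values.columns), "feature id")
        if self.layer == "methylation":
            bad = (self.values < 0) | (self.values > 1)
            if bad.any().any():
                r, c = np.argwhere(bad.to_numpy())[0]
                raise DataModelError(
                    "methylation beta value outside [0, 1] at sample "
                    f"{self.values.index[r]!r}, feature {self.values.columns[c]!r}: "
                    f"{self.values.iat[r, c]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observation mask (True = observed)."""
        return self.values.notna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.copy())


@dataclass
class MultiOmicsDataset:
    """Ordered omics layers over one shared sample universe.

    A sample that entirely lacks a layer is represented by an all-NaN row in
    that layer (so block-missingness stays representable), never by absence.
    Feature ids must be globally unique across layers; on collision the
    reader prefixes ``layer:``.
    """

    layers: dict[str, OmicsMatrix]
    covariates: OmicsMatrix | None = None

    def __post_init__(self) -> None:
        mats = list(self.layers.values()) + ([self.covariates] if self.covariates is not None else [])
        if not mats:
            raise DataModelError("dataset needs at least one layer")
        ref = mats[0].sample_ids
        for m in mats[1:]:
            if m.sample_ids != ref:
                raise DataModelError(
                    f"layer {m.layer!r} sample ids differ from {mats[0].layer!r}"
                )
        all_feats: list[str] = []
        for m in mats:
            all_feats.extend(m.feature_ids)
        _check_unique(all_feats, "feature id (across layers)")

    @property
    def sample_ids(self) -> list[str]:
        return next(iter(self.layers.values())).sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def layer_of(self, feature: str) -> str:
        for m in self.all_matrices():
            if feature in m.values.columns:
                return m.layer
        raise KeyError(feature)

    def all_matrices(self) -> list[OmicsMatrix]:
        out = list(self.layers.values())
        if self.covariates is not None:
            out.append(self.covariates)
        return out

    def feature_index(self) -> dict[str, str]:
        """Map feature id -> layer label, over all layers and covariates."""
        return {f: m.layer for m in self.all_matrices() for f in m.feature_ids}

    def column(self, feature: str) -> pd.Series:
        for m in self.all_matrices():
            if feature in m.values.columns:
                return m.values[feature]
        raise KeyError(feature)

    def copy(self) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            {k: v.copy() for k, v in self.layers.items()},
            self.covariates.copy() if self.covariates is not None else None,
        )


@dataclass
class PriorNetwork:
    """Undirected prior-knowledge edges over layered feature ids."""

    edges: set[tuple[str, str]]  # stored sorted within each pair
    layer_of: dict[str, str]

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.edges:
            if a == b:
                raise DataModelError(f"self-loop on {a!r}")
            canon.add((a, b) if a <= b else (b, a))
        self.edges = canon
        for a, b in self.edges:
            for node in (a, b):
                if node not in self.layer_of:
                    raise DataModelError(f"no layer assignment for endpoint {node!r}")

    def neighbours(self, node: str) -> list[str]:
        out = [b if a == node else a for a, b in self.edges if node in (a, b)]
        return sorted(out)

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}


@dataclass
class ModelSpec:
    """Predictor groups for one expression response, derived from the prior.

    Groups are ordered (expression neighbours, cnv, methylation, covariates)
    and each group carries the omics-layer label used by the sparse-group
    penalty; ``m`` is the number of non-empty groups.
    """

    response: str
    predictor_groups: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for label, feats in self.predictor_groups:
            if self.response in feats:
                raise DataModelError(f"response {self.response!r} inside predictor group {label!r}")

    @property
    def predictors(self) -> list[str]:
        return [f for _, feats in self.predictor_groups for f in feats]

    @property
    def group_sizes(self) -> list[int]:
        return [len(feats) for _, feats in self.predictor_groups]

    @property
    def m(self) -> int:
        return sum(1 for _, feats in self.predictor_groups if feats)


@dataclass
class FitResult:
    """Fitted sparse regression for one response."""

    response: str
    coefficients: dict[str, float]
    intercept: float
    r2: float
    rmse: float
    lambda_chosen: float
    extra_hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise DataModelError("rmse must be >= 0")
        if self.r2 > 1 + 1e-12:
            raise DataModelError("r2 must be <= 1")
        if self.lambda_chosen < 0:
            raise DataModelError("lambda must be >= 0")


@dataclass(frozen=True)
class NetworkEdge:
    response: str
    predictor: str
    coefficient: float
    model_r2: float


@dataclass
class MultiOmicsNetwork:
    """Assembled multi-omics graph: nonzero effects from well-fitting models."""

    edges: list[NetworkEdge]
    layer_of: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in (e.response, e.predictor)}

    def undirected_edge_set(self) -> set[tuple[str, str]]:
        """Collapse directed records to unordered pairs for comparison metrics."""
        return {tuple(sorted((e.response, e.predictor))) for e in self.edges}

    @property
    def n_edges(self) -> int:
        return len(self.undirected_edge_set())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def build_model_specs(
    prior: PriorNetwork,
    dataset: MultiOmicsDataset,
    include_covariates: bool = True,
) -> list[ModelSpec]:
    """One ModelSpec per expression feature with at least one resolvable predictor.

    Candidate predictors of a gene are its prior neighbours, partitioned by
    omics layer; prior nodes absent from the dataset are dropped (counted and
    logged). Covariates always form their own trailing group when present.
    Deterministic and order-stable: responses in dataset column order, group
    members sorted.
    """
    feat_layer = dataset.feature_index()
    known = set(feat_layer)
    prior_nodes = prior.nodes
    unresolved = prior_nodes - known
    if unresolved:
        logger.warning("dropping %d prior nodes absent from the dataset", len(unresolved))
    if not (prior_nodes & known):
        raise DataModelError("no overlap between prior features and dataset features")

    if "expression" not in dataset.layers:
        raise DataModelError("dataset has no expression layer")
    expr_features = dataset.layers["expression"].feature_ids
    cov_features = dataset.covariates.feature_ids if include_covariates and dataset.covariates is not None else []

    # adjacency restricted to resolvable nodes
    adj: dict[str, set[str]] = {}
    for a, b in prior.edges:
        if a in known and b in known:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)

    specs: list[ModelSpec] = []
    for gene in expr_features:
        neigh = adj.get(gene, set())
        by_layer: dict[str, list[str]] = {}
        for nb in sorted(neigh):
            by_layer.setdefault(feat_layer[nb], []).append(nb)
        groups: list[tuple[str, list[str]]] = []
        for label in ("expression", "cnv", "methylation"):
            feats = by_layer.get(label, [])
            if feats:
                groups.append((label, feats))
        if not groups:
            continue  # no resolvable omics predictor: no model for this gene
        if cov_features:
            groups.append(("covariate", list(cov_features)))
        specs.append(ModelSpec(gene, groups))
    return specs
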