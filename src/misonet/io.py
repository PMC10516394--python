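"""Readers and writers for omics matrices, prior edge lists and networks.

Matrix files are TSV with a header row of feature ids and a first column of
sample ids; missing entries are the literal ``NA`` or an empty cell, and are
written back as ``NA``. Priors are two-column edge lists. Networks are
written as TSV edge tables or GraphML.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (
    DataModelError,
    MultiOmicsDataset,
    MultiOmicsNetwork,
    NetworkEdge,
    OmicsMatrix,
    PriorNetwork,
)

logger = logging.getLogger(__name__)

_NA_TOKENS = ("NA", "")


def read_omics_matrix(path: str | Path, layer: str) -> OmicsMatrix:
    """Read one layer from TSV; NA/empty cells become missing entries."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    features = header[1:]
    seen: set[str] = set()
    for f in features:
        if f in seen:
            raise DataModelError(f"duplicate feature id {f!r} in {path}")
        seen.add(f)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(_NA_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    df.columns = features
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataModelError(f"duplicate sample id {dup!r} in {path}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        # locate the offending cell for a usable error message
        for c in df.columns:
            for r in df.index:
                cell = df.at[r, c]
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise DataModelError(
                            f"non-numeric cell {cell!r} at sample {r!r}, feature {c!r} in {path}"
                        ) from None
        raise
    return OmicsMatrix(layer, values.astype(float))


def write_omics_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="sample")


def read_prior_network(
    path: str | Path, layer_map: Mapping[str, str]
) -> PriorNetwork:
    """Read a two-column edge list; undirected, deduplicated.

    Self-loop lines are skipped with a warning; endpoints missing from
    ``layer_map`` are an error.
    """
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataModelError(f"line {lineno} of {path} has fewer than two columns")
            a, b = parts[0], parts[1]
            if a == b:
                logger.warning("skipping self-loop %r at line %d of %s", a, lineno, path)
                continue
            for node in (a, b):
                if node not in layer_map:
                    raise DataModelError(
                        f"endpoint {node!r} (line {lineno} of {path}) has no layer assignment"
                    )
            edges.add((a, b) if a <= b else (b, a))
    return PriorNetwork(edges, dict(layer_map))


def write_prior_network(prior: PriorNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(prior.edges):
            fh.write(f"{a}\t{b}\n")


_NET_COLUMNS = ["response", "predictor", "coefficient", "model_r2", "response_layer", "predictor_layer"]


def write_network(net: MultiOmicsNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write an assembled network as a TSV edge table or GraphML."""
    if format == "tsv":
        rows = [
            {
                "response": e.response,
                "predictor": e.predictor,
                "coefficient": e.coefficient,
                "model_r2": e.model_r2,
                "response_layer": net.layer_of.get(e.response, ""),
                "predictor_layer": net.layer_of.get(e.predictor, ""),
            }
            for e in sorted(net.edges, key=lambda e: (e.response, e.predictor))
        ]
        pd.DataFrame(rows, columns=_NET_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        g = nx.DiGraph()
        for n in sorted(net.nodes):
            g.add_node(n, layer=net.layer_of.get(n, ""))
        for e in net.edges:
            g.add_edge(e.response, e.predictor, coefficient=e.coefficient, model_r2=e.model_r2)
        nx.write_graphml(g, path)
    else:
        raise DataModelError(f"unknown network format {format!r}; expected 'tsv' or 'graphml'")


def read_network(path: str | Path, format: str = "tsv") -> MultiOmicsNetwork:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"response": str, "predictor": str})
        edges = [
            NetworkEdge(r.response, r.predictor, float(r.coefficient), float(r.model_r2))
            for r in df.itertuples()
        ]
        layer_of = {}
        for r in df.itertuples():
            if isinstance(r.response_layer, str) and r.response_layer:
                layer_of[r.response] = r.response_layer
            if isinstance(r.predictor_layer, str) and r.predictor_layer:
                layer_of[r.predictor] = r.predictor_layer
        return MultiOmicsNetwork(edges, layer_of)
    elif format == "graphml":
        g = nx.read_graphml(path)
        edges = [
            NetworkEdge(u, v, float(d["coefficient"]), float(d["model_r2"]))
            for u, v, d in g.edges(data=True)
        ]
        layer_of = {n: d.get("layer", "") for n, d in g.nodes(data=True) if d.get("layer")}
        return MultiOmicsNetwork(edges, layer_of)
    raise DataModelError(f"unknown network format {format!r}; expected 'tsv' or 'graphml'")


def write_dataset(ds: MultiOmicsDataset, directory: str | Path) -> None:
    """Write each layer (and covariates) as ``<layer>.tsv`` under a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, m in ds.layers.items():
        write_omics_matrix(m, directory / f"{name}.tsv")
    if ds.covariates is not None:
        write_omics_matrix(ds.covariates, directory / "covariate.tsv")


def read_dataset(directory: str | Path, layers: list[str] | None = None) -> MultiOmicsDataset:
    directory = Path(directory)
    if layers is None:
        # only recognised omics layer files; priors/manifests live alongside
        layers = [
            p.stem
            for p in sorted(directory.glob("*.tsv"))
            if p.stem in ("expression", "cnv", "methylation")
        ]
    mats = {name: read_omics_matrix(directory / f"{name}.tsv", name) for name in layers}
    cov_path = directory / "covariate.tsv"
    cov = read_omics_matrix(cov_path, "covariate") if cov_path.exists() else None
    return MultiOmicsDataset(mats, cov)
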