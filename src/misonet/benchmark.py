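"""Configuration-driven benchmark: generate -> perturb -> infer -> evaluate.

A single config document (YAML/JSON-compatible dict) with sections
``data``, ``scenario``, ``method``, ``evaluation``, ``output`` drives the
whole pipeline. Each (method, kind, m, a) cell is repeated ``n_repeats``
times with derived seeds (suite seed -> scenario seed -> repeat seed); the
result is one tidy row per repeat plus a mean +/- SD summary. Reference
networks (full-data, and optionally stability-selected) are computed once
per (dataset, method).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import build_model_specs
from .evaluation import edge_f1, topology_metrics
from .inference import METHODS, assemble_network, derive_seed, fit_all_models, stability_selection
from .io import read_dataset, read_prior_network, write_network
from .synthetic import (
    PRESETS,
    MissingnessScenario,
    apply_scenario,
    generate_ground_truth,
    simulate_dataset,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"data", "scenario", "method", "evaluation", "output", "seed"}
_DATA_KEYS = {"preset", "n_genes", "n_cnv", "n_meth", "mean_degree", "n_samples", "path", "prior_path", "seed"}
_SCENARIO_KEYS = {"kind", "m", "a", "target_layers"}
_EVAL_KEYS = {"r2_threshold", "n_repeats", "stability_reference", "stability_repeats"}

_ROW_COLUMNS = [
    "method", "scenario", "m", "a", "repeat", "n_nodes", "n_edges", "median_r2",
    "precision", "recall", "f1_full", "f1_stability", "f1_truth",
    "transitivity", "mean_betweenness", "error",
]


def _as_list(x) -> list:
    return list(x) if isinstance(x, (list, tuple)) else [x]


def validate_config(config: dict) -> dict:
    """Reject unknown keys and unknown labels before any computation."""
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data = config.get("data", {})
    if bad := set(data) - _DATA_KEYS:
        raise ConfigError(f"unknown data keys: {sorted(bad)}")
    scen = config.get("scenario", {})
    if bad := set(scen) - _SCENARIO_KEYS:
        raise ConfigError(f"unknown scenario keys: {sorted(bad)}")
    for kind in _as_list(scen.get("kind", "single_random")):
        if kind not in ("single_random", "multi_random", "block", "downsample"):
            raise ConfigError(f"unknown scenario kind {kind!r}")
    for meth in _as_list(config.get("method", "knnSGLasso")):
        if meth not in METHODS:
            raise ConfigError(f"unknown method {meth!r}; expected one of {METHODS}")
    if bad := set(config.get("evaluation", {})) - _EVAL_KEYS:
        raise ConfigError(f"unknown evaluation keys: {sorted(bad)}")
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_data(config: dict, suite_seed: int):
    """Return (dataset, prior, ground_truth or None)."""
    data = config.get("data", {})
    if "path" in data:
        ds = read_dataset(data["path"])
        layer_map = ds.feature_index()
        prior = read_prior_network(data["prior_path"], layer_map)
        return ds, prior, None
    preset = data.get("preset")
    dims = dict(PRESETS[preset]) if preset else {}
    for key in ("n_genes", "n_cnv", "n_meth"):
        if key in data:
            dims[key] = int(data[key])
    dims.setdefault("n_genes", 100)
    dims.setdefault("n_cnv", 20)
    dims.setdefault("n_meth", 30)
    gen_seed = int(data.get("seed", derive_seed(suite_seed, "data")))
    gt = generate_ground_truth(mean_degree=float(data.get("mean_degree", 3.0)), seed=gen_seed, **dims)
    ds = simulate_dataset(gt, int(data.get("n_samples", 150)), seed=derive_seed(gen_seed, "samples"))
    return ds, gt.prior, gt


def run_scenario(config: dict) -> pd.DataFrame:
    """Run one method x scenario grid; one row per (m, a, repeat)."""
    validate_config(config)
    suite_seed = int(config.get("seed", 0))
    ds, prior, gt = _load_data(config, suite_seed)
    specs = build_model_specs(prior, ds)
    layer_of = ds.feature_index()
    scen_cfg = config.get("scenario", {})
    eval_cfg = config.get("evaluation", {})
    r2_threshold = float(eval_cfg.get("r2_threshold", 0.1))
    n_repeats = int(eval_cfg.get("n_repeats", 5))
    methods = _as_list(config.get("method", "knnSGLasso"))
    kinds = _as_list(scen_cfg.get("kind", "single_random"))
    m_grid = [float(v) for v in _as_list(scen_cfg.get("m", [0.0]))]
    a_grid = [float(v) for v in _as_list(scen_cfg.get("a", [0.0]))]
    target_layers = list(scen_cfg.get("target_layers", ["expression"]))

    rows: list[dict] = []
    references: dict[str, Any] = {}
    stability_refs: dict[str, Any] = {}
    want_stability = bool(eval_cfg.get("stability_reference", False))
    for method in methods:
        ref_key = method
        if ref_key not in references:
            fits = fit_all_models(ds, specs, method, seed=derive_seed(suite_seed, method, "reference"),
                                  prior=prior)
            references[ref_key] = assemble_network(fits, r2_threshold, layer_of)
            if want_stability:
                stability_refs[ref_key] = stability_selection(
                    ds, specs, method,
                    n_repeats=int(eval_cfg.get("stability_repeats", 5)),
                    seed=derive_seed(suite_seed, method, "stability-ref"),
                    r2_threshold=r2_threshold, prior=prior,
                )
        full_ref = references[ref_key]
        for kind in kinds:
            for m in m_grid:
                for a in a_grid:
                    for rep in range(n_repeats):
                        rep_seed = derive_seed(suite_seed, method, kind, m, a, rep)
                        if m == 0.0 and a == 0.0:
                            # the unperturbed cell is the full-data run itself;
                            # share the reference seed so it reproduces it
                            rep_seed = derive_seed(suite_seed, method, "reference")
                        row = {
                            "method": method, "scenario": kind, "m": m, "a": a, "repeat": rep,
                            "error": "",
                        }
                        try:
                            scenario = MissingnessScenario(kind, m, a, target_layers, rep_seed)
                            perturbed = apply_scenario(ds, scenario)
                            fits = fit_all_models(perturbed, specs, method, seed=rep_seed, prior=prior)
                            net = assemble_network(fits, r2_threshold, layer_of)
                            prec, rec, f1 = edge_f1(net, full_ref)
                            topo = topology_metrics(net)
                            row.update(
                                n_nodes=topo.n_nodes, n_edges=topo.n_edges,
                                median_r2=float(np.median([f.r2 for f in fits])) if fits else 0.0,
                                precision=prec, recall=rec, f1_full=f1,
                                transitivity=topo.transitivity,
                                mean_betweenness=topo.mean_betweenness,
                            )
                            if want_stability:
                                row["f1_stability"] = edge_f1(net, stability_refs[ref_key])[2]
                            if gt is not None:
                                truth = gt.true_edge_pairs()
                                inferred = net.undirected_edge_set()
                                inter = len(truth & inferred)
                                p_t = inter / len(inferred) if inferred else 0.0
                                r_t = inter / len(truth) if truth else 0.0
                                row["f1_truth"] = 2 * p_t * r_t / (p_t + r_t) if p_t + r_t else 0.0
                        except Exception as exc:  # noqa: BLE001 - cell-level robustness
                            logger.warning("cell (%s, %s, m=%s, a=%s, rep=%d) failed: %s",
                                           method, kind, m, a, rep, exc)
                            row["error"] = str(exc)
                        rows.append(row)
    df = pd.DataFrame(rows)
    for col in _ROW_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[_ROW_COLUMNS]


def run_benchmark_suite(config: dict, output_dir: str | Path | None = None) -> dict:
    """Full suite: per-repeat table, mean +/- SD summary, and provenance."""
    validate_config(config)
    table = run_scenario(config)
    metric_cols = ["n_nodes", "n_edges", "median_r2", "precision", "recall",
                   "f1_full", "f1_stability", "f1_truth", "transitivity", "mean_betweenness"]
    grouped = table.groupby(["method", "scenario", "m", "a"], sort=True)[metric_cols]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    summary = summary.reset_index()
    provenance = {
        "config_hash": config_hash(config),
        "seed": int(config.get("seed", 0)),
        "config": config,
    }
    out = {"table": table, "summary": summary, "provenance": provenance}
    outdir = output_dir or config.get("output", {}).get("dir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "results.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return out
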