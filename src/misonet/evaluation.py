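"""Prediction, network-reconstruction, topological and eQTM metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import FitResult, MultiOmicsNetwork, OmicsMatrix

logger = logging.getLogger(__name__)


def prediction_metrics(fits_a: list[FitResult], fits_b: list[FitResult]) -> dict:
    """Distribution summaries of per-model RMSE and R^2, plus a two-sided
    Wilcoxon rank-sum p-value comparing the two R^2 distributions (normal
    approximation with tie correction)."""
    if not fits_a or not fits_b:
        raise ValueError("both fit lists must be nonempty")

    def summarize(fits):
        r2 = np.array([f.r2 for f in fits])
        rmse = np.array([f.rmse for f in fits])
        return {
            "n_models": len(fits),
            "r2_median": float(np.median(r2)),
            "r2_iqr": float(np.subtract(*np.percentile(r2, [75, 25]))),
            "rmse_median": float(np.median(rmse)),
            "rmse_iqr": float(np.subtract(*np.percentile(rmse, [75, 25]))),
        }

    r2_a = [f.r2 for f in fits_a]
    r2_b = [f.r2 for f in fits_b]
    # Mann-Whitney U with the asymptotic normal approximation handles ties
    res = stats.mannwhitneyu(r2_a, r2_b, alternative="two-sided", method="asymptotic")
    return {
        "a": summarize(fits_a),
        "b": summarize(fits_b),
        "ranksum_statistic": float(res.statistic),
        "ranksum_pvalue": float(res.pvalue),
    }


def edge_f1(net: MultiOmicsNetwork, reference: MultiOmicsNetwork) -> tuple[float, float, float]:
    """Undirected edge-set precision, recall and F1 against a reference."""
    e_net = net.undirected_edge_set()
    e_ref = reference.undirected_edge_set()
    inter = len(e_net & e_ref)
    precision = inter / len(e_net) if e_net else 0.0
    recall = inter / len(e_ref) if e_ref else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    degree: dict[str, int]
    betweenness: dict[str, float]
    transitivity: float

    @property
    def mean_betweenness(self) -> float:
        return float(np.mean(list(self.betweenness.values()))) if self.betweenness else 0.0


def topology_metrics(net: MultiOmicsNetwork) -> TopologyMetrics:
    """Degree distribution, normalized betweenness and global transitivity.

    Structural metrics only: the graph is undirected and unweighted
    (coefficients ignored); betweenness uses the standard
    2/((N-1)(N-2)) normalization; transitivity is 3 * triangles /
    connected triples.
    """
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.undirected_edge_set())
    if g.number_of_nodes() == 0:
        return TopologyMetrics(0, 0, {}, {}, 0.0)
    return TopologyMetrics(
        g.number_of_nodes(),
        g.number_of_edges(),
        dict(g.degree()),
        nx.betweenness_centrality(g, normalized=True),
        float(nx.transitivity(g)),
    )


def eqtm_baseline(
    expr: OmicsMatrix,
    meth: OmicsMatrix,
    candidate_pairs: list[tuple[str, str]],
    p_threshold: float = 1e-5,
    fdr: float = 0.01,
) -> tuple[list[tuple[str, str]], int]:
    """Linear-regression eQTM scan over candidate (gene, methylation) pairs.

    Each pair is a simple regression of expression on methylation with a
    two-sided t-test on the slope; pairs survive if raw p < p_threshold AND
    Benjamini-Hochberg q < fdr (both filters, conjunctively). Returns the
    surviving pairs and the number of genes with at least one significant
    methylation site.
    """
    if not candidate_pairs:
        raise ValueError("candidate_pairs must be nonempty")
    tested: list[tuple[str, str]] = []
    pvals: list[float] = []
    for gene, site in candidate_pairs:
        x = meth.values[site].to_numpy(dtype=float)
        y = expr.values[gene].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            logger.warning("skipping eQTM pair (%s, %s): constant or too few values", gene, site)
            continue
        res = stats.linregress(x[ok], y[ok])
        tested.append((gene, site))
        pvals.append(float(res.pvalue))
    if not tested:
        return [], 0
    reject_fdr = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
    significant = [
        pair
        for pair, p, rej in zip(tested, pvals, reject_fdr)
        if p < p_threshold and rej
    ]
    genes = {g for g, _ in significant}
    return significant, len(genes)


def eqtm_from_network(net: MultiOmicsNetwork) -> tuple[set[tuple[str, str]], int]:
    """Expression-methylation edges of an inferred network and the count of
    genes linked to at least one methylation site."""
    pairs: set[tuple[str, str]] = set()
    for e in net.edges:
        la = net.layer_of.get(e.response, "")
        lb = net.layer_of.get(e.predictor, "")
        if {la, lb} == {"expression", "methylation"}:
            gene, site = (e.response, e.predictor) if la == "expression" else (e.predictor, e.response)
            pairs.add((gene, site))
    genes = {g for g, _ in pairs}
    return pairs, len(genes)
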