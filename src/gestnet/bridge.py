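"""Bridge centralities: which nodes connect the communities.

Three node-level metrics quantify a node's role in linking its community to
the rest of the network:

* bridge expected influence (BEI) — the signed sum of a node's edge weights
  to nodes outside its community (direct connections only);
* bridge closeness (BCL) — the inverse of the mean shortest-path distance to
  all out-community nodes, with edge lengths 1/|weight| (the standard
  weighted-network convention: strong edges are short);
* bridge betweenness (BBW) — the number of shortest paths between node pairs
  in *different* communities that pass through the node (endpoints excluded),
  with tied geodesics counted fractionally.

The significance of pairwise differences in a metric is tested with a
nonparametric participant bootstrap: the community partition and the edge
inclusion mask are held fixed at the full-sample solution while the edge
weights are re-estimated per replicate, so the test isolates sampling
variability in the centralities from model-selection variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import (
    EstimatedNetwork,
    nearest_positive_definite,
    partial_correlations,
    rank_correlation_matrix,
    EIG_FLOOR,
    _table_matrix,
)

METRICS = ("bei", "bcl", "bbw")


def _graph(weights: np.ndarray, labels: tuple[str, ...]) -> nx.Graph:
    """Undirected graph on nonzero weights with length = 1/|weight|."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = weights[i, j]
            if w != 0.0:
                g.add_edge(labels[i], labels[j], weight=w, length=1.0 / abs(w))
    return g


def bridge_expected_influence(weights: np.ndarray, labels: tuple[str, ...],
                              partition: dict[str, int], node: str) -> float:
    i = labels.index(node)
    out = [j for j, lab in enumerate(labels) if partition[lab] != partition[node]]
    return float(weights[i, out].sum())


def bridge_closeness(weights: np.ndarray, labels: tuple[str, ...],
                     partition: dict[str, int], node: str) -> float:
    g = _graph(weights, labels)
    dist = nx.single_source_dijkstra_path_length(g, node, weight="length")
    out_nodes = [lab for lab in labels if partition[lab] != partition[node]]
    if not out_nodes:
        return 0.0
    d = [dist.get(lab, math.inf) for lab in out_nodes]
    mean_d = float(np.mean(d))
    return 0.0 if math.isinf(mean_d) else 1.0 / mean_d


def bridge_betweenness(weights: np.ndarray, labels: tuple[str, ...],
                       partition: dict[str, int], node: str) -> float:
    return _bbw_all(weights, labels, partition)[node]


def _bbw_all(weights: np.ndarray, labels: tuple[str, ...],
             partition: dict[str, int]) -> dict[str, float]:
    """Fractional betweenness restricted to cross-community node pairs."""
    g = _graph(weights, labels)
    score = {lab: 0.0 for lab in labels}
    labs = list(labels)
    for si, s in enumerate(labs):
        for t in labs[si + 1:]:
            if partition[s] == partition[t]:
                continue
            try:
                paths = list(nx.all_shortest_paths(g, s, t, weight="length"))
            except nx.NetworkXNoPath:
                continue
            frac = 1.0 / len(paths)
            for path in paths:
                for v in path[1:-1]:
                    score[v] += frac
    return score


def bridge_scores(network: EstimatedNetwork | np.ndarray,
                  partition: dict[str, int],
                  labels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """All three bridge metrics for every node, as a tidy per-node table."""
    if isinstance(network, EstimatedNetwork):
        weights, labels = network.selected_weights, network.node_labels
    else:
        weights = np.asarray(network, dtype=float)
        if labels is None:
            labels = tuple(str(i) for i in range(weights.shape[0]))
    bbw = _bbw_all(weights, labels, partition)
    rows = []
    for lab in labels:
        rows.append((lab,
                     bridge_expected_influence(weights, labels, partition, lab),
                     bridge_closeness(weights, labels, partition, lab),
                     bbw[lab]))
    return pd.DataFrame(rows, columns=["node", "bei", "bcl", "bbw"])


def _metric_vector(weights: np.ndarray, labels: tuple[str, ...],
                   partition: dict[str, int], metric: str) -> np.ndarray:
    if metric == "bei":
        comm = np.array([partition[lab] for lab in labels])
        cross = comm[:, None] != comm[None, :]
        return (weights * cross).sum(axis=1)
    if metric == "bcl":
        return np.array([bridge_closeness(weights, labels, partition, lab)
                         for lab in labels])
    if metric == "bbw":
        bbw = _bbw_all(weights, labels, partition)
        return np.array([bbw[lab] for lab in labels])
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


@dataclass(frozen=True)
class BridgeDiffResult:
    """Bootstrap test of pairwise differences in one bridge metric.

    ``significant[i, j]`` is True iff the percentile CI of
    metric(i) - metric(j) excludes zero.
    """

    metric: str
    node_labels: tuple[str, ...]
    diff_lower: np.ndarray
    diff_upper: np.ndarray
    significant: np.ndarray
    n_boot: int
    ci: float
    seed: int | None

    def significance_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=self.node_labels,
                            columns=self.node_labels)


def bridge_difference_test(
    table: pd.DataFrame,
    network: EstimatedNetwork,
    partition: dict[str, int],
    metric: str = "bei",
    n_boot: int = 5000,
    ci: float = 0.95,
    seed: int | None = None,
) -> BridgeDiffResult:
    """Percentile-bootstrap test of all pairwise metric differences.

    Per replicate: resample participants, re-estimate the partial Spearman
    weights, apply the full-sample inclusion mask (no re-selection), and
    recompute the metric under the full-sample partition.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    x, cols = _table_matrix(table, list(network.node_labels))
    n, p = x.shape
    mask = network.included
    rng = np.random.default_rng(seed)
    vals = np.empty((n_boot, p))
    b = 0
    while b < n_boot:
        xb = x[rng.integers(0, n, size=n)]
        if np.any(np.ptp(xb, axis=0) == 0):
            continue
        corr = rank_correlation_matrix(xb)
        if np.linalg.eigvalsh(corr).min() < EIG_FLOOR:
            corr = nearest_positive_definite(corr)
        w = partial_correlations(corr, repair=False)
        w = np.where(mask, w, 0.0)
        np.fill_diagonal(w, 0.0)
        vals[b] = _metric_vector(w, network.node_labels, partition, metric)
        b += 1

    diffs = vals[:, :, None] - vals[:, None, :]
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    lo = np.percentile(diffs, lo_q, axis=0)
    hi = np.percentile(diffs, hi_q, axis=0)
    sig = (lo > 0) | (hi < 0)
    np.fill_diagonal(sig, False)
    return BridgeDiffResult(metric=metric, node_labels=network.node_labels,
                            diff_lower=lo, diff_upper=hi, significant=sig,
                            n_boot=n_boot, ci=ci, seed=seed)
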