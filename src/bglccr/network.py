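"""Signed co-occurrence networks of β-glucosidase-producing taxa.

Edges connect taxa whose abundance profiles across samples correlate beyond
a fixed threshold (default |r| ≥ 0.8, Spearman) and pass a permutation test
(default 1,000 permutations, α = 0.05).  Edge sign follows the correlation
sign: positive edges mark co-occurring taxa, negative edges competition.
High-glucose and non-glucose sample groups yield separate networks whose
topology (edge counts, sign balance, clustering) can be compared.

Permutations shuffle the sample order of one profile of each pair; one
shared set of permutations is used for all pairs so the edge set is fully
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    positive_fraction: float
    mean_degree: float
    global_clustering_coefficient: float


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((x**2).sum(axis=1, keepdims=True))
    return x / norm


def build_network(
    abundance: pd.DataFrame,
    method: str = "spearman",
    r_min: float = 0.8,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> nx.Graph:
    """Build the signed co-occurrence graph from a taxa × samples table.

    Zero-variance taxa cannot be correlated and are excluded (listed in
    ``graph.graph['excluded_taxa']``).  The permutation p-value of a pair is
    ``(1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm)``; an edge is retained when
    |r| ≥ ``r_min`` and p ≤ ``alpha``.  Deterministic for a given seed.
    """
    if method not in ("pearson", "spearman"):
        raise NetworkError(f"unknown correlation method {method!r}")
    n_samples = abundance.shape[1]
    if n_samples < 3:
        raise NetworkError(f"need at least 3 samples, got {n_samples}")
    values = abundance.to_numpy(dtype=float)
    variances = values.var(axis=1)
    keep = variances > 0
    excluded = [t for t, k in zip(abundance.index, keep) if not k]
    taxa = [t for t, k in zip(abundance.index, keep) if k]
    x = values[keep]
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 1, x)
    z = _standardize_rows(x)
    r_obs = z @ z.T
    rng = np.random.default_rng(seed)
    n_taxa = len(taxa)
    exceed = np.zeros((n_taxa, n_taxa), dtype=np.int64)
    abs_obs = np.abs(r_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        r_perm = z @ z[:, perm].T
        exceed += np.abs(r_perm) >= abs_obs - 1e-12
    p_perm = (1 + exceed) / (1 + n_perm)

    graph = nx.Graph()
    graph.graph["excluded_taxa"] = excluded
    graph.graph["method"] = method
    graph.graph["r_min"] = r_min
    graph.graph["alpha"] = alpha
    graph.graph["n_perm"] = n_perm
    graph.graph["seed"] = seed
    mean_abundance = values[keep].mean(axis=1)
    for taxon, ab in zip(taxa, mean_abundance):
        graph.add_node(taxon, mean_abundance=float(ab))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            r = float(r_obs[i, j])
            if abs(r) >= r_min and p_perm[i, j] <= alpha:
                graph.add_edge(
                    taxa[i],
                    taxa[j],
                    r=r,
                    sign="positive" if r > 0 else "negative",
                    p_perm=float(p_perm[i, j]),
                )
    # node size attribute of the rendered network: the number of connections
    for taxon in graph.nodes:
        graph.nodes[taxon]["degree"] = graph.degree[taxon]
    return graph


def network_stats(graph: nx.Graph) -> NetworkStats:
    """Topology summary: counts, sign balance, mean degree and the global
    (sign-blind) clustering coefficient 3×triangles / connected triples."""
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    n_positive = sum(1 for _, _, d in graph.edges(data=True) if d.get("sign") == "positive")
    n_negative = n_edges - n_positive
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive=n_positive,
        n_negative=n_negative,
        positive_fraction=n_positive / n_edges if n_edges else 0.0,
        mean_degree=2.0 * n_edges / n_nodes if n_nodes else 0.0,
        global_clustering_coefficient=nx.transitivity(graph) if n_nodes else 0.0,
    )


def stats_to_frame(stats_: NetworkStats) -> pd.DataFrame:
    return pd.DataFrame([stats_.__dict__])


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "taxon_i": u,
            "taxon_j": v,
            "r": d["r"],
            "sign": d["sign"],
            "p_perm": d["p_perm"],
        }
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "r", "sign", "p_perm"])


def write_graphml(graph: nx.Graph, path: str) -> None:
    out = graph.copy()
    out.graph.pop("excluded_taxa", None)  # GraphML cannot hold list attributes
    nx.write_graphml(out, path)
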