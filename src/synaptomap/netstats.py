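"""Synaptome network construction and topology metrics.

The region similarity matrix is binarized by keeping the top fraction of
off-diagonal similarities (default 5%, matching the displayed network) and
the resulting graph is summarized by: mean local clustering coefficient
(fraction of closed triangles around a node), greedy-maximized modularity,
characteristic path length over reachable pairs, and small-worldness

    sigma = (C_net / C_rand) / (l_net / l_rand)

where the random reference is the mean over degree-preserving edge
rewirings of the same graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GraphMetrics",
    "network_from_similarity",
    "topology_metrics",
    "degree_vector",
    "within_between_ratio",
]


@dataclass
class GraphMetrics:
    clustering: float              # C_net, mean triangle fraction
    modularity: float              # Q, greedy maximization
    path_length: float             # l_net over reachable pairs
    disconnected_fraction: float   # fraction of unreachable node pairs
    c_rand_mean: float
    c_rand_sd: float
    l_rand_mean: float
    l_rand_sd: float
    small_worldness: float         # sigma
    n_nulls: int

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def network_from_similarity(matrix: np.ndarray, ids: list | None = None,
                            edge_density: float = 0.05) -> nx.Graph:
    """Binary graph of the top ``edge_density`` fraction of similarities.

    Keeps the ceil(density * n_pairs) largest off-diagonal entries; ties at
    the cut are broken by region-id (row, col) order.
    """
    S = np.asarray(matrix, float)
    n = len(S)
    if ids is None:
        ids = list(range(n))
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge density must be in (0, 1]")
    iu = np.triu_indices(n, k=1)
    n_edges = int(np.ceil(edge_density * len(iu[0])))
    # sort by (-similarity, row, col): ties resolved by id order
    order = np.lexsort((iu[1], iu[0], -S[iu]))
    g = nx.Graph()
    g.add_nodes_from(ids)
    for idx in order[:n_edges]:
        i, j = iu[0][idx], iu[1][idx]
        g.add_edge(ids[i], ids[j], weight=float(S[i, j]))
    return g


def _path_length(g: nx.Graph) -> tuple[float, float]:
    """Mean shortest path over reachable pairs + unreachable fraction."""
    n = g.number_of_nodes()
    total_pairs = n * (n - 1) / 2
    s = 0.0
    reached = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                s += d
                reached += 1
    reached //= 2  # each pair counted twice
    s /= 2
    if reached == 0:
        return np.nan, 1.0
    return s / reached, 1.0 - reached / total_pairs


def topology_metrics(g: nx.Graph, n_nulls: int = 20, seed: int = 0) -> GraphMetrics:
    """Clustering, modularity, path length and small-worldness of a graph.

    The null ensemble is ``n_nulls`` degree-preserving rewirings (10
    attempted swaps per edge) of the input graph, so node and edge counts
    and the degree sequence are conserved.
    """
    if g.number_of_nodes() < 3:
        raise ValueError("need at least three nodes")
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    c_net = nx.average_clustering(g)
    comms = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, comms)
    l_net, disc = _path_length(g)

    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_nulls):
        h = g.copy()
        nswap = 10 * h.number_of_edges()
        try:
            nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException:
            pass  # graph admits few/no degree-preserving swaps; use as-is
        cs.append(nx.average_clustering(h))
        ls.append(_path_length(h)[0])
    c_rand, c_sd = float(np.mean(cs)), float(np.std(cs))
    l_rand, l_sd = float(np.nanmean(ls)), float(np.nanstd(ls))
    if c_rand > 0 and l_rand > 0 and np.isfinite(l_net):
        sigma = (c_net / c_rand) / (l_net / l_rand)
    else:
        sigma = np.nan
    return GraphMetrics(clustering=c_net, modularity=q, path_length=l_net,
                        disconnected_fraction=disc, c_rand_mean=c_rand,
                        c_rand_sd=c_sd, l_rand_mean=l_rand, l_rand_sd=l_sd,
                        small_worldness=float(sigma), n_nulls=n_nulls)


def degree_vector(matrix: np.ndarray, ids: list | None = None) -> pd.Series:
    """Weighted node degree: mean off-diagonal similarity per region.

    Exported for correlation against user-supplied external degree vectors
    (e.g. a functional-connectome node degree).
    """
    S = np.asarray(matrix, float)
    n = len(S)
    deg = (S.sum(axis=1) - np.diag(S)) / (n - 1)
    return pd.Series(deg, index=ids if ids is not None else range(n), name="degree")


def within_between_ratio(matrix: np.ndarray, ids: list,
                         membership: dict) -> pd.DataFrame:
    """Within- vs between-area similarity per overarching area.

    within: mean similarity among the area's subregion pairs; between:
    mean similarity from the area's subregions to all other regions.
    Areas with a single subregion have undefined within (null row values).
    """
    S = np.asarray(matrix, float)
    areas = sorted({membership[i] for i in ids})
    idx_of = {rid: k for k, rid in enumerate(ids)}
    rows = []
    for area in areas:
        members = [idx_of[i] for i in ids if membership[i] == area]
        others = [idx_of[i] for i in ids if membership[i] != area]
        if len(members) < 2:
            rows.append(dict(area=area, within=np.nan, between=np.nan,
                             ratio=np.nan, n_subregions=len(members)))
            continue
        sub = S[np.ix_(members, members)]
        within = sub[np.triu_indices(len(members), k=1)].mean()
        between = S[np.ix_(members, others)].mean() if others else np.nan
        ratio = within / between if between and between > 0 else np.nan
        rows.append(dict(area=area, within=float(within), between=float(between),
                         ratio=float(ratio), n_subregions=len(members)))
    return pd.DataFrame(rows)
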