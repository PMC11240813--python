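"""Co-occurrence network construction and module detection.

A network keeps the full correlation matrix plus a boolean adjacency at
the chosen |r| threshold (isolated nodes are retained).  Modules come
from topological-overlap dissimilarity on the |r|-weighted adjacency,
average-linkage hierarchical clustering and a fixed-height cut, so the
partition is a pure, deterministic function of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class CooccurrenceNetwork:
    corr: pd.DataFrame  # symmetric, unit diagonal
    adjacency: pd.DataFrame  # boolean, no self-loops
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.corr.index)

    def edge_list(self) -> pd.DataFrame:
        """Long-format edges (source, target, weight), i < j."""
        rows = []
        nodes = self.nodes
        adj = self.adjacency.to_numpy()
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if adj[i, j]:
                    rows.append(
                        {
                            "source": nodes[i],
                            "target": nodes[j],
                            "weight": float(self.corr.iloc[i, j]),
                        }
                    )
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def build_network(corr: pd.DataFrame, edge_threshold: float = 0.3) -> CooccurrenceNetwork:
    """Threshold a correlation matrix into a network: edge iff |r| >= t."""
    if not 0 < edge_threshold <= 1:
        raise ValueError("edge_threshold must be in (0, 1]")
    c = corr.to_numpy(float)
    if c.shape[0] != c.shape[1] or not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    adj = np.abs(c) >= edge_threshold
    np.fill_diagonal(adj, False)
    return CooccurrenceNetwork(
        corr=corr.copy(),
        adjacency=pd.DataFrame(adj, index=corr.index, columns=corr.columns),
        threshold=edge_threshold,
    )


def topological_overlap(network: CooccurrenceNetwork) -> pd.DataFrame:
    """TOM similarity on the |r|-weighted, thresholded adjacency."""
    a = np.abs(network.corr.to_numpy(float)) * network.adjacency.to_numpy(float)
    k = a.sum(axis=1)
    shared = a @ a
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            tom[i, j] = tom[j, i] = (shared[i, j] + a[i, j]) / denom
    return pd.DataFrame(tom, index=network.corr.index, columns=network.corr.columns)


def detect_modules(
    network: CooccurrenceNetwork, cut_height: float = 0.8
) -> pd.Series:
    """Partition nodes into modules (node -> integer module id).

    Average-linkage clustering of 1 - TOM, cut at ``cut_height``.
    Disconnected cliques map to separate modules; an edgeless network
    yields all singletons.
    """
    nodes = network.nodes
    if len(nodes) == 0:
        raise ValueError("network has no nodes")
    if len(nodes) == 1:
        return pd.Series([1], index=nodes, name="module")
    diss = 1.0 - topological_overlap(network).to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    return pd.Series(labels, index=nodes, name="module")
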