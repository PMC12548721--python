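"""Exact Manhattan-distance k-nearest-neighbour graphs over fingerprints.

The similarity substrate for chemical-space maps: the k-NN graph under
the Manhattan (city-block) metric, which on count fingerprints sums the
absolute differences in substructure occurrences.  The search is exact
— all pairwise distances are evaluated in row blocks — because the
datasets this package handles are desk-scale and exactness makes the
graph testable against a brute-force oracle.  Ties at equal distance are
broken toward the lower index so the graph is deterministic.  Tree
layout of the graph (e.g. for TMAP-style visualisation) is delegated to
external tools via the edge-list export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

DEFAULT_K = 20
_BLOCK = 256


def manhattan_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of absolute coordinate differences between two vectors."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum())


@dataclass
class NeighborGraph:
    """Directed k-NN graph: ``edges[i]`` holds (source, target, distance)."""

    n_points: int
    k: int
    edges: np.ndarray  # structured columns via to_frame()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": self.edges[:, 0].astype(np.int64),
                "target": self.edges[:, 1].astype(np.int64),
                "distance": self.edges[:, 2].astype(np.float64),
            }
        )

    def write_edge_list(self, path, sep: str = "\t") -> None:
        """Write a (source, target, distance) table readable by graph tools."""
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def read_edge_list(cls, path, sep: str = "\t") -> "NeighborGraph":
        df = pd.read_csv(path, sep=sep)
        edges = df[["source", "target", "distance"]].to_numpy(dtype=np.float64)
        n_points = int(max(df["source"].max(), df["target"].max())) + 1
        k = int((df["source"] == df["source"].iloc[0]).sum()) if len(df) else 0
        return cls(n_points=n_points, k=k, edges=edges)


def knn_graph(fingerprints, k: int = DEFAULT_K) -> NeighborGraph:
    """Exact k nearest neighbours per point under Manhattan distance.

    Each point gets ``min(k, n - 1)`` outgoing edges, never to itself;
    equal distances resolve to the lower index.  Distances are computed
    in blocks of rows to bound memory on larger inputs.
    """
    X = np.asarray(fingerprints, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 points in a 2-D array")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n = X.shape[0]
    k_eff = min(k, n - 1)

    edges = np.empty((n * k_eff, 3), dtype=np.float64)
    row = 0
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        dist = cdist(X[start:stop], X, metric="cityblock")
        for local_i in range(stop - start):
            i = start + local_i
            d = dist[local_i]
            order = np.lexsort((np.arange(n), d))  # distance, then index
            neighbours = order[order != i][:k_eff]
            for j in neighbours:
                edges[row] = (i, j, d[j])
                row += 1
    return NeighborGraph(n_points=n, k=k_eff, edges=edges)
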