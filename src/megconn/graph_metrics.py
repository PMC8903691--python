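"""Graph-theoretic network summaries: degree, strength, path length, clustering.

All four metrics are computed on the undirected skeleton of the thresholded
connectivity graph; strength uses the absolute correlation as edge weight,
the other three binarize.  The reporting conventions are:

* degree D: number of retained edges incident to a node (each unordered pair
  counted once), averaged over nodes;
* strength S: sum of |R| over a node's retained edges, averaged over nodes;
* characteristic path length L: mean shortest-path hop count over connected
  node pairs (disconnected pairs are excluded from the mean; a graph with no
  edges has no defined L and yields NaN, never 0);
* clustering coefficient C: per node, 2 * triangles / (k (k - 1)); nodes of
  degree < 2 contribute 0; averaged over all nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityGraph
from .preprocessing import BandDefinition

__all__ = [
    "GraphMetrics",
    "degree",
    "strength",
    "path_length",
    "clustering",
    "compute_metrics",
]


@dataclass
class GraphMetrics:
    degree_D: float
    strength_S: float
    path_length_L: float
    clustering_C: float
    band: BandDefinition | None = None
    subject_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "D": self.degree_D,
            "S": self.strength_S,
            "L": self.path_length_L,
            "C": self.clustering_C,
        }


def _to_nx(graph: ConnectivityGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_sources))
    for e in graph.edges:
        g.add_edge(e.a, e.b, weight=abs(e.R))
    return g


def degree(graph: ConnectivityGraph) -> tuple[np.ndarray, float]:
    """Per-node undirected degree and its mean over nodes."""
    g = _to_nx(graph)
    d = np.array([g.degree(i) for i in range(graph.n_sources)], dtype=float)
    return d, float(d.mean()) if graph.n_sources else 0.0


def strength(graph: ConnectivityGraph) -> tuple[np.ndarray, float]:
    """Per-node strength (sum of |R| over incident edges) and its mean."""
    g = _to_nx(graph)
    s = np.array(
        [g.degree(i, weight="weight") for i in range(graph.n_sources)], dtype=float
    )
    return s, float(s.mean()) if graph.n_sources else 0.0


def path_length(graph: ConnectivityGraph, mode: str = "exclude") -> float:
    """Characteristic path length on the binarized undirected graph.

    ``mode='exclude'`` (default) averages shortest-path hop counts over
    connected node pairs only; ``mode='harmonic'`` returns the harmonic mean
    over all pairs (disconnected pairs enter with infinite distance, i.e.
    zero reciprocal).  A graph with no connected pair returns NaN.
    """
    if mode not in ("exclude", "harmonic"):
        raise ValueError("mode must be 'exclude' or 'harmonic'")
    g = _to_nx(graph)
    dists = []
    n_pairs_total = 0
    for a, lengths in nx.all_pairs_shortest_path_length(g):
        for b, d in lengths.items():
            if a != b:
                dists.append(d)
    n = graph.n_sources
    n_pairs_total = n * (n - 1)
    if not dists:
        return float("nan")
    if mode == "exclude":
        return float(np.mean(dists))
    inv_sum = float(np.sum(1.0 / np.asarray(dists, dtype=float)))
    if inv_sum == 0.0:
        return float("nan")
    return n_pairs_total / inv_sum


def clustering(graph: ConnectivityGraph) -> tuple[np.ndarray, float]:
    """Per-node binary clustering coefficient and its mean over all nodes.

    Isolated and degree-1 nodes contribute 0 (they are not dropped), so group
    means always compare identical node sets.
    """
    g = _to_nx(graph)
    cc = nx.clustering(g)
    c = np.array([cc[i] for i in range(graph.n_sources)], dtype=float)
    return c, float(c.mean()) if graph.n_sources else 0.0


def compute_metrics(graph: ConnectivityGraph, l_mode: str = "exclude") -> GraphMetrics:
    """All four summary metrics for one subject's thresholded graph."""
    _, d = degree(graph)
    _, s = strength(graph)
    length = path_length(graph, mode=l_mode)
    _, c = clustering(graph)
    return GraphMetrics(
        degree_D=d,
        strength_S=s,
        path_length_L=length,
        clustering_C=c,
        band=graph.band,
        subject_id=graph.subject_id,
    )
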