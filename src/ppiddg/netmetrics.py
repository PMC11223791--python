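"""Network-analysis metrics on interface graphs and wild-type/mutant deltas.

The metric block covers degree, PageRank, closeness, eccentricity,
clustering, diameter/radius, Kleinberg (HITS) authority, adjacency spectral
energy, degree-distribution Shannon entropy, articulation ("central")
points and degree-1 ("end") points.  The change in mean authority between
the wild-type and mutant interface graphs is the delta-authority feature.

Conventions (the source metrics are named, not defined, by their upstream
description; these are this package's declared interpretations):

* metrics are computed on the unweighted simple graph;
* path-based metrics (closeness, eccentricity, diameter, radius) are per
  connected component with unreachable pairs excluded, and the graph-level
  diameter/radius are the max/min over components;
* authority is the L2-normalized, sign-fixed projection of the uniform
  vector onto the principal eigenspace of A^T A, i.e. the HITS fixed point
  from a uniform start (well-defined even for bipartite graphs);
* energy is the sum of absolute adjacency eigenvalues; entropy is the
  Shannon entropy (natural log) of the empirical distribution of degree
  values, hence 0 for regular graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import networkx as nx
import numpy as np

from .interface import InterfaceGraph


class UndefinedMetricsError(ValueError):
    """Metrics requested on an empty graph."""


PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-10


@dataclass
class NetworkMetricSet:
    mean_degree: float
    max_degree: float
    mean_pagerank: float
    mean_closeness: float
    mean_eccentricity: float
    mean_clustering: float
    diameter: float
    radius: float
    mean_authority: float
    energy: float
    degree_entropy: float
    n_articulation_points: float
    n_end_points: float
    node_table: dict[str, np.ndarray] | None = None

    @staticmethod
    def scalar_names() -> list[str]:
        return [f.name for f in fields(NetworkMetricSet) if f.name != "node_table"]

    def scalars(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.scalar_names()])


@dataclass
class MetricDelta:
    """Mutant minus wild-type value for every scalar metric."""

    values: dict[str, float]

    def as_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in NetworkMetricSet.scalar_names()])

    @staticmethod
    def column_names() -> list[str]:
        return [f"dmetric_{n}" for n in NetworkMetricSet.scalar_names()]

    @property
    def delta_authority(self) -> float:
        return self.values["mean_authority"]


def _to_networkx(graph: InterfaceGraph | nx.Graph | np.ndarray) -> nx.Graph:
    if isinstance(graph, nx.Graph):
        return graph
    if isinstance(graph, np.ndarray):
        return nx.from_numpy_array(graph)
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges)
    return g


def authority_scores(adjacency: np.ndarray) -> np.ndarray:
    """HITS authority: uniform vector projected onto the top eigenspace of A^T A."""
    n = adjacency.shape[0]
    ata = adjacency.T @ adjacency
    if not ata.any():
        return np.zeros(n)
    evals, evecs = np.linalg.eigh(ata)
    top = evals[-1]
    space = evecs[:, evals >= top * (1 - 1e-9)]
    u = np.full(n, 1.0 / np.sqrt(n))
    v = space @ (space.T @ u)
    norm = np.linalg.norm(v)
    if norm < 1e-12:  # uniform start orthogonal to the top eigenspace
        v = evecs[:, -1]
        norm = 1.0
    v = v / norm
    if v.sum() < 0:
        v = -v
    # the HITS iterate is entrywise non-negative; clip numerical dust
    return np.where(v < 0, np.maximum(v, 0.0), v) if v.min() > -1e-12 else v


def compute_metrics(graph: InterfaceGraph | nx.Graph | np.ndarray) -> NetworkMetricSet:
    """Full metric block for one graph; raises on an empty graph."""
    g = _to_networkx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise UndefinedMetricsError("metrics undefined on an empty graph")
    degrees = np.array([d for _, d in sorted(g.degree())], dtype=float)
    pagerank_d = nx.pagerank(g, alpha=PAGERANK_DAMPING, tol=PAGERANK_TOL, max_iter=1000)
    pagerank = np.array([pagerank_d[i] for i in sorted(g.nodes)])
    closeness_d = nx.closeness_centrality(g, wf_improved=False)
    closeness = np.array([closeness_d[i] for i in sorted(g.nodes)])
    clustering_d = nx.clustering(g)
    clustering = np.array([clustering_d[i] for i in sorted(g.nodes)])

    ecc: dict = {}
    diameters, radii = [], []
    for comp in nx.connected_components(g):
        sub_ecc = nx.eccentricity(g.subgraph(comp))
        ecc.update(sub_ecc)
        diameters.append(max(sub_ecc.values()))
        radii.append(min(sub_ecc.values()))
    eccentricity = np.array([ecc[i] for i in sorted(g.nodes)], dtype=float)

    adjacency = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    authority = authority_scores(adjacency)
    energy = float(np.abs(np.linalg.eigvalsh(adjacency)).sum())

    _, counts = np.unique(degrees, return_counts=True)
    p = counts / n
    degree_entropy = float(-(p * np.log(p)).sum())

    return NetworkMetricSet(
        mean_degree=float(degrees.mean()),
        max_degree=float(degrees.max()),
        mean_pagerank=float(pagerank.mean()),
        mean_closeness=float(closeness.mean()),
        mean_eccentricity=float(eccentricity.mean()),
        mean_clustering=float(clustering.mean()),
        diameter=float(max(diameters)),
        radius=float(min(radii)),
        mean_authority=float(authority.mean()),
        energy=energy,
        degree_entropy=degree_entropy,
        n_articulation_points=float(len(list(nx.articulation_points(g)))),
        n_end_points=float((degrees == 1).sum()),
        node_table={
            "degree": degrees, "pagerank": pagerank, "closeness": closeness,
            "eccentricity": eccentricity, "clustering": clustering,
            "authority": authority,
        },
    )


def delta_metrics(wt: NetworkMetricSet, mut: NetworkMetricSet) -> MetricDelta:
    """Elementwise mutant minus wild type over the scalar block."""
    return MetricDelta({
        name: getattr(mut, name) - getattr(wt, name)
        for name in NetworkMetricSet.scalar_names()
    })
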