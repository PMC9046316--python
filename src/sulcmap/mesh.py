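"""Geometry engine: triangle/vertex areas, adjacency, and multi-source
geodesic distances along the cortical surface.

Geodesics are shortest paths on the weighted edge graph (edge weight =
Euclidean edge length, Dijkstra).  On a flat triangulated grid with
diagonals this overestimates true geodesic distance by at most ~8.2 %
(1/cos(pi/8)) in the worst direction; the package documents and tests a 9 %
bound.  Subset surface areas attribute one third of each triangle's area to
each of its member vertices, which makes areas of a vertex partition sum
exactly to the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

from .errors import IntegrityError
from .types import TriangleMesh, VertexOverlay

log = logging.getLogger(__name__)


def triangle_areas(mesh: TriangleMesh) -> np.ndarray:
    """Area of every face (mm^2)."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex area: one third of each incident triangle (mm^2)."""
    areas = triangle_areas(mesh)
    va = np.zeros(mesh.n_vertices)
    np.add.at(va, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    return va


def surface_area(mesh: TriangleMesh, subset="all") -> float:
    """Surface area (mm^2) of the whole mesh or of a vertex subset.

    For a subset, each triangle contributes one third of its area per member
    vertex, so sub-areas of a partition sum exactly to the total.
    An empty subset yields 0 with a logged warning.
    """
    if isinstance(subset, str) and subset == "all":
        return float(triangle_areas(mesh).sum())
    idx = np.asarray(list(subset) if isinstance(subset, (set, frozenset)) else subset,
                     dtype=np.int64)
    if idx.size == 0:
        log.warning("surface_area called with an empty subset; returning 0")
        return 0.0
    if idx.min() < 0 or idx.max() >= mesh.n_vertices:
        raise IntegrityError(f"subset index out of range: {idx.max()}")
    return float(vertex_areas(mesh)[idx].sum())


def edge_graph(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Symmetric sparse adjacency with Euclidean edge lengths as weights."""
    e = mesh.edges()
    lengths = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = sparse.coo_matrix(
        (np.concatenate([lengths, lengths]),
         (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n))
    return g.tocsr()


def vertex_adjacency(mesh: TriangleMesh) -> list[list[tuple[int, float]]]:
    """Neighbour lists with edge lengths: ``adj[u] = [(v, length_uv), ...]``."""
    g = edge_graph(mesh)
    adj: list[list[tuple[int, float]]] = []
    indptr, indices, data = g.indptr, g.indices, g.data
    for u in range(mesh.n_vertices):
        sl = slice(indptr[u], indptr[u + 1])
        adj.append(list(zip(indices[sl].tolist(), data[sl].tolist())))
    return adj


@dataclass
class GeodesicField:
    """Distance (mm) from a source vertex set along the mesh edge graph."""

    distance: VertexOverlay
    source_vertices: np.ndarray
    method: str = "edge-graph"

    def bind(self, mesh: TriangleMesh) -> "GeodesicField":
        self.distance.bind(mesh)
        return self


def geodesic_distance(mesh: TriangleMesh, sources, graph: sparse.csr_matrix | None = None
                      ) -> GeodesicField:
    """Multi-source shortest-path distance over the weighted edge graph.

    Each vertex gets the distance to its nearest source; unreachable
    vertices are flagged invalid.  Raises ``ValueError`` on an empty source
    set.
    """
    src = np.asarray(list(sources) if isinstance(sources, (set, frozenset)) else sources,
                     dtype=np.int64)
    if src.ndim == 0:
        src = src[None]
    if src.size == 0:
        raise ValueError("geodesic_distance requires a nonempty source set")
    if src.min() < 0 or src.max() >= mesh.n_vertices:
        raise IntegrityError(f"source index out of range: {src.max()}")
    g = edge_graph(mesh) if graph is None else graph
    dist = dijkstra(g, directed=False, indices=src, min_only=True)
    valid = np.isfinite(dist)
    overlay = VertexOverlay(np.where(valid, dist, np.nan), units="mm", valid_mask=valid)
    return GeodesicField(distance=overlay, source_vertices=np.unique(src))


def shortest_path(graph: sparse.csr_matrix, source: int, target: int
                  ) -> tuple[list[int], float]:
    """Single-pair shortest path on a weighted graph; returns (path, length)."""
    dist, pred = dijkstra(graph, directed=False, indices=source,
                          return_predecessors=True)
    if not np.isfinite(dist[target]):
        raise IntegrityError(f"vertices {source} and {target} are not connected")
    path = [target]
    while path[-1] != source:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return path, float(dist[target])


def subgraph(graph: sparse.csr_matrix, mask: np.ndarray) -> sparse.csr_matrix:
    """Restrict a graph to vertices where ``mask`` is True (others isolated)."""
    keep = sparse.diags(mask.astype(float))
    return (keep @ graph @ keep).tocsr()


def largest_component(graph: sparse.csr_matrix, candidates: np.ndarray) -> np.ndarray:
    """Largest connected component of ``graph`` restricted to candidate vertices."""
    g = subgraph(graph, candidates)
    n_comp, lab = connected_components(g, directed=False)
    lab = np.where(candidates, lab, -1)
    ids, counts = np.unique(lab[lab >= 0], return_counts=True)
    best = ids[np.argmax(counts)]
    return lab == best
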