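"""Functional delineation of V1: vertical-meridian borders from the polar
angle map, the foveal confluence line, and geodesic distance from it.

The V1/V2 border lies at vertical-meridian representations: the dorsal
border at the lower vertical meridian (-90 deg) and the ventral border at
the upper vertical meridian (+90 deg).  Borders are found by banding
(vertices within ``tol_deg`` of the meridian), taking the largest connected
band component, and thinning it to a shortest path from its most foveal to
its most peripheral vertex; edges are penalized by angular distance from
the meridian so the path hugs the meridian representation.

The foveal confluence is a curved line linking the foveal endpoints of the
two borders through the most foveal measurements: a shortest path whose
edge weights are inflated by eccentricity, so it prefers low-eccentricity
cortex.  Distance from the fovea is the multi-source geodesic from the
line (or, optionally, a single-source geodesic from its midpoint, which
yields closely correlated fields).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .errors import DelineationError
from .mesh import GeodesicField, edge_graph, geodesic_distance, largest_component
from .types import RetinotopicMap, TriangleMesh, wrap_angle_deg

log = logging.getLogger(__name__)


@dataclass
class V1Delineation:
    """Borders, confluence line, V1 membership and distance-from-fovea."""

    v1_vertices: np.ndarray
    dorsal_border: list[int]
    ventral_border: list[int]
    confluence_line: list[int]
    distance_from_fovea: GeodesicField

    def v1_mask(self, n_vertices: int) -> np.ndarray:
        m = np.zeros(n_vertices, dtype=bool)
        m[self.v1_vertices] = True
        return m


def _angdist(angles: np.ndarray, meridian: float) -> np.ndarray:
    return np.abs(wrap_angle_deg(angles - meridian))


def _weighted_path(graph: sparse.csr_matrix, weights: np.ndarray,
                   source: int, target: int, what: str) -> list[int]:
    """Shortest path with per-edge weights = length * mean vertex penalty."""
    coo = graph.tocoo()
    w = coo.data * 0.5 * (weights[coo.row] + weights[coo.col])
    g = sparse.csr_matrix((w, (coo.row, coo.col)), shape=graph.shape)
    dist, pred = dijkstra(g, directed=False, indices=source, return_predecessors=True)
    if not np.isfinite(dist[target]):
        raise DelineationError(f"{what}: endpoints are disconnected")
    path = [target]
    while path[-1] != source:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return path


def detect_meridian_borders(rmap: RetinotopicMap, mesh: TriangleMesh,
                            v1_hint=None, tol_deg: float = 10.0,
                            graph: sparse.csr_matrix | None = None,
                            ) -> tuple[list[int], list[int]]:
    """Find the dorsal (-90 deg) and ventral (+90 deg) V1 borders.

    Returns two vertex paths ordered from the foveal to the peripheral end.
    Raises :class:`DelineationError` naming the meridian if no band of
    vertices within ``tol_deg`` of it exists.
    """
    rmap.bind(mesh)
    g = edge_graph(mesh) if graph is None else graph
    hint_mask = None
    if v1_hint is not None:
        hint_mask = np.zeros(mesh.n_vertices, dtype=bool)
        hint_mask[np.asarray(list(v1_hint), dtype=np.int64)] = True

    borders = {}
    for name, meridian in (("dorsal", -90.0), ("ventral", +90.0)):
        ad = _angdist(rmap.polar_angle.values, meridian)
        band = rmap.valid & (ad <= tol_deg)
        if hint_mask is not None:
            band &= hint_mask
        if not band.any():
            raise DelineationError(
                f"no vertices within {tol_deg} deg of the "
                f"{name} ({meridian:+.0f} deg) meridian")
        comp = largest_component(g, band)
        idx = np.flatnonzero(comp)
        ecc = rmap.eccentricity.values[idx]
        # endpoints: extreme eccentricity, ties broken toward the meridian
        foveal = int(idx[np.lexsort((idx, ad[idx], ecc))[0]])
        peripheral = int(idx[np.lexsort((idx, ad[idx], -ecc))[0]])
        if foveal == peripheral:
            raise DelineationError(
                f"{name} meridian band degenerates to a single vertex")
        penalty = np.where(comp, 1.0 + ad / max(tol_deg, 1e-9), np.inf)
        borders[name] = _weighted_path(g, penalty, foveal, peripheral,
                                       f"{name} border")
    return borders["dorsal"], borders["ventral"]


def foveal_confluence_line(rmap: RetinotopicMap, mesh: TriangleMesh,
                           borders: tuple[list[int], list[int]],
                           foveal_quantile: float = 0.05,
                           e_scale: float = 1.0,
                           v1_hint=None,
                           graph: sparse.csr_matrix | None = None) -> list[int]:
    """Curved line through the most foveal measurements linking the foveal
    endpoints of the dorsal and ventral borders.

    Edge weights are ``length * (1 + E_mid / e_scale)`` so the path prefers
    low-eccentricity vertices.  If any path vertex exceeds the
    ``foveal_quantile`` quantile of V1 eccentricity (+0.5 deg tolerance), a
    warning is logged.
    """
    dorsal, ventral = borders
    if not dorsal or not ventral:
        raise DelineationError("borders are empty; cannot build confluence line")
    g = edge_graph(mesh) if graph is None else graph
    ecc = rmap.eccentricity.values
    fill = np.nanmax(np.where(rmap.valid, ecc, np.nan))
    ecc_eff = np.where(rmap.valid, ecc, fill)
    penalty = 1.0 + ecc_eff / e_scale
    path = _weighted_path(g, penalty, dorsal[0], ventral[0], "confluence line")

    scope = (np.asarray(list(v1_hint), dtype=np.int64) if v1_hint is not None
             else np.flatnonzero(rmap.valid))
    q = float(np.quantile(ecc[scope][rmap.valid[scope]], foveal_quantile))
    path_valid = [v for v in path if rmap.valid[v]]
    worst = float(np.max(ecc[path_valid])) if path_valid else 0.0
    if worst > q + 0.5:
        log.warning(
            "confluence line passes through eccentricity %.2f deg, above the "
            "%.0f%% foveal quantile %.2f deg", worst, 100 * foveal_quantile, q)
    return path


def distance_from_fovea(mesh: TriangleMesh, v1_vertices, confluence_line: list[int],
                        mode: str = "line",
                        graph: sparse.csr_matrix | None = None) -> GeodesicField:
    """Geodesic distance of every vertex from the foveal confluence.

    ``mode='line'``: multi-source geodesic from every line vertex.
    ``mode='midpoint'``: single-source geodesic from the line's middle
    vertex (treating the confluence as a point).
    """
    if not confluence_line:
        raise DelineationError("confluence line is empty")
    if mode == "line":
        sources = confluence_line
    elif mode == "midpoint":
        sources = [confluence_line[len(confluence_line) // 2]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return geodesic_distance(mesh, sources, graph=graph)


def delineate_v1(rmap: RetinotopicMap, mesh: TriangleMesh,
                 v1_hint=None, tol_deg: float = 10.0,
                 foveal_quantile: float = 0.05, e_scale: float = 1.0,
                 ecc_max: float | None = None,
                 distance_mode: str = "line") -> V1Delineation:
    """Full delineation: borders, confluence line, V1 region and distances.

    When ``v1_hint`` is absent, V1 is the connected region of valid
    vertices around the confluence line, capped at the ``ecc_max``
    eccentricity isoline (the stimulated-field extent) when given.
    """
    g = edge_graph(mesh)
    borders = detect_meridian_borders(rmap, mesh, v1_hint=v1_hint,
                                      tol_deg=tol_deg, graph=g)
    line = foveal_confluence_line(rmap, mesh, borders,
                                  foveal_quantile=foveal_quantile,
                                  e_scale=e_scale, v1_hint=v1_hint, graph=g)
    if v1_hint is not None:
        v1 = np.unique(np.asarray(list(v1_hint), dtype=np.int64))
    else:
        region = rmap.valid.copy()
        if ecc_max is not None:
            region &= rmap.eccentricity.values <= ecc_max
        region[line] = True
        comp = largest_component(g, region)
        v1 = np.flatnonzero(comp)
    field = distance_from_fovea(mesh, v1, line, mode=distance_mode, graph=g)
    return V1Delineation(v1_vertices=v1, dorsal_border=borders[0],
                         ventral_border=borders[1], confluence_line=line,
                         distance_from_fovea=field)
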