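"""Shared fixtures: small analytic meshes, a both-diagonal grid for
geodesic oracles, and session-scoped synthetic subjects."""

from __future__ import annotations

import numpy as np
import pytest

import sulcmap as sm
from sulcmap.types import TriangleMesh


@pytest.fixture
def unit_square_mesh() -> TriangleMesh:
    """Unit square in the z=0 plane split into two triangles (area 1)."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleMesh(verts, faces)


def make_grid_mesh(n_rows: int, n_cols: int, spacing: float = 1.0,
                   both_diagonals: bool = True) -> TriangleMesh:
    """Flat triangulated grid; with both diagonals per cell the edge graph
    carries the octile metric (worst-direction overestimate 1/cos(pi/8))."""
    ii, jj = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    verts = np.column_stack([ii.ravel() * spacing, jj.ravel() * spacing,
                             np.zeros(n_rows * n_cols)])
    faces = []
    for i in range(n_rows - 1):
        for j in range(n_cols - 1):
            v00 = i * n_cols + j
            v01, v10, v11 = v00 + 1, v00 + n_cols, v00 + n_cols + 1
            faces += [[v00, v10, v11], [v00, v11, v01]]
            if both_diagonals:
                faces += [[v00, v10, v01], [v10, v11, v01]]
    return TriangleMesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def grid20() -> TriangleMesh:
    return make_grid_mesh(20, 20)


def bellman_ford_distances(mesh: TriangleMesh, sources) -> np.ndarray:
    """Independent brute-force shortest-path oracle (edge relaxation to
    convergence); no scipy graph code involved."""
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    dist = np.full(mesh.n_vertices, np.inf)
    dist[np.asarray(list(sources), dtype=int)] = 0.0
    for _ in range(mesh.n_vertices):
        new = dist.copy()
        np.minimum.at(new, e[:, 1], dist[e[:, 0]] + w)
        np.minimum.at(new, e[:, 0], dist[e[:, 1]] + w)
        if np.array_equal(new, dist):
            break
        dist = new
    return dist


@pytest.fixture(scope="session")
def human_subject():
    """Noiseless synthetic human hemisphere (pial, white, truth)."""
    preset = sm.human_preset()
    return (*sm.generate_v1_patch(preset, seed=11, subject_id="h-test"), preset)


@pytest.fixture(scope="session")
def macaque_subject():
    preset = sm.macaque_preset()
    return (*sm.generate_v1_patch(preset, seed=12, subject_id="m-test"), preset)


@pytest.fixture(scope="session")
def human_delineation(human_subject):
    pial, white, truth, preset = human_subject
    return sm.delineate_v1(truth.true_map, pial, ecc_max=preset.stimulus_radius)
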