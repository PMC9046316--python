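"""Core in-memory containers: triangle meshes, per-vertex overlays,
retinotopic maps, and named vertex label sets.

Conventions used package-wide
-----------------------------
* Vertex indexing is 0-based everywhere.
* Polar angle is in degrees with 0 deg = contralateral horizontal meridian,
  +90 deg = upper vertical meridian, -90 deg = lower vertical meridian;
  values lie in (-180, 180].
* Eccentricity is in degrees of visual angle, >= 0.
* Mesh coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, IntegrityError, UnitsError

VALID_UNITS = ("deg", "mm", "unitless")
SURFACE_KINDS = ("pial", "white", "inflated", "sphere", "synthetic")


def wrap_angle_deg(angle):
    """Wrap angles (degrees) into (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped


def wrap_angle_rad(angle):
    """Wrap angles (radians) into (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    return -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)


@dataclass
class TriangleMesh:
    """A triangulated cortical surface patch.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    surface_kind : one of ``pial, white, inflated, sphere, synthetic``
    """

    vertices: np.ndarray
    faces: np.ndarray
    surface_kind: str = "synthetic"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DimensionError(f"faces must be (m, 3), got {self.faces.shape}")
        if self.surface_kind not in SURFACE_KINDS:
            raise ValueError(f"surface_kind must be one of {SURFACE_KINDS}")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self, check_degenerate: bool = True) -> None:
        """Check structural invariants; raise :class:`IntegrityError` on failure."""
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise IntegrityError(
                f"face index out of range: max index {self.faces.max()} "
                f"with {self.n_vertices} vertices"
            )
        if check_degenerate and self.n_faces:
            tri = self.vertices[self.faces]
            cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            areas = 0.5 * np.linalg.norm(cross, axis=1)
            if np.any(areas <= 0):
                bad = int(np.argmin(areas))
                raise IntegrityError(f"face {bad} has zero area (collinear vertices)")

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with u < v."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)


@dataclass
class VertexOverlay:
    """One scalar per vertex with units and a validity mask."""

    values: np.ndarray
    units: str = "unitless"
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise DimensionError("overlay values must be 1-D")
        if self.units not in VALID_UNITS:
            raise UnitsError(f"units must be one of {VALID_UNITS}, got {self.units!r}")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape:
                raise DimensionError("valid_mask shape must match values")
            self.valid_mask = self.valid_mask & np.isfinite(self.values)

    def __len__(self) -> int:
        return self.values.shape[0]

    def bind(self, mesh: TriangleMesh) -> "VertexOverlay":
        """Check the overlay length against a mesh; return self for chaining."""
        if len(self) != mesh.n_vertices:
            raise DimensionError(
                f"overlay has {len(self)} values but mesh has {mesh.n_vertices} vertices"
            )
        return self

    def require_units(self, units: str) -> "VertexOverlay":
        if self.units != units:
            raise UnitsError(f"expected units {units!r}, got {self.units!r}")
        return self


def check_same_length(*overlays: VertexOverlay) -> int:
    ns = {len(o) for o in overlays}
    if len(ns) != 1:
        raise DimensionError(f"overlays have mismatched lengths: {sorted(ns)}")
    return ns.pop()


@dataclass
class RetinotopicMap:
    """Per-vertex polar angle (deg), eccentricity (deg) and optional coherence."""

    polar_angle: VertexOverlay
    eccentricity: VertexOverlay
    coherence: VertexOverlay | None = None

    def __post_init__(self):
        self.polar_angle.require_units("deg")
        self.eccentricity.require_units("deg")
        overlays = [self.polar_angle, self.eccentricity]
        if self.coherence is not None:
            self.coherence.require_units("unitless")
            overlays.append(self.coherence)
        check_same_length(*overlays)
        pa = self.polar_angle.values
        m = self.polar_angle.valid_mask
        if np.any((pa[m] <= -180.0) | (pa[m] > 180.0)):
            raise ValueError("polar angle must lie in (-180, 180] degrees")
        ecc = self.eccentricity.values
        me = self.eccentricity.valid_mask
        if np.any(ecc[me] < 0):
            raise ValueError("eccentricity must be >= 0")

    @property
    def n_vertices(self) -> int:
        return len(self.polar_angle)

    @property
    def valid(self) -> np.ndarray:
        """Vertices valid in both angle and eccentricity overlays."""
        v = self.polar_angle.valid_mask & self.eccentricity.valid_mask
        return v

    def bind(self, mesh: TriangleMesh) -> "RetinotopicMap":
        self.polar_angle.bind(mesh)
        return self


@dataclass
class LabelSet:
    """Named vertex subsets (e.g. V1, rCaS, eCaS) with cohort metadata.

    Labels may overlap: the retrocalcarine sulcus is typically a subset of V1.
    """

    labels: dict[str, np.ndarray] = field(default_factory=dict)
    species: str = "human"
    hemisphere: str = "left"
    subject_id: str = ""

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, idx in self.labels.items():
            arr = np.unique(np.asarray(list(idx) if isinstance(idx, (set, frozenset)) else idx,
                                       dtype=np.int64))
            clean[name] = arr
        self.labels = clean

    def bind(self, mesh: TriangleMesh) -> "LabelSet":
        for name, idx in self.labels.items():
            if idx.size and (idx.min() < 0 or idx.max() >= mesh.n_vertices):
                raise IntegrityError(
                    f"label {name!r} references vertex {idx.max()} "
                    f"but mesh has {mesh.n_vertices} vertices"
                )
        return self

    def __getitem__(self, name: str) -> np.ndarray:
        return self.labels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.labels

    def names(self) -> list[str]:
        return list(self.labels.keys())

    def mask(self, name: str, n_vertices: int) -> np.ndarray:
        m = np.zeros(n_vertices, dtype=bool)
        m[self.labels[name]] = True
        return m
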