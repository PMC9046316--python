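"""Per-sulcus morphometric and retinotopic summaries: surface areas on the
pial and white surfaces, percentage of V1, mean eccentricity and
eccentricity/distance ranges, visual-field coverage in Cartesian
coordinates, and group overlap maps across subjects on a shared mesh.

Vertices of a sulcus label that fall outside V1 are included in its area
(the sulcus exists anatomically regardless) but excluded from its
eccentricity statistics, mirroring how hemispheres whose external calcarine
extends beyond V1 are handled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .delineate import V1Delineation
from .errors import DimensionError
from .mesh import surface_area
from .types import LabelSet, RetinotopicMap, TriangleMesh, VertexOverlay

log = logging.getLogger(__name__)


@dataclass
class SulcalSummary:
    """One subject x hemisphere x sulcus row of the group table."""

    subject_id: str
    species: str
    hemisphere: str
    sulcus: str
    area_pial: float
    area_white: float
    pct_of_v1: float
    mean_ecc: float
    ecc_min: float
    ecc_max: float
    dist_min: float
    dist_max: float
    n_vertices: int

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_sulcus(rmap: RetinotopicMap, pial: TriangleMesh,
                     white: TriangleMesh, labels: LabelSet,
                     delineation: V1Delineation, sulcus: str,
                     coherence_weighted: bool = False) -> SulcalSummary:
    """Morphometric + retinotopic summary of one labeled sulcus.

    Areas are measured on both surfaces via one-third vertex attribution;
    ``pct_of_v1`` normalizes the pial area of the label's intersection with
    V1 by V1's pial area.  Eccentricity statistics use valid labeled
    vertices inside V1 (optionally coherence-weighted).
    """
    if sulcus not in labels:
        raise KeyError(f"label {sulcus!r} not present in label set")
    labels.bind(pial)
    n = pial.n_vertices
    label_mask = labels.mask(sulcus, n)
    v1_mask = delineation.v1_mask(n)

    area_pial = surface_area(pial, np.flatnonzero(label_mask))
    area_white = surface_area(white, np.flatnonzero(label_mask))
    v1_area = surface_area(pial, delineation.v1_vertices)
    inter = label_mask & v1_mask
    pct = 100.0 * surface_area(pial, np.flatnonzero(inter)) / v1_area if v1_area else 0.0
    if not inter.any():
        log.info("label %r is disjoint from V1 for subject %s",
                 sulcus, labels.subject_id)

    stat_mask = inter & rmap.valid & delineation.distance_from_fovea.distance.valid_mask
    ecc = rmap.eccentricity.values[stat_mask]
    dist = delineation.distance_from_fovea.distance.values[stat_mask]
    if ecc.size:
        if coherence_weighted and rmap.coherence is not None:
            w = rmap.coherence.values[stat_mask]
            mean_ecc = float(np.average(ecc, weights=w)) if w.sum() > 0 else float(np.mean(ecc))
        else:
            mean_ecc = float(np.mean(ecc))
        ecc_min, ecc_max = float(ecc.min()), float(ecc.max())
        dist_min, dist_max = float(dist.min()), float(dist.max())
    else:
        mean_ecc = ecc_min = ecc_max = dist_min = dist_max = float("nan")
    return SulcalSummary(
        subject_id=labels.subject_id, species=labels.species,
        hemisphere=labels.hemisphere, sulcus=sulcus,
        area_pial=area_pial, area_white=area_white, pct_of_v1=pct,
        mean_ecc=mean_ecc, ecc_min=ecc_min, ecc_max=ecc_max,
        dist_min=dist_min, dist_max=dist_max, n_vertices=int(stat_mask.sum()))


def summaries_frame(summaries) -> pd.DataFrame:
    """Tidy DataFrame, one row per subject x hemisphere x sulcus."""
    return pd.DataFrame([s.as_dict() for s in summaries])


@dataclass
class FieldCoverage:
    """Cartesian visual-field positions (deg), one per valid labeled vertex."""

    points: np.ndarray  # (k, 2): x, y
    vertices: np.ndarray


def field_coverage(rmap: RetinotopicMap, label_vertices,
                   hemisphere: str = "left") -> FieldCoverage:
    """Convert polar angle/eccentricity to Cartesian visual-field points.

    Under the package convention (0 deg = contralateral horizontal
    meridian, +90 = upper vertical) the contralateral hemifield is x > 0
    for the left hemisphere and x < 0 for the right.
    """
    idx = np.asarray(list(label_vertices) if isinstance(label_vertices, (set, frozenset))
                     else label_vertices, dtype=np.int64)
    valid = rmap.valid[idx]
    idx = idx[valid]
    theta = np.deg2rad(rmap.polar_angle.values[idx])
    ecc = rmap.eccentricity.values[idx]
    sign = 1.0 if hemisphere == "left" else -1.0
    x = sign * ecc * np.cos(theta)
    y = ecc * np.sin(theta)
    return FieldCoverage(points=np.column_stack([x, y]), vertices=idx)


def group_overlap(label_sets, sulcus: str, n_vertices: int,
                  ) -> tuple[VertexOverlay, VertexOverlay]:
    """Per-vertex subject counts and fractions for one sulcus across a cohort.

    All label sets must be indexed on the same template mesh (same vertex
    count); nonzero counts range over [1, n_subjects].
    """
    counts = np.zeros(n_vertices)
    n_subjects = 0
    for ls in label_sets:
        if sulcus not in ls:
            continue
        idx = ls[sulcus]
        if idx.size and idx.max() >= n_vertices:
            raise DimensionError(
                f"label set for subject {ls.subject_id!r} indexes vertex "
                f"{idx.max()} on a template of {n_vertices} vertices")
        counts[idx] += 1
        n_subjects += 1
    frac = counts / n_subjects if n_subjects else counts
    return (VertexOverlay(counts, units="unitless"),
            VertexOverlay(frac, units="unitless"))
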