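"""Readers and writers for the surface-geometry and overlay formats the
pipeline touches: FreeSurfer binary surfaces, curv overlays and label files,
GIFTI (.surf.gii / .func.gii / .label.gii), CSV overlays and JSON label sets.

FreeSurfer binary parsing is delegated to :mod:`nibabel.freesurfer`; this
module adds the magic-byte pre-checks (so malformed files raise
:class:`~sulcmap.errors.FormatError` naming the byte offset), validity-mask
handling, and the package's container types.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel import freesurfer as fsio

from .errors import DimensionError, FormatError, IntegrityError
from .types import LabelSet, TriangleMesh, VertexOverlay

log = logging.getLogger(__name__)

TRIANGLE_MAGIC = b"\xff\xff\xfe"  # FreeSurfer binary triangle-surface magic
CURV_MAGIC = b"\xff\xff\xff"      # curv "new format" magic (-1 as int24)


def _check_magic(path: Path, expected: bytes, what: str) -> None:
    data = path.read_bytes()
    if len(data) < len(expected):
        raise FormatError(
            f"{path}: truncated {what} file ({len(data)} bytes) — "
            f"expected magic {expected.hex()} at byte offset 0"
        )
    if data[: len(expected)] != expected:
        raise FormatError(
            f"{path}: bad magic bytes {data[:len(expected)].hex()} at byte offset 0 — "
            f"expected {expected.hex()} for a {what} file"
        )


def _infer_format(path: Path, kind: str) -> str:
    name = path.name.lower()
    if name.endswith(".gii"):
        return {"surface": "gifti", "overlay": "gifti-func", "label": "gifti-label"}[kind]
    if name.endswith(".csv"):
        return "csv"
    if name.endswith(".json"):
        return "json"
    if kind == "label" or name.endswith(".label"):
        return "freesurfer-label"
    return {"surface": "freesurfer-binary", "overlay": "freesurfer-curv"}[kind]


# ---------------------------------------------------------------------------
# surfaces

def read_surface(path, format: str | None = None, surface_kind: str = "pial") -> TriangleMesh:
    """Read a triangle mesh from FreeSurfer binary or GIFTI.

    Vertex order is preserved exactly as stored; the mesh's structural
    invariants (index range, non-degenerate faces) are checked on load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path, "surface")
    if fmt == "freesurfer-binary":
        _check_magic(path, TRIANGLE_MAGIC, "FreeSurfer triangle surface")
        try:
            verts, faces = fsio.read_geometry(str(path))
        except Exception as exc:  # truncation past the magic
            raise FormatError(
                f"{path}: unreadable FreeSurfer surface past byte offset 3 "
                f"(file is {path.stat().st_size} bytes): {exc}"
            ) from exc
    elif fmt == "gifti":
        img = nib.load(str(path))
        verts = faces = None
        for arr in img.darrays:
            if arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                verts = arr.data
            elif arr.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                faces = arr.data
        if verts is None or faces is None:
            raise FormatError(f"{path}: GIFTI file lacks pointset/triangle arrays")
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    mesh = TriangleMesh(np.asarray(verts), np.asarray(faces), surface_kind=surface_kind)
    mesh.validate(check_degenerate=False)
    return mesh


def write_surface(mesh: TriangleMesh, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path, "surface")
    if fmt == "freesurfer-binary":
        fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown surface format {fmt!r}")


# ---------------------------------------------------------------------------
# overlays

def read_overlay(path, format: str | None = None, units: str = "unitless",
                 mesh: TriangleMesh | None = None, n_vertices: int | None = None,
                 one_based: bool = False) -> VertexOverlay:
    """Read a per-vertex scalar overlay.

    NaN values become entries of the validity mask.  CSV files carry two
    columns ``vertex,value`` (header optional); indices are 0-based unless
    ``one_based`` is set.  ``n_vertices`` (or ``mesh``) sizes sparse CSV
    overlays; vertices absent from the file are invalid.
    """
    path = Path(path)
    fmt = format or _infer_format(path, "overlay")
    if mesh is not None and n_vertices is None:
        n_vertices = mesh.n_vertices
    if fmt == "freesurfer-curv":
        _check_magic(path, CURV_MAGIC, "FreeSurfer curv")
        try:
            values = np.asarray(fsio.read_morph_data(str(path)), dtype=np.float64)
        except Exception as exc:
            raise FormatError(
                f"{path}: unreadable curv data past byte offset 3: {exc}") from exc
    elif fmt == "gifti-func":
        img = nib.load(str(path))
        values = np.asarray(img.darrays[0].data, dtype=np.float64)
    elif fmt == "csv":
        df = _read_vertex_value_csv(path)
        idx = df["vertex"].to_numpy(dtype=np.int64)
        if one_based:
            idx = idx - 1
        if idx.size and idx.min() < 0:
            raise IntegrityError(f"{path}: negative vertex index (is the file 1-based?)")
        n = n_vertices if n_vertices is not None else (int(idx.max()) + 1 if idx.size else 0)
        if idx.size and idx.max() >= n:
            raise DimensionError(
                f"{path}: vertex index {idx.max()} exceeds vertex count {n}")
        values = np.full(n, np.nan)
        values[idx] = df["value"].to_numpy(dtype=np.float64)
    else:
        raise ValueError(f"unknown overlay format {fmt!r}")
    ov = VertexOverlay(values, units=units)
    if mesh is not None:
        ov.bind(mesh)
    elif n_vertices is not None and len(ov) != n_vertices:
        raise DimensionError(f"{path}: {len(ov)} values, expected {n_vertices}")
    return ov


def _read_vertex_value_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: CSV overlay needs two columns (vertex,value)")
    first = df.iloc[0, 0]
    if isinstance(first, str) and not first.strip().lstrip("-").isdigit():
        df = df.iloc[1:]  # header row
    out = pd.DataFrame({
        "vertex": pd.to_numeric(df.iloc[:, 0]),
        "value": pd.to_numeric(df.iloc[:, 1]),
    })
    return out


def write_overlay(overlay: VertexOverlay, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path, "overlay")
    values = overlay.values.copy()
    values[~overlay.valid_mask] = np.nan
    if fmt == "freesurfer-curv":
        fsio.write_morph_data(str(path), values.astype(np.float32))
    elif fmt == "gifti-func":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(values.astype(np.float32), intent="NIFTI_INTENT_NONE")
        ])
        nib.save(img, str(path))
    elif fmt == "csv":
        pd.DataFrame({"vertex": np.arange(len(values)), "value": values}).to_csv(
            path, index=False)
    else:
        raise ValueError(f"unknown overlay format {fmt!r}")


# ---------------------------------------------------------------------------
# labels

def read_labels(path, format: str | None = None, name: str | None = None,
                species: str = "human", hemisphere: str = "left",
                subject_id: str = "") -> LabelSet:
    """Read a label set from FreeSurfer .label (one label), GIFTI label, or JSON."""
    path = Path(path)
    fmt = format or _infer_format(path, "label")
    if fmt == "freesurfer-label":
        idx = fsio.read_label(str(path))
        label_name = name or path.stem.split(".")[-1]
        labels = {label_name: np.asarray(idx, dtype=np.int64)}
        meta = {}
    elif fmt == "gifti-label":
        img = nib.load(str(path))
        data = np.asarray(img.darrays[0].data).astype(np.int64)
        table = img.labeltable.get_labels_as_dict()
        labels = {}
        for key, label_name in table.items():
            if int(key) == 0:
                continue
            labels[label_name] = np.flatnonzero(data == int(key))
        meta = {}
    elif fmt == "json":
        doc = json.loads(path.read_text())
        labels = {k: np.asarray(v, dtype=np.int64) for k, v in doc["labels"].items()}
        meta = {k: doc[k] for k in ("species", "hemisphere", "subject_id") if k in doc}
    else:
        raise ValueError(f"unknown label format {fmt!r}")
    for label_name, idx in labels.items():
        if len(np.unique(idx)) != len(idx):
            log.warning("label %r contains duplicate vertex indices; deduplicating",
                        label_name)
    return LabelSet(labels=labels,
                    species=meta.get("species", species),
                    hemisphere=meta.get("hemisphere", hemisphere),
                    subject_id=meta.get("subject_id", subject_id))


def write_labels(labelset: LabelSet, path, format: str | None = None,
                 name: str | None = None) -> None:
    """Write a label set.

    FreeSurfer .label files hold a single label: pass ``name`` to select it.
    JSON and GIFTI label files hold all labels (GIFTI assigns each vertex the
    last label containing it, since that format cannot express overlap).
    """
    path = Path(path)
    fmt = format or _infer_format(path, "label")
    if fmt == "freesurfer-label":
        if name is None:
            if len(labelset.labels) != 1:
                raise ValueError("FreeSurfer label files hold one label; pass name=")
            name = next(iter(labelset.labels))
        idx = labelset.labels[name]
        lines = [f"#!ascii label, from sulcmap ({name})", str(len(idx))]
        lines += [f"{i}  0.000  0.000  0.000 0.0000000000" for i in idx]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "gifti-label":
        n = 1 + (max((int(v.max()) for v in labelset.labels.values() if v.size), default=0))
        data = np.zeros(n, dtype=np.int32)
        table = nib.gifti.GiftiLabelTable()
        table.labels.append(_gifti_label(0, "???"))
        for key, (label_name, idx) in enumerate(labelset.labels.items(), start=1):
            data[idx] = key
            table.labels.append(_gifti_label(key, label_name))
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(data, intent="NIFTI_INTENT_LABEL",
                                     datatype="NIFTI_TYPE_INT32")])
        img.labeltable = table
        nib.save(img, str(path))
    elif fmt == "json":
        doc = {
            "labels": {k: [int(i) for i in v] for k, v in labelset.labels.items()},
            "species": labelset.species,
            "hemisphere": labelset.hemisphere,
            "subject_id": labelset.subject_id,
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown label format {fmt!r}")


def _gifti_label(key: int, name: str):
    lab = nib.gifti.GiftiLabel(key=key)
    lab.label = name
    lab.red = lab.green = lab.blue = 0.5
    lab.alpha = 1.0
    return lab
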