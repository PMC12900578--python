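"""Mesh and landmark-annotation I/O.

Reads dental-cast surface meshes (STL binary/ASCII, PLY) and landmark
annotations in the MeshLab PickPoints XML format (``.pp``), plus a plain
JSON interchange format, and converts meshes to 6-channel point clouds
(positions + area-weighted vertex normals).
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import trimesh

from .core import (
    AnnotationError,
    DegenerateMeshError,
    DentalCastMesh,
    FDI_LABELS,
    FormatError,
    LandmarkSet,
    PointCloud6D,
)

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_pickpoints",
    "write_pickpoints",
    "read_landmarks_json",
    "write_landmarks_json",
    "mesh_to_pointcloud",
]


def read_mesh(path: str | os.PathLike) -> DentalCastMesh:
    """Read an STL or PLY mesh into a :class:`DentalCastMesh`.

    STL files are triangle soup: vertices shared between triangles are
    repeated in the file. Duplicates are merged by *exact* coordinate match
    (bit-wise equality); no tolerance welding is applied, so fine gingival
    detail is never collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        loaded = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises many types for bad files
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if verts.size == 0 or faces.size == 0:
        raise FormatError(f"mesh {path} has no geometry")
    verts, faces = _merge_exact_duplicates(verts, faces)
    if len(verts) < 4:
        raise DegenerateMeshError(
            f"mesh {path} has only {len(verts)} distinct vertices after merging"
        )
    # drop degenerate faces produced by merging (zero-area slivers keep
    # three distinct indices and are retained)
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    keep = (a != b) & (b != c) & (a != c)
    return DentalCastMesh(verts, faces[keep], cast_id=path.stem)


def _merge_exact_duplicates(verts: np.ndarray, faces: np.ndarray):
    """Merge vertices that are bit-wise identical, remapping faces."""
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    return uniq, inverse[faces]


def write_mesh(mesh: DentalCastMesh, path: str | os.PathLike) -> None:
    """Write a mesh as STL (``.stl``) or PLY (``.ply``) based on extension."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


# ---------------------------------------------------------------------------
# MeshLab PickPoints (.pp)
# ---------------------------------------------------------------------------

def read_pickpoints(path: str | os.PathLike) -> LandmarkSet:
    """Read a MeshLab PickPoints ``.pp`` XML annotation.

    Point names must be exactly the twelve FDI codes 16..26; order in the
    file is arbitrary and is normalized to the canonical 16 → 26 order.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except (ET.ParseError, OSError) as exc:
        raise FormatError(f"cannot parse PickPoints file {path}: {exc}") from exc
    root = tree.getroot()
    labels: list[str] = []
    points: list[list[float]] = []
    for el in root.iter("point"):
        name = el.get("name")
        if name is None:
            raise AnnotationError(f"{path}: point element without a name")
        try:
            xyz = [float(el.get(k)) for k in ("x", "y", "z")]
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"{path}: non-numeric coordinate on point {name!r}"
            ) from exc
        labels.append(name.strip())
        points.append(xyz)
    _check_labels(labels, str(path))
    return LandmarkSet(tuple(labels), np.array(points), cast_id=path.stem)


def _check_labels(labels: list[str], where: str) -> None:
    missing = sorted(set(FDI_LABELS) - set(labels))
    extra = sorted(set(labels) - set(FDI_LABELS))
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if missing or extra or dupes:
        raise AnnotationError(
            f"{where}: bad landmark labels: missing={missing} "
            f"unknown={extra} duplicated={dupes}"
        )


def write_pickpoints(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    """Write landmarks as MeshLab-compatible PickPoints XML.

    Attribute conventions follow MeshLab 2022.02: ``x``/``y``/``z``/``name``
    plus ``active="1"`` (ignored on read); coordinates to six decimals.
    """
    root = ET.Element("PickedPoints")
    doc = ET.SubElement(root, "DocumentData")
    ET.SubElement(doc, "DataFileName", {"name": f"{landmarks.cast_id or 'cast'}.stl"})
    for label, p in zip(landmarks.labels, landmarks.points):
        ET.SubElement(
            root,
            "point",
            {
                "x": f"{p[0]:.6f}",
                "y": f"{p[1]:.6f}",
                "z": f"{p[2]:.6f}",
                "name": label,
                "active": "1",
            },
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    try:
        tree.write(str(path), xml_declaration=True, encoding="unicode")
    except OSError as exc:
        raise OSError(f"cannot write PickPoints file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def write_landmarks_json(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    """Write landmarks as ``{cast_id, landmarks: [{label, x, y, z}]}``."""
    payload = {
        "cast_id": landmarks.cast_id,
        "landmarks": [
            {"label": l, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
            for l, p in zip(landmarks.labels, landmarks.points)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks_json(path: str | os.PathLike) -> LandmarkSet:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise FormatError(f"cannot read landmark JSON {path}: {exc}") from exc
    labels = [str(e["label"]) for e in payload["landmarks"]]
    _check_labels(labels, str(path))
    pts = np.array([[e["x"], e["y"], e["z"]] for e in payload["landmarks"]])
    return LandmarkSet(tuple(labels), pts, cast_id=payload.get("cast_id", ""))


# ---------------------------------------------------------------------------
# Mesh → point cloud
# ---------------------------------------------------------------------------

def mesh_to_pointcloud(mesh: DentalCastMesh) -> PointCloud6D:
    """Convert a mesh to a 6-channel point cloud (one point per vertex).

    Vertex normals are area-weighted averages of incident face normals
    (accumulating the un-normalized face cross products, whose magnitude is
    twice the face area, then unit-normalizing). Vertices with no incident
    face carry no normal and are dropped.
    """
    v, f = mesh.vertices, mesh.faces
    e1 = v[f[:, 1]] - v[f[:, 0]]
    e2 = v[f[:, 2]] - v[f[:, 0]]
    face_cross = np.cross(e1, e2)  # |.| = 2 * area, direction = face normal
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, f[:, k], face_cross)
    norms = np.linalg.norm(acc, axis=1)
    incident = np.zeros(len(v), dtype=bool)
    incident[f.ravel()] = True
    keep = incident & (norms > 0)
    if not keep.any():
        raise DegenerateMeshError("all vertices isolated or with null normals")
    normals = acc[keep] / norms[keep, None]
    return PointCloud6D(v[keep], normals, frame="cast_mm")
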