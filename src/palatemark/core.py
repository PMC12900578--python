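"""Domain types shared across the landmarking pipeline.

The pipeline localizes twelve palatal gingival-margin landmarks — the most
apical point on the palatal gingival margin of each maxillary tooth from
first molar to first molar (FDI codes 16..26) — on triangular surface
meshes of maxillary dental casts, with coordinates in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical FDI order: patient-right first molar sweeping anteriorly to the
#: right central incisor, then left central incisor to left first molar.
FDI_LABELS: tuple[str, ...] = (
    "16", "15", "14", "13", "12", "11",
    "21", "22", "23", "24", "25", "26",
)

N_LANDMARKS = len(FDI_LABELS)


class PalatemarkError(Exception):
    """Base class for pipeline errors."""


class FormatError(PalatemarkError):
    """Unreadable or malformed input file."""


class DegenerateMeshError(PalatemarkError):
    """Mesh too small or geometrically degenerate for processing."""


class AnnotationError(PalatemarkError):
    """Landmark annotation missing, duplicated, or unrecognized."""


class DegenerateGeometryError(PalatemarkError):
    """Point set too degenerate for the requested geometric operation."""


class FrameError(PalatemarkError):
    """Coordinate-frame mismatch between inputs."""


class ConfigError(PalatemarkError):
    """Inconsistent configuration or weight shapes."""


class DetectionFailureError(PalatemarkError):
    """Too few candidates survived to resolve 12 landmarks."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class SupervisionGapError(PalatemarkError):
    """True landmark lies too far outside a training patch to supervise it."""


class TrainingError(PalatemarkError):
    """Training diverged (non-finite loss)."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class UndefinedStatisticError(PalatemarkError):
    """Statistic undefined for the given input (empty list, zero variance)."""


@dataclass
class DentalCastMesh:
    """Triangular surface mesh of a maxillary dental cast, in millimetres."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    cast_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateMeshError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DegenerateMeshError("faces must be (F, 3)")
        if not np.isfinite(self.vertices).all():
            raise DegenerateMeshError("non-finite vertex coordinates")
        v = len(self.vertices)
        if v < 4:
            raise DegenerateMeshError(f"mesh has {v} vertices; need at least 4")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= v):
            raise DegenerateMeshError("face index out of range")
        if len(self.faces):
            a, b, c = self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]
            if ((a == b) | (b == c) | (a == c)).any():
                raise DegenerateMeshError("degenerate face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class LandmarkSet:
    """Twelve FDI-labeled landmark points, canonically ordered 16 → 26."""

    labels: tuple[str, ...]
    points: np.ndarray  # (12, 3) float
    cast_id: str = ""

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        self.points = np.asarray(self.points, dtype=np.float64)
        if sorted(self.labels) != sorted(FDI_LABELS):
            missing = sorted(set(FDI_LABELS) - set(self.labels))
            extra = sorted(set(self.labels) - set(FDI_LABELS))
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AnnotationError(
                f"landmark labels invalid: missing={missing} unknown={extra} duplicated={dupes}"
            )
        if self.points.shape != (N_LANDMARKS, 3):
            raise AnnotationError(f"expected (12, 3) points, got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise AnnotationError("non-finite landmark coordinates")
        # normalize to canonical order
        if self.labels != FDI_LABELS:
            order = [self.labels.index(l) for l in FDI_LABELS]
            self.points = self.points[order]
            self.labels = FDI_LABELS

    def point(self, label: str) -> np.ndarray:
        return self.points[FDI_LABELS.index(str(label))]

    def with_points(self, points: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.labels, points, self.cast_id)


@dataclass
class PointCloud6D:
    """Point positions plus unit normals; the 6-channel network input."""

    positions: np.ndarray  # (N, 3)
    normals: np.ndarray  # (N, 3), unit length
    frame: str = "cast_mm"  # "cast_mm" | "normalized"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.normals = np.asarray(self.normals, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise DegenerateGeometryError("positions must be (N, 3)")
        if self.normals.shape != self.positions.shape:
            raise DegenerateGeometryError("normals must match positions shape")
        if len(self.positions) < 1:
            raise DegenerateGeometryError("empty point cloud")
        if not np.isfinite(self.positions).all():
            raise DegenerateGeometryError("non-finite positions")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise DegenerateGeometryError("normals must be unit length")
        if self.frame not in ("cast_mm", "normalized"):
            raise FrameError(f"unknown frame tag {self.frame!r}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def features(self) -> np.ndarray:
        """The N×6 array of positions and normals fed to the networks."""
        return np.concatenate([self.positions, self.normals], axis=1)
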