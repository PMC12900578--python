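"""Canonical orientation, bounding-box normalization, and farthest-point sampling.

Casts arrive in arbitrary scanner pose. Preprocessing (1) rotates each
cloud into a deterministic canonical frame via principal axes with fixed
sign rules, (2) centers and isotropically scales it so the longest axis of
its bounding box spans [-1, 1], and (3) evenly downsamples it with greedy
farthest-point sampling (24,000 points at full scale). The composed
similarity transform is retained so predictions can be mapped back to
cast-frame millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DegenerateGeometryError,
    LandmarkSet,
    PalatemarkError,
    PointCloud6D,
)

__all__ = [
    "NormalizationTransform",
    "canonical_orient",
    "normalize_bbox",
    "farthest_point_sample",
    "fps_indices",
    "preprocess_cloud",
]


@dataclass
class NormalizationTransform:
    """Similarity transform q = scale * (R p + t).

    ``scale`` is in normalized units per millimetre; ``rotation`` is a
    proper orthonormal matrix (det +1).
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.scale <= 0:
            raise PalatemarkError("scale must be positive")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise PalatemarkError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "NormalizationTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * (points @ self.rotation.T + self.translation)

    def apply_normals(self, normals: np.ndarray) -> np.ndarray:
        """Normals are direction-only: rotated, never rescaled."""
        return normals @ self.rotation.T

    def invert(self, points: np.ndarray) -> np.ndarray:
        return (points / self.scale - self.translation) @ self.rotation

    def invert_normals(self, normals: np.ndarray) -> np.ndarray:
        return normals @ self.rotation

    def compose(self, outer: "NormalizationTransform") -> "NormalizationTransform":
        """Return the transform equivalent to applying self, then ``outer``."""
        return NormalizationTransform(
            rotation=outer.rotation @ self.rotation,
            translation=outer.rotation @ self.translation
            + outer.translation / self.scale,
            scale=self.scale * outer.scale,
        )

    def apply_landmarks(self, lms: LandmarkSet) -> LandmarkSet:
        return lms.with_points(self.apply(lms.points))

    def invert_landmarks(self, lms: LandmarkSet) -> LandmarkSet:
        return lms.with_points(self.invert(lms.points))


def canonical_orient(
    cloud: PointCloud6D,
) -> tuple[PointCloud6D, NormalizationTransform]:
    """Rotate a cloud into the canonical anatomical frame.

    Principal axes of the positions map to x (widest, transverse),
    y (antero-posterior), z (flattest, occluso-palatal). Signs are fixed
    deterministically: z so the mean normal points up (occlusal +z), y so
    the point of largest |y| lies at negative y (the anterior incisor
    region sticks out furthest), and x = y cross z completes a right-handed
    frame.
    """
    pos = cloud.positions
    if len(pos) < 3:
        raise DegenerateGeometryError("need at least 3 points to orient")
    center = pos.mean(axis=0)
    centered = pos - center
    cov = centered.T @ centered / len(pos)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12 * max(evals[-1], 1.0):
        raise DegenerateGeometryError("rank-deficient covariance; cannot orient")
    x_axis = evecs[:, 2]
    y_axis = evecs[:, 1]
    z_axis = evecs[:, 0]
    if cloud.normals.mean(axis=0) @ z_axis < 0:
        z_axis = -z_axis
    ycoord = centered @ y_axis
    if ycoord[np.argmax(np.abs(ycoord))] > 0:
        y_axis = -y_axis
    x_axis = np.cross(y_axis, z_axis)
    R = np.vstack([x_axis, y_axis, z_axis])
    tf = NormalizationTransform(R, -R @ center, 1.0)
    out = PointCloud6D(tf.apply(pos), tf.apply_normals(cloud.normals), cloud.frame)
    return out, tf


def normalize_bbox(
    cloud: PointCloud6D,
) -> tuple[PointCloud6D, NormalizationTransform]:
    """Center on the bounding box and scale the longest axis to [-1, 1].

    The scale is a single isotropic factor 2 / (longest-axis extent), so
    aspect ratios are preserved; the other axes end up within [-1, 1].
    """
    pos = cloud.positions
    lo, hi = pos.min(axis=0), pos.max(axis=0)
    extent = float((hi - lo).max())
    if extent <= 0:
        raise DegenerateGeometryError("zero spatial extent; cannot normalize")
    scale = 2.0 / extent
    center = (lo + hi) / 2.0
    tf = NormalizationTransform(np.eye(3), -center, scale)
    out = PointCloud6D(tf.apply(pos), cloud.normals.copy(), frame="normalized")
    return out, tf


def fps_indices(
    positions: np.ndarray,
    m: int,
    start: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Greedy max-min farthest-point sampling; returns selected indices.

    The first point is ``start`` if given, else a seeded random point if
    ``seed`` is given, else — deterministically — the point farthest from
    the centroid. Each subsequent point maximizes its minimum distance to
    the selected set; ties break to the lowest index.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = len(positions)
    if not 1 <= m <= n:
        raise PalatemarkError(f"cannot sample {m} points from {n}")
    if start is None:
        if seed is not None:
            start = int(np.random.default_rng(np.random.PCG64(seed)).integers(0, n))
        else:
            d0 = np.linalg.norm(positions - positions.mean(axis=0), axis=1)
            start = int(np.argmax(d0))
    chosen = np.empty(m, dtype=np.int64)
    chosen[0] = start
    dmin = np.linalg.norm(positions - positions[start], axis=1)
    for i in range(1, m):
        nxt = int(np.argmax(dmin))  # argmax returns the first (lowest) index on ties
        chosen[i] = nxt
        np.minimum(dmin, np.linalg.norm(positions - positions[nxt], axis=1), out=dmin)
    return chosen


def farthest_point_sample(
    cloud: PointCloud6D,
    m: int,
    start: int | None = None,
    seed: int | None = None,
) -> PointCloud6D:
    """Downsample a cloud to ``m`` evenly spread points (with their normals)."""
    idx = fps_indices(cloud.positions, m, start=start, seed=seed)
    return PointCloud6D(cloud.positions[idx], cloud.normals[idx], cloud.frame)


def preprocess_cloud(
    cloud: PointCloud6D,
    n_points: int,
    landmarks: LandmarkSet | None = None,
):
    """Full preprocessing: orient, normalize, farthest-point sample.

    Returns ``(sampled_cloud, transform, transformed_landmarks)``; the
    transform composes orientation and normalization and maps cast-frame
    millimetres to the normalized frame (and back via ``invert``).
    """
    oriented, tf1 = canonical_orient(cloud)
    normed, tf2 = normalize_bbox(oriented)
    tf = tf1.compose(tf2)
    sampled = farthest_point_sample(normed, min(n_points, len(normed)))
    lms_norm = tf.apply_landmarks(landmarks) if landmarks is not None else None
    return sampled, tf, lms_norm
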