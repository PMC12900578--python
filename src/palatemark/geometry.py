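"""Point-cloud geodesics, density clustering, and patch extraction.

The refinement stage works on the downsampled point cloud, where mesh
connectivity no longer exists, so along-surface (geodesic) distances are
approximated by shortest paths on a symmetrized k-nearest-neighbour graph.
Coarse candidate points are grouped into 12 clusters with DBSCAN, each
cluster centred, labelled with its FDI tooth identity by angular order
along the arch, and a 6 mm geodesic ball around each centroid becomes a
local refinement patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .core import (
    DetectionFailureError,
    FDI_LABELS,
    LandmarkSet,
    PalatemarkError,
    PointCloud6D,
)
from .preprocess import NormalizationTransform, fps_indices

__all__ = [
    "NeighborGraph",
    "ClusterLabeling",
    "LocalPatch",
    "build_knn_graph",
    "geodesic_distances",
    "geodesic_ball",
    "dbscan_cluster",
    "two_means",
    "resolve_to_12",
    "assign_fdi_labels",
]


@dataclass
class NeighborGraph:
    """Symmetric weighted neighbour graph over a point cloud."""

    n_nodes: int
    matrix: csr_matrix  # symmetric, positive Euclidean edge weights


@dataclass
class ClusterLabeling:
    """DBSCAN-style labeling: per-point cluster id, -1 for noise."""

    labels: np.ndarray  # (n,) int, -1 = noise
    n_clusters: int
    centroids: np.ndarray  # (n_clusters, 3) member means


@dataclass
class LocalPatch:
    """A geodesic ball of cloud points around a (snapped) centre."""

    indices: np.ndarray  # parent indices into the full cloud
    positions: np.ndarray  # (m, 3), same frame as the cloud
    normals: np.ndarray  # (m, 3)
    center: np.ndarray  # (3,) snapped centre position
    radius_mm: float

    def __len__(self) -> int:
        return len(self.indices)


def build_knn_graph(cloud: PointCloud6D, k: int = 8) -> NeighborGraph:
    """Symmetrized k-NN graph with Euclidean weights; always connected.

    If the raw k-NN graph splits into components, the single shortest edge
    between the two nearest components is added, iteratively, until the
    graph is connected — so every geodesic is finite.
    """
    pos = cloud.positions
    n = len(pos)
    if n <= k:
        raise PalatemarkError(f"need more than k={k} points, got {n}")
    tree = cKDTree(pos)
    dist, idx = tree.query(pos, k=k + 1)  # first neighbour is the point itself
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    mat = csr_matrix((vals, (rows, cols)), shape=(n, n))
    mat = mat.maximum(mat.T)  # symmetrize
    mat = _bridge_components(mat, pos)
    return NeighborGraph(n, mat)


def _bridge_components(mat: csr_matrix, pos: np.ndarray) -> csr_matrix:
    while True:
        n_comp, comp = connected_components(mat, directed=False)
        if n_comp == 1:
            return mat
        # bridge component 0 to its nearest other component by the single
        # shortest inter-component edge
        in0 = comp == 0
        idx0 = np.flatnonzero(in0)
        idx1 = np.flatnonzero(~in0)
        tree = cKDTree(pos[idx1])
        d, j = tree.query(pos[idx0])
        a = int(np.argmin(d))
        i_from, i_to, w = idx0[a], idx1[int(j[a])], float(d[a])
        add = csr_matrix(
            ([w, w], ([i_from, i_to], [i_to, i_from])), shape=mat.shape
        )
        mat = mat.maximum(add)


def geodesic_distances(graph: NeighborGraph, source: int) -> np.ndarray:
    """Single-source shortest-path (Dijkstra) distances along the graph."""
    if not 0 <= source < graph.n_nodes:
        raise PalatemarkError(f"source {source} out of range")
    return dijkstra(graph.matrix, directed=False, indices=source)


def geodesic_ball(
    cloud: PointCloud6D,
    graph: NeighborGraph,
    center_point: np.ndarray,
    radius_mm: float,
    transform: NormalizationTransform,
) -> LocalPatch:
    """All points within ``radius_mm`` geodesically of the snapped centre.

    ``center_point`` (any 3-vector in the cloud's frame) is snapped to the
    nearest cloud point; the physical radius is converted to the cloud's
    normalized units via ``transform.scale``.
    """
    if radius_mm <= 0:
        raise PalatemarkError("radius_mm must be > 0")
    center_point = np.asarray(center_point, dtype=np.float64)
    snapped = int(np.argmin(np.linalg.norm(cloud.positions - center_point, axis=1)))
    radius = radius_mm * transform.scale if cloud.frame == "normalized" else radius_mm
    dist = dijkstra(graph.matrix, directed=False, indices=snapped, limit=radius * 1.0001)
    members = np.flatnonzero(dist <= radius)
    return LocalPatch(
        indices=members,
        positions=cloud.positions[members],
        normals=cloud.normals[members],
        center=cloud.positions[snapped].copy(),
        radius_mm=radius_mm,
    )


def dbscan_cluster(
    points: np.ndarray, eps: float, min_samples: int
) -> ClusterLabeling:
    """Density-based clustering with standard DBSCAN semantics.

    Core points have >= ``min_samples`` neighbours within ``eps`` (counting
    themselves); clusters grow by density reachability; border points join
    the first-reached core's cluster; unreachable points are noise.
    Deterministic for a given input order.
    """
    points = np.asarray(points, dtype=np.float64)
    if eps <= 0 or min_samples < 1:
        raise PalatemarkError("eps must be > 0 and min_samples >= 1")
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit(points).labels_
    n_clusters = int(labels.max()) + 1 if (labels >= 0).any() else 0
    centroids = np.array(
        [points[labels == c].mean(axis=0) for c in range(n_clusters)]
    ).reshape(n_clusters, 3)
    return ClusterLabeling(labels, n_clusters, centroids)


def two_means(points: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-means split: Lloyd iterations from the farthest pair.

    Returns a boolean array (True = second cluster). Used when DBSCAN
    merges two landmark groups and a cluster must be split.
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if n < 2:
        raise PalatemarkError("cannot split fewer than 2 points")
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    c = np.stack([points[i], points[j]])
    assign = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        new = ((points[:, None, :] - c[None, :, :]) ** 2).sum(-1).argmin(axis=1) == 1
        if (new == assign).all() and _ > 0:
            break
        assign = new
        for g in (0, 1):
            sel = assign == bool(g)
            if sel.any():
                c[g] = points[sel].mean(axis=0)
    return assign


def resolve_to_12(
    labeling: ClusterLabeling, candidates: np.ndarray
) -> np.ndarray:
    """Force the clustering down (or up) to exactly 12 centroids.

    >12 clusters: keep the 12 largest by membership (ties by compactness,
    i.e. smaller mean squared radius wins). <12: recursively split the
    largest cluster by 2-means; if even all clustered points are too few,
    recruit noise points by nearest-centroid assignment (or, with no
    clusters at all, treat every candidate as one cluster and split).
    """
    candidates = np.asarray(candidates, dtype=np.float64)
    if len(candidates) < 12:
        raise DetectionFailureError(
            f"only {len(candidates)} candidates; need at least 12",
            achieved=len(candidates),
        )
    labels = labeling.labels.copy()
    groups = [np.flatnonzero(labels == c) for c in range(labeling.n_clusters)]
    groups = [g for g in groups if len(g)]
    if not groups:
        groups = [np.arange(len(candidates))]
    clustered = int(sum(len(g) for g in groups))
    if clustered < 12:
        # recruit noise points so a 12-way split is possible
        noise = np.setdiff1d(np.arange(len(candidates)), np.concatenate(groups))
        cents = np.array([candidates[g].mean(axis=0) for g in groups])
        near = ((candidates[noise][:, None, :] - cents[None]) ** 2).sum(-1).argmin(1)
        groups = [
            np.sort(np.concatenate([g, noise[near == gi]]))
            for gi, g in enumerate(groups)
        ]
    while len(groups) > 12:
        key = sorted(
            range(len(groups)),
            key=lambda gi: (
                -len(groups[gi]),
                float(
                    ((candidates[groups[gi]] - candidates[groups[gi]].mean(0)) ** 2)
                    .sum(1)
                    .mean()
                ),
            ),
        )
        groups = [groups[gi] for gi in sorted(key[:12])]
    while len(groups) < 12:
        order = sorted(range(len(groups)), key=lambda gi: -len(groups[gi]))
        gi = next((g for g in order if len(groups[g]) >= 2), None)
        if gi is None:
            raise DetectionFailureError(
                f"cannot split singleton clusters to reach 12 "
                f"({len(groups)} achieved)",
                achieved=len(groups),
            )
        g = groups.pop(gi)
        sel = two_means(candidates[g])
        groups.insert(gi, g[~sel])
        groups.append(g[sel])
    return np.array([candidates[g].mean(axis=0) for g in groups])


def arch_angles(points: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Signed angle of each point about the arch centre, in the x-y plane.

    Measured from the anterior (-y) direction, positive toward +x, so the
    quadrant-1 (patient-right) side has positive angles. Assumes the
    canonical frame (transverse x, incisors at negative y). ``center``
    defaults to the points' own x-y mean.
    """
    points = np.asarray(points, dtype=np.float64)
    c = points[:, :2].mean(axis=0) if center is None else np.asarray(center)[:2]
    rel = points[:, :2] - c
    return np.arctan2(rel[:, 0], -rel[:, 1])


@dataclass
class ArchTemplate:
    """Per-label mean landmark geometry in the canonical normalized frame.

    Computed from training-split ground truth; anchors the cluster → FDI
    assignment so a duplicated or missed tooth perturbs its neighbours
    only locally instead of rotating every label, and provides a
    population-prior position for teeth the coarse stage failed to cover.
    """

    center: np.ndarray  # (2,) x-y arch centre
    phi: np.ndarray  # (12,) canonical-order label angles about the centre
    positions: np.ndarray  # (12, 3) mean label positions

    def save(self, path) -> None:
        np.savetxt(
            path, np.concatenate([self.center, self.phi, self.positions.ravel()])
        )

    @classmethod
    def load(cls, path) -> "ArchTemplate":
        v = np.loadtxt(path)
        return cls(v[:2], v[2:14], v[14:].reshape(12, 3))


def label_angle_template(landmark_sets) -> ArchTemplate:
    """Build an :class:`ArchTemplate` from canonically-framed ground truth."""
    all_pts = np.stack([lms.points for lms in landmark_sets])  # (n, 12, 3)
    center = all_pts.reshape(-1, 3)[:, :2].mean(axis=0)
    phis = np.stack(
        [arch_angles(lms.points, center) for lms in landmark_sets]
    )
    return ArchTemplate(center, phis.mean(axis=0), all_pts.mean(axis=0))


def assign_fdi_labels(
    centroids: np.ndarray,
    cast_id: str = "",
    template: ArchTemplate | None = None,
) -> LandmarkSet:
    """Assign FDI identities to 12 centroids by angular order along the arch.

    Assumes the canonical frame (transverse x, incisors at negative y).
    Without a template, centroids are sorted by their signed angle about
    the arch centre, sweeping from the most posterior point at positive x
    to the most posterior point at negative x: 16, 15, ..., 11, 21, ..., 26.
    With an :class:`ArchTemplate` (from training ground truth), labels are
    assigned by the optimal one-to-one matching of centroid positions to
    the per-label mean positions instead, which is robust to a duplicated
    or missing tooth among the centroids.
    """
    centroids = np.asarray(centroids, dtype=np.float64)
    if centroids.shape != (12, 3):
        raise PalatemarkError("expected exactly 12 centroids")
    if template is None:
        phi = arch_angles(centroids)
        if np.min(np.abs(np.diff(np.sort(phi)))) < 1e-9:
            raise PalatemarkError("ambiguous angular ordering of centroids")
        order = np.argsort(-phi, kind="stable")
        return LandmarkSet(FDI_LABELS, centroids[order], cast_id=cast_id)
    from scipy.optimize import linear_sum_assignment

    cost = np.linalg.norm(
        centroids[:, None, :] - template.positions[None, :, :], axis=-1
    )
    rows, cols = linear_sum_assignment(cost)
    points = np.empty((12, 3))
    points[cols] = centroids[rows]
    return LandmarkSet(FDI_LABELS, points, cast_id=cast_id)
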