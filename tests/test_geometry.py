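"""Geodesics, DBSCAN, cluster resolution, and FDI label assignment."""

import numpy as np
import pytest

from palatemark.core import FDI_LABELS, PalatemarkError, PointCloud6D
from palatemark.core import DetectionFailureError
from palatemark.geometry import (
    assign_fdi_labels,
    build_knn_graph,
    dbscan_cluster,
    geodesic_ball,
    geodesic_distances,
    resolve_to_12,
    two_means,
)
from palatemark.preprocess import NormalizationTransform


def _cloud(points):
    points = np.asarray(points, dtype=float)
    normals = np.tile([0.0, 0.0, 1.0], (len(points), 1))
    return PointCloud6D(points, normals)


IDENTITY = NormalizationTransform(np.eye(3), np.zeros(3), 1.0)


class TestKnnGraph:
    def test_symmetric_connected_minimal(self):
        pts = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]
        g = build_knn_graph(_cloud(pts), k=1)
        m = g.matrix.toarray()
        np.testing.assert_allclose(m, m.T)
        assert (m.sum(axis=1) > 0).all()

    def test_weights_are_euclidean(self, rng):
        pts = rng.normal(size=(30, 3))
        g = build_knn_graph(_cloud(pts), k=4)
        m = g.matrix.tocoo()
        for i, j, w in zip(m.row, m.col, m.data):
            assert w == pytest.approx(np.linalg.norm(pts[i] - pts[j]), abs=1e-12)

    def test_matches_bruteforce_knn(self, rng):
        pts = rng.normal(size=(200, 3))
        k = 5
        g = build_knn_graph(_cloud(pts), k=k)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(200):
            for j in np.argsort(d[i])[:k]:
                expected.add((i, int(j)))
                expected.add((int(j), i))
        got = set(zip(*g.matrix.nonzero()))
        # bridging may only ever add edges; with dense Gaussian points there
        # is a single component, so the sets match exactly
        assert got == expected

    def test_disconnected_components_bridged(self):
        a = np.random.default_rng(0).normal(size=(10, 3)) * 0.1
        pts = np.vstack([a, a + [100, 0, 0], a + [0, 200, 0]])
        g = build_knn_graph(_cloud(pts), k=2)
        from scipy.sparse.csgraph import connected_components

        n_comp, _ = connected_components(g.matrix, directed=False)
        assert n_comp == 1


class TestGeodesics:
    def test_chain_distances(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        g = build_knn_graph(_cloud(pts), k=1)
        np.testing.assert_allclose(geodesic_distances(g, 0), np.arange(6.0))

    def test_geodesic_at_least_euclidean(self, rng):
        for _ in range(5):
            pts = rng.normal(size=(60, 3))
            g = build_knn_graph(_cloud(pts), k=4)
            d = geodesic_distances(g, 0)
            euclid = np.linalg.norm(pts - pts[0], axis=1)
            assert (d >= euclid - 1e-9).all()

    def test_matches_bellman_ford_oracle(self, rng):
        """Dijkstra geodesics equal an explicit edge-relaxation oracle."""
        pts = rng.normal(size=(100, 3))
        g = build_knn_graph(_cloud(pts), k=4)
        got = geodesic_distances(g, 3)
        coo = g.matrix.tocoo()
        edges = list(zip(coo.row, coo.col, coo.data))
        dist = np.full(100, np.inf)
        dist[3] = 0.0
        for _ in range(99):  # Bellman-Ford: V-1 relaxation sweeps
            changed = False
            for i, j, w in edges:
                if dist[i] + w < dist[j]:
                    dist[j] = dist[i] + w
                    changed = True
            if not changed:
                break
        np.testing.assert_allclose(got, dist, atol=1e-12)

    def test_triangle_inequality(self, rng):
        pts = rng.normal(size=(40, 3))
        g = build_knn_graph(_cloud(pts), k=4)
        da = geodesic_distances(g, 0)
        db = geodesic_distances(g, 1)
        assert (da <= da[1] + db + 1e-9).all()


class TestGeodesicBall:
    def test_chain_ball_hand_countable(self):
        """1 mm spaced chain, centre at the end, 2.5 mm radius -> 3 points."""
        pts = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        g = build_knn_graph(_cloud(pts), k=1)
        patch = geodesic_ball(_cloud(pts), g, [0, 0, 0], 2.5, IDENTITY)
        assert sorted(patch.indices) == [0, 1, 2]

    def test_c_shape_excludes_far_tip(self):
        """Tips 3 mm apart straight-line but ~20 mm along the curve: a 6 mm
        geodesic ball at one tip excludes the other (a Euclidean ball would
        include it)."""
        t = np.linspace(0, 2 * np.pi * 0.93, 60)
        r = 20.0 / (2 * np.pi * 0.93)  # arc length 20 mm
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros_like(t)])
        tip_gap = np.linalg.norm(pts[0] - pts[-1])
        assert tip_gap < 3.5
        g = build_knn_graph(_cloud(pts), k=2)
        patch = geodesic_ball(_cloud(pts), g, pts[0], 6.0, IDENTITY)
        assert 0 in patch.indices
        assert len(pts) - 1 not in patch.indices
        # verify against the explicit distance array
        d = geodesic_distances(g, 0)
        np.testing.assert_array_equal(np.sort(patch.indices), np.flatnonzero(d <= 6.0))

    def test_radius_monotonicity(self, prepared_small):
        cloud, tf = prepared_small[0], prepared_small[1]
        g = build_knn_graph(cloud, k=8)
        center = cloud.positions[100]
        small = set(geodesic_ball(cloud, g, center, 3.0, tf).indices)
        large = set(geodesic_ball(cloud, g, center, 6.0, tf).indices)
        assert small <= large

    def test_radius_converted_from_mm(self, prepared_small):
        cloud, tf = prepared_small[0], prepared_small[1]
        g = build_knn_graph(cloud, k=8)
        patch = geodesic_ball(cloud, g, cloud.positions[0], 6.0, tf)
        d = geodesic_distances(g, int(patch.indices[0]))
        # all members within the normalized-unit radius
        assert (d[patch.indices] <= 6.0 * tf.scale * 1.0001).all()


def _bruteforce_dbscan(points, eps, min_samples):
    """Literal density-reachability expansion, index-ordered seeds."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    neigh = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(neigh[i]) >= min_samples for i in range(n)])
    labels = np.full(n, -2)
    cid = 0
    for i in range(n):
        if labels[i] != -2 or not core[i]:
            continue
        labels[i] = cid
        frontier = [i]
        while frontier:
            j = frontier.pop(0)
            for q in neigh[j]:
                if labels[q] == -2:
                    labels[q] = cid
                    if core[q]:
                        frontier.append(q)
        cid += 1
    labels[labels == -2] = -1
    return labels


class TestDBSCAN:
    def test_two_blobs(self, rng):
        pts = np.vstack(
            [rng.normal(size=(10, 3)) * 0.3, rng.normal(size=(10, 3)) * 0.3 + 100]
        )
        out = dbscan_cluster(pts, eps=2.0, min_samples=3)
        assert out.n_clusters == 2
        assert (out.labels >= 0).all()
        for c in range(2):
            np.testing.assert_allclose(
                out.centroids[c], pts[out.labels == c].mean(axis=0)
            )

    def test_isolated_point_is_noise(self):
        pts = np.array([[0, 0, 0], [100.0, 0, 0], [100.1, 0, 0], [100.2, 0, 0]])
        out = dbscan_cluster(pts, eps=1.0, min_samples=2)
        assert out.labels[0] == -1

    def test_matches_bruteforce_partition(self, rng):
        """Same set partition (and noise set) as literal density reachability."""
        for _ in range(5):
            centers = rng.uniform(-10, 10, (5, 3))
            pts = np.vstack([c + rng.normal(size=(10, 3)) * 0.4 for c in centers])
            got = dbscan_cluster(pts, eps=1.5, min_samples=4).labels
            want = _bruteforce_dbscan(pts, 1.5, 4)
            assert set(map(frozenset, _partition(got))) == set(
                map(frozenset, _partition(want))
            )
            np.testing.assert_array_equal(got == -1, want == -1)

    def test_permutation_stable_partition(self, rng):
        pts = np.vstack([rng.normal(size=(12, 3)) * 0.3 + c
                         for c in ([0, 0, 0], [5, 0, 0], [0, 5, 0])])
        base = dbscan_cluster(pts, 1.0, 3).labels
        perm = rng.permutation(len(pts))
        permuted = dbscan_cluster(pts[perm], 1.0, 3).labels
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        assert set(map(frozenset, _partition(base))) == set(
            map(frozenset, _partition(permuted[inv]))
        )


def _partition(labels):
    return [np.flatnonzero(labels == c) for c in np.unique(labels) if c >= 0]


class TestResolveTo12:
    def _cands(self, rng, centers, per=21):
        return np.vstack([c + rng.normal(size=(per, 3)) * 0.1 for c in centers])

    def test_twelve_tight_clusters_passthrough(self, rng):
        centers = rng.uniform(-50, 50, (12, 3))
        cands = self._cands(rng, centers)
        lab = dbscan_cluster(cands, eps=1.0, min_samples=4)
        assert lab.n_clusters == 12
        out = resolve_to_12(lab, cands)
        for c in range(12):
            np.testing.assert_allclose(
                out[c], cands[lab.labels == c].mean(axis=0), atol=1e-9
            )

    def test_merged_pair_split_by_two_means(self, rng):
        """11 DBSCAN clusters (two true groups merged) still yield 12 outputs."""
        centers = np.array([[i * 10.0, 0, 0] for i in range(11)] + [[0, 0.8, 0]])
        cands = self._cands(rng, centers, per=10)
        lab = dbscan_cluster(cands, eps=1.5, min_samples=4)
        assert lab.n_clusters == 11
        out = resolve_to_12(lab, cands)
        assert out.shape == (12, 3)
        # the split equals a direct 2-means on the merged group
        merged = cands[np.isin(np.arange(len(cands)), np.flatnonzero(lab.labels == 0))]
        sel = two_means(merged)
        expected = {tuple(np.round(merged[sel].mean(0), 6)),
                    tuple(np.round(merged[~sel].mean(0), 6))}
        got = {tuple(np.round(c, 6)) for c in out}
        assert expected <= got

    def test_more_than_twelve_keeps_largest(self, rng):
        centers = rng.uniform(-80, 80, (14, 3))
        sizes = [21] * 12 + [3, 3]
        cands = np.vstack(
            [c + rng.normal(size=(s, 3)) * 0.1 for c, s in zip(centers, sizes)]
        )
        lab = dbscan_cluster(cands, eps=1.0, min_samples=3)
        assert lab.n_clusters == 14
        out = resolve_to_12(lab, cands)
        d = np.linalg.norm(out[:, None] - centers[None, :12], axis=-1)
        assert (d.min(axis=1) < 0.5).all()

    def test_noise_recruited_when_clusters_too_small(self, rng):
        """If clustered points are too few for 12 groups, noise points are
        recruited by nearest centroid before splitting."""
        # one dense blob of 8 + 20 isolated noise points
        cands = np.vstack(
            [rng.normal(size=(8, 3)) * 0.1,
             rng.uniform(-100, 100, (20, 3))]
        )
        lab = dbscan_cluster(cands, eps=1.0, min_samples=4)
        assert lab.n_clusters == 1
        assert (lab.labels == -1).sum() == 20
        out = resolve_to_12(lab, cands)
        assert out.shape == (12, 3)

    def test_too_few_candidates_raises(self):
        lab = dbscan_cluster(np.zeros((5, 3)), 1.0, 1)
        with pytest.raises(DetectionFailureError) as e:
            resolve_to_12(lab, np.zeros((5, 3)))
        assert e.value.achieved == 5

    def test_centroids_inside_hull_of_members(self, rng):
        centers = rng.uniform(-50, 50, (12, 3))
        cands = self._cands(rng, centers)
        out = resolve_to_12(dbscan_cluster(cands, 1.0, 4), cands)
        lo, hi = cands.min(axis=0), cands.max(axis=0)
        assert ((out >= lo - 1e-9) & (out <= hi + 1e-9)).all()


class TestAssignLabels:
    def test_recovers_generator_identities(self):
        """Angular ordering matches ground-truth identities on 20 casts."""
        from palatemark.mesh_io import mesh_to_pointcloud
        from palatemark.preprocess import preprocess_cloud
        from palatemark.synthetic import CastShapeParams, generate_dataset

        for i, (mesh, lms) in enumerate(
            generate_dataset(20, CastShapeParams(target_vertices=2000), seed=42)
        ):
            cloud = mesh_to_pointcloud(mesh)
            _, tf, lms_norm = preprocess_cloud(cloud, 512, lms)
            shuffled = np.random.default_rng(i).permutation(12)
            out = assign_fdi_labels(lms_norm.points[shuffled])
            np.testing.assert_allclose(out.points, lms_norm.points, atol=1e-12)

    def test_mirror_swaps_quadrants(self, prepared_small):
        lms_norm = prepared_small[2]
        base = assign_fdi_labels(lms_norm.points)
        mirrored = assign_fdi_labels(lms_norm.points * [-1, 1, 1])
        for label in FDI_LABELS:
            partner = ("2" if label[0] == "1" else "1") + label[1]
            np.testing.assert_allclose(
                mirrored.point(partner), base.point(label) * [-1, 1, 1]
            )

    def test_wrong_count_rejected(self):
        with pytest.raises(PalatemarkError):
            assign_fdi_labels(np.zeros((11, 3)))

    def test_template_matching_localizes_damage(self, prepared_small, rng):
        """With an angular template, a duplicated+missing tooth perturbs
        only the affected labels; rank-order assignment would rotate all
        labels between the duplicate and the gap."""
        from palatemark.geometry import label_angle_template

        lms_norm = prepared_small[2]
        template = label_angle_template([lms_norm])
        # corrupt: two centroids at tooth 14, none at tooth 26
        pts = lms_norm.points.copy()
        i14, i26 = FDI_LABELS.index("14"), FDI_LABELS.index("26")
        pts[i26] = pts[i14] + rng.normal(0, 1e-3, 3)

        def n_wrong(assigned):
            return sum(
                np.linalg.norm(assigned.point(l) - lms_norm.point(l)) > 1e-2
                for l in FDI_LABELS
            )

        with_template = n_wrong(assign_fdi_labels(pts, template=template))
        rank_only = n_wrong(assign_fdi_labels(pts))
        # template matching keeps the damage local; rank ordering rotates
        # every label between the duplicate and the gap
        assert with_template <= 3
        assert rank_only >= 8
        assert with_template < rank_only

    def test_template_agrees_with_rank_order_on_clean_input(self, prepared_small):
        from palatemark.geometry import label_angle_template

        lms_norm = prepared_small[2]
        template = label_angle_template([lms_norm])
        shuffled = np.random.default_rng(5).permutation(12)
        a = assign_fdi_labels(lms_norm.points[shuffled])
        b = assign_fdi_labels(lms_norm.points[shuffled], template=template)
        np.testing.assert_allclose(a.points, b.points)
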