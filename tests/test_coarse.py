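"""Coarse stage: targets, candidate generation, and the composite losses."""

import numpy as np
import pytest

from palatemark.coarse import (
    CoarseNet,
    CoarseNetConfig,
    CoarseOutput,
    chamfer_loss,
    coarse_forward,
    coarse_targets,
    coarse_total_loss,
    distance_loss,
    make_candidates,
    separation_loss,
)
from palatemark.core import FDI_LABELS, FrameError, LandmarkSet, PointCloud6D

TINY = CoarseNetConfig(
    sa_npoints=(16, 8, 4),
    sa_nsample=(8, 8, 8),
    mlp_widths=((8, 16), (16, 32), (32, 64)),
    fp_widths=((32,), (32,), (16, 16)),
    head_width=16,
    n_candidates=16,
)


def _toy_cloud(rng, n=64):
    pos = rng.uniform(-1, 1, (n, 3))
    nrm = rng.normal(size=(n, 3))
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return PointCloud6D(pos, nrm, frame="normalized")


def _toy_landmarks(rng):
    return LandmarkSet(FDI_LABELS, rng.uniform(-1, 1, (12, 3)))


class TestTargets:
    def test_point_on_landmark_has_zero_target(self, rng):
        lms = _toy_landmarks(rng)
        pos = np.vstack([lms.points[5], rng.uniform(-1, 1, (9, 3))])
        nrm = np.tile([0.0, 0.0, 1.0], (10, 1))
        cloud = PointCloud6D(pos, nrm, frame="normalized")
        td, toff = coarse_targets(cloud, lms)
        assert td[0] == 0.0
        np.testing.assert_array_equal(toff[0], 0.0)

    def test_offset_lands_on_a_landmark(self, rng):
        cloud = _toy_cloud(rng, 200)
        lms = _toy_landmarks(rng)
        td, toff = coarse_targets(cloud, lms)
        landed = cloud.positions + toff
        d = np.linalg.norm(landed[:, None] - lms.points[None], axis=-1)
        assert d.min(axis=1).max() < 1e-12

    def test_matches_bruteforce_12way_scan(self, rng):
        cloud = _toy_cloud(rng, 1000)
        lms = _toy_landmarks(rng)
        td, toff = coarse_targets(cloud, lms)
        for i in range(0, 1000, 37):
            ds = [np.linalg.norm(lms.points[j] - cloud.positions[i]) for j in range(12)]
            j = int(np.argmin(ds))
            assert td[i] == pytest.approx(ds[j], abs=1e-12)
            np.testing.assert_allclose(
                toff[i], lms.points[j] - cloud.positions[i], atol=1e-12
            )

    def test_frame_mismatch_rejected(self, rng):
        pos = rng.uniform(-1, 1, (10, 3))
        nrm = np.tile([0.0, 0.0, 1.0], (10, 1))
        cloud = PointCloud6D(pos, nrm, frame="cast_mm")
        with pytest.raises(FrameError):
            coarse_targets(cloud, _toy_landmarks(rng))


class TestForward:
    def test_output_shapes_and_finiteness(self, rng):
        cloud = _toy_cloud(rng)
        net = CoarseNet(TINY, seed=0)
        out = coarse_forward(cloud, net)
        assert out.pred_distance.shape == (64,)
        assert out.pred_offset.shape == (64, 3)
        assert np.isfinite(out.pred_distance).all()
        assert (out.pred_distance >= 0).all()
        assert np.isfinite(out.pred_offset).all()

    def test_deterministic_for_fixed_weights(self, rng):
        cloud = _toy_cloud(rng)
        net = CoarseNet(TINY, seed=0)
        o1 = coarse_forward(cloud, net)
        o2 = coarse_forward(cloud, net)
        np.testing.assert_array_equal(o1.pred_distance, o2.pred_distance)
        np.testing.assert_array_equal(o1.pred_offset, o2.pred_offset)

    def test_permutation_equivariance_with_shared_structure(self, rng):
        """Permuting input points permutes outputs when the grouping
        structure is held fixed (indices remapped through the permutation)."""
        cloud = _toy_cloud(rng)
        net = CoarseNet(TINY, seed=0)
        struct = net.structure(cloud)
        base = coarse_forward(cloud, net, struct)
        perm = rng.permutation(64)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(64)
        permuted = PointCloud6D(
            cloud.positions[perm], cloud.normals[perm], cloud.frame
        )
        # remap the structure's level-0 references through the permutation
        import copy

        ps = copy.deepcopy(struct)
        ps.sa[0].group_idx = inv[struct.sa[0].group_idx]
        ps.sa[0].center_idx = inv[struct.sa[0].center_idx]
        ps.fp[-1].idx = struct.fp[-1].idx[perm]
        ps.fp[-1].w = struct.fp[-1].w[perm]
        out = coarse_forward(permuted, net, ps)
        np.testing.assert_allclose(out.pred_distance, base.pred_distance[perm], atol=1e-5)
        np.testing.assert_allclose(out.pred_offset, base.pred_offset[perm], atol=1e-5)


class TestCandidates:
    def test_zero_offsets_select_input_points(self, rng):
        cloud = _toy_cloud(rng)
        out = CoarseOutput(rng.uniform(0, 1, 64), np.zeros((64, 3)))
        cand = make_candidates(cloud, out, 16)
        pos_set = {tuple(p) for p in cloud.positions}
        assert all(tuple(c) in pos_set for c in cand)

    def test_oracle_predictions_give_zero_chamfer(self, rng):
        cloud = _toy_cloud(rng, 200)
        lms = _toy_landmarks(rng)
        td, toff = coarse_targets(cloud, lms)
        cand = make_candidates(cloud, CoarseOutput(td, toff), 64)
        assert chamfer_loss(cand, lms.points) == pytest.approx(0.0, abs=1e-20)

    def test_candidate_count_fixed(self, rng):
        cloud = _toy_cloud(rng, 300)
        out = CoarseOutput(rng.uniform(0, 1, 300), rng.normal(size=(300, 3)))
        assert make_candidates(cloud, out, 256).shape == (256, 3)


class TestLosses:
    def test_distance_loss_perfect_and_constant(self, rng):
        x = rng.uniform(0, 1, 50)
        assert distance_loss(x, x) == 0.0
        e = 0.3  # below delta: quadratic branch e^2/2
        assert distance_loss(x + e, x) == pytest.approx(e**2 / 2)

    def test_distance_loss_matches_elementwise_oracle(self, rng):
        pred = rng.normal(size=200) * 2
        true = rng.normal(size=200) * 2
        acc = 0.0
        for p, t in zip(pred, true):
            r = abs(p - t)
            acc += 0.5 * r**2 if r <= 1.0 else (r - 0.5)
        assert distance_loss(pred, true) == pytest.approx(acc / 200, abs=1e-12)

    def test_chamfer_1d_toy(self):
        """Candidates {0}, landmarks {1, 3}: 1 + (1 + 9)/2 = 6."""
        c = np.array([[0.0, 0, 0]])
        l = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        assert chamfer_loss(c, l) == pytest.approx(6.0)

    def test_chamfer_matches_double_loop(self, rng):
        c = rng.normal(size=(20, 3))
        l = rng.normal(size=(7, 3))
        t1 = np.mean([min(np.sum((ci - lj) ** 2) for lj in l) for ci in c])
        t2 = np.mean([min(np.sum((ci - lj) ** 2) for ci in c) for lj in l])
        assert chamfer_loss(c, l) == pytest.approx(t1 + t2, abs=1e-12)

    def test_separation_zero_when_spread(self, rng):
        c = np.arange(30).reshape(10, 3) * 10.0
        assert separation_loss(c, margin=0.05) == 0.0

    def test_separation_single_coincident_pair(self):
        c = np.array([[0.0, 0, 0], [0.0, 0, 0], [10, 0, 0], [20, 0, 0]])
        m = 0.5
        n_pairs = 4 * 3 / 2
        assert separation_loss(c, margin=m) == pytest.approx(m**2 / n_pairs)

    def test_separation_matches_pairwise_loop(self, rng):
        c = rng.normal(size=(15, 3)) * 0.05
        m = 0.08
        acc = 0.0
        pairs = 0
        for i in range(15):
            for j in range(i + 1, 15):
                pairs += 1
                d = np.linalg.norm(c[i] - c[j])
                acc += max(0.0, m - d) ** 2
        assert separation_loss(c, m) == pytest.approx(acc / pairs, abs=1e-12)

    def test_total_loss_zero_and_linearity(self, rng):
        lms = _toy_landmarks(rng)
        # cloud contains every landmark, so oracle candidates cover them all
        pos = np.vstack([lms.points, rng.uniform(-1, 1, (88, 3))])
        nrm = np.tile([0.0, 0.0, 1.0], (100, 1))
        cloud = PointCloud6D(pos, nrm, frame="normalized")
        td, toff = coarse_targets(cloud, lms)
        out = CoarseOutput(td, toff)
        cand = make_candidates(cloud, out, 32)
        total, parts = coarse_total_loss(out, (td, toff), cand, lms)
        assert parts["distance"] == 0.0 and parts["offset"] == 0.0
        assert parts["chamfer"] == pytest.approx(0.0, abs=1e-20)
        # doubling a component weight doubles its contribution
        t1, p1 = coarse_total_loss(out, (td, toff), cand, lms, weights=(1, 1, 0.1))
        t2, _ = coarse_total_loss(out, (td, toff), cand, lms, weights=(1, 1, 0.2))
        assert t2 - t1 == pytest.approx(0.1 * p1["separation"], abs=1e-15)

    def test_oracle_loss_reduces_to_coincidence_separation(self, prepared_small):
        """With oracle predictions on a synthetic cast the distance, offset
        and chamfer terms vanish exactly; only the separation hinge stays
        active, because several oracle candidates coincide on the *same*
        landmark (the landmarks themselves are farther apart than the
        margin). Its value equals a closed-form count of coincident pairs."""
        cloud, _, lms_norm, _ = prepared_small
        td, toff = coarse_targets(cloud, lms_norm)
        out = CoarseOutput(td, toff)
        n = 64
        cand = make_candidates(cloud, out, n)
        total, parts = coarse_total_loss(out, (td, toff), cand, lms_norm)
        assert parts["distance"] == 0.0 and parts["offset"] == 0.0
        assert parts["chamfer"] == pytest.approx(0.0, abs=1e-20)
        owner = np.linalg.norm(
            cand[:, None] - lms_norm.points[None], axis=-1
        ).argmin(axis=1)
        margin = 0.05
        pairs = sum(k * (k - 1) / 2 for k in np.bincount(owner, minlength=12))
        expected = margin**2 * pairs / (n * (n - 1) / 2)
        assert parts["separation"] == pytest.approx(expected, rel=1e-9)
        assert total == pytest.approx(0.1 * expected, rel=1e-9)
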