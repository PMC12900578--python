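"""Dataset splitting, the two training loops, and the end-to-end predictor.

Both stages train with Adam: the coarse stage for 50 epochs at learning
rate 0.001, the refinement stage for 50 epochs at 0.002 with global
gradient-norm clipping at 0.5. The best-validation-loss checkpoint is
retained. Refinement patches are centred on ground-truth landmarks by
default during training (oracle-patch mode) and on coarse cluster
centroids at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .coarse import (
    CoarseNet,
    coarse_forward,
    coarse_targets,
    coarse_training_loss,
    make_candidates,
)
from .config import PipelineConfig, TrainingConfig
from .core import (
    DentalCastMesh,
    DetectionFailureError,
    LandmarkSet,
    PalatemarkError,
    PointCloud6D,
    TrainingError,
)
from .geometry import (
    NeighborGraph,
    assign_fdi_labels,
    build_knn_graph,
    dbscan_cluster,
    geodesic_ball,
    resolve_to_12,
)
from .mesh_io import mesh_to_pointcloud
from .preprocess import NormalizationTransform, preprocess_cloud
from .refine import (
    RefineNet,
    extract_landmark,
    heatmap_target,
    refine_forward,
    standardize_patch,
)

__all__ = [
    "PreparedCast",
    "prepare_cast",
    "split_dataset",
    "train_coarse",
    "train_refine",
    "predict",
    "predict_prepared",
]


@dataclass
class PreparedCast:
    """A preprocessed cast: normalized cloud, transform, targets, caches."""

    cloud: PointCloud6D
    transform: NormalizationTransform
    landmarks_norm: LandmarkSet | None
    landmarks_mm: LandmarkSet | None
    cast_id: str
    coarse_structure: object = None
    graph: NeighborGraph | None = None

    def get_structure(self, net: CoarseNet):
        if self.coarse_structure is None:
            self.coarse_structure = net.structure(self.cloud)
        return self.coarse_structure

    def get_graph(self, k: int) -> NeighborGraph:
        if self.graph is None:
            self.graph = build_knn_graph(self.cloud, k)
        return self.graph


def prepare_cast(
    mesh: DentalCastMesh,
    landmarks: LandmarkSet | None,
    n_points: int,
) -> PreparedCast:
    """Mesh -> oriented, normalized, farthest-point-sampled cloud."""
    cloud = mesh_to_pointcloud(mesh)
    sampled, tf, lms_norm = preprocess_cloud(cloud, n_points, landmarks)
    return PreparedCast(sampled, tf, lms_norm, landmarks, mesh.cast_id)


def split_dataset(casts: list, fractions, seed: int = 0):
    """Seeded shuffle then contiguous split by rounded fractions.

    Rounding rule: train and validation sizes are floored, the remainder
    goes to test. Splits are disjoint and exhaustive; the same seed always
    yields the same split.
    """
    if not casts:
        raise PalatemarkError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise PalatemarkError("fractions must be non-negative and sum to 1")
    n = len(casts)
    order = np.random.default_rng(np.random.PCG64(seed)).permutation(n)
    n_train = int(np.floor(fractions[0] * n + 1e-9))
    n_val = int(np.floor(fractions[1] * n + 1e-9))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise PalatemarkError(
            f"split {n_train}/{n_val}/{n_test} has an empty partition at n={n}"
        )
    train = [casts[i] for i in order[:n_train]]
    val = [casts[i] for i in order[n_train : n_train + n_val]]
    test = [casts[i] for i in order[n_train + n_val :]]
    return train, val, test


# ---------------------------------------------------------------------------
# coarse training
# ---------------------------------------------------------------------------


def train_coarse(
    train: list[PreparedCast],
    val: list[PreparedCast],
    config: TrainingConfig,
    net_config,
) -> tuple[CoarseNet, list[dict]]:
    """Minimize the composite coarse loss; keep the best-validation weights."""
    net = CoarseNet(net_config, seed=config.seed)
    params = net.params
    opt = _nn.Adam(params, lr=config.coarse_lr)
    rng = np.random.default_rng(np.random.PCG64((config.seed * 7919 + 1) % 2**31))
    targets = {id(c): coarse_targets(c.cloud, c.landmarks_norm) for c in train + val}
    history: list[dict] = []
    best = (np.inf, _nn.get_state(params))

    def cast_loss_t(cast: PreparedCast):
        dist, off, _ = net.forward_t(cast.cloud, cast.get_structure(net))
        return coarse_training_loss(
            dist, off, cast.cloud, targets[id(cast)],
            cast.landmarks_norm, net_config,
        )

    for epoch in range(config.coarse_epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for s in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[s : s + config.batch_size]]
            opt.zero_grad()
            losses = [cast_loss_t(c) for c in batch]
            total = losses[0]
            for l in losses[1:]:
                total = _nn.add(total, l)
            total = _nn.scale(total, 1.0 / len(losses))
            if not np.isfinite(total.item()):
                raise TrainingError("coarse loss diverged", epoch=epoch)
            total.backward()
            opt.step()
            epoch_losses.append(total.item())
        val_loss = float(np.mean([cast_loss_t(c).item() for c in val])) if val else np.nan
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if val and val_loss < best[0]:
            best = (val_loss, _nn.get_state(params))
    if val and config.coarse_epochs > 0:
        _nn.set_state(params, best[1])
    return net, history


# ---------------------------------------------------------------------------
# refinement training
# ---------------------------------------------------------------------------


def _build_training_patches(
    cast: PreparedCast,
    refine_net: RefineNet,
    pipeline: PipelineConfig,
    coarse_net: CoarseNet | None,
    center_rng: np.random.Generator | None = None,
):
    """Standardized patches + heatmap targets + structures for one cast.

    Oracle-patch mode centres the 12 patches on the true landmarks, with
    seeded random offsets (``oracle_center_jitter_mm``) so the scorer sees
    the landmark away from the patch centre, as it will at inference;
    otherwise centres come from the coarse stage's resolved centroids.
    Patches whose true landmark cannot be supervised are skipped.
    """
    graph = cast.get_graph(pipeline.preprocess.knn_k)
    if pipeline.training.oracle_patches or coarse_net is None:
        centers = cast.landmarks_norm.points
        jitter = pipeline.training.oracle_center_jitter_mm
        if center_rng is not None and jitter > 0:
            direction = center_rng.normal(size=(12, 3))
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            radius = jitter * center_rng.uniform(0, 1, (12, 1)) ** (1 / 3)
            centers = centers + direction * radius * cast.transform.scale
    else:
        out = coarse_forward(cast.cloud, coarse_net, cast.get_structure(coarse_net))
        cand = make_candidates(cast.cloud, out, pipeline.coarse.n_candidates)
        labeling = dbscan_cluster(
            cand,
            pipeline.cluster.eps_mm * cast.transform.scale,
            pipeline.cluster.min_samples,
        )
        centers = assign_fdi_labels(resolve_to_12(labeling, cand)).points
    patches, tgts, structs, skipped = [], [], [], 0
    from .core import SupervisionGapError

    for j in range(12):
        patch = geodesic_ball(
            cast.cloud, graph, centers[j],
            pipeline.cluster.ball_radius_mm, cast.transform,
        )
        std = standardize_patch(patch, refine_net.config)
        try:
            t = heatmap_target(
                std,
                cast.landmarks_norm.points[j],
                refine_net.config.heatmap_sigma,
                cast.transform,
            )
        except SupervisionGapError:
            skipped += 1
            continue
        patches.append(std)
        tgts.append(t.probs)
        structs.append(refine_net.structure(std))
    return patches, tgts, structs, skipped


def train_refine(
    train: list[PreparedCast],
    val: list[PreparedCast],
    config: TrainingConfig,
    refine_config,
    pipeline: PipelineConfig | None = None,
    coarse_net: CoarseNet | None = None,
) -> tuple[RefineNet, list[dict]]:
    """Train the patch scorer with gradient clipping at 0.5 global norm."""
    pipeline = pipeline or PipelineConfig()
    net = RefineNet(refine_config, seed=config.seed + 1)
    params = net.params
    opt = _nn.Adam(params, lr=config.refine_lr)
    rng = np.random.default_rng(np.random.PCG64((config.seed * 104729 + 2) % 2**31))

    prepared = {}
    n_skipped = 0
    patch_rng = np.random.default_rng(np.random.PCG64((config.seed * 613 + 5) % 2**31))
    for c in train:
        patches, tgts, structs, skipped = _build_training_patches(
            c, net, pipeline, coarse_net, center_rng=patch_rng
        )
        n_skipped += skipped
        if patches:
            prepared[id(c)] = (patches, np.array(tgts), structs)
    for c in val:
        patches, tgts, structs, skipped = _build_training_patches(
            c, net, pipeline, coarse_net, center_rng=patch_rng
        )
        n_skipped += skipped
        if patches:
            prepared[id(c)] = (patches, np.array(tgts), structs)
    train = [c for c in train if id(c) in prepared]
    val = [c for c in val if id(c) in prepared]
    if not train:
        raise TrainingError("no trainable patches (all supervision gaps)")

    dtype = net.config.np_dtype

    def batch_loss_t(casts):
        patches, tgts, structs = [], [], []
        for c in casts:
            p, t, s = prepared[id(c)]
            patches += p
            tgts.append(t)
            structs += s
        target = np.concatenate(tgts).astype(dtype)
        logits, _ = net.logits_t(patches, structs)
        logp = _nn.log_softmax(logits, axis=1)
        return _nn.scale(_nn.nll(logp, target), 1.0 / len(patches))

    history: list[dict] = []
    best = (np.inf, _nn.get_state(params))
    for epoch in range(config.refine_epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for s in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[s : s + config.batch_size]]
            opt.zero_grad()
            loss = batch_loss_t(batch)
            if not np.isfinite(loss.item()):
                raise TrainingError("refine loss diverged", epoch=epoch)
            loss.backward()
            opt.clip_global_norm(config.grad_clip_norm)
            opt.step()
            epoch_losses.append(loss.item())
        val_loss = (
            float(np.mean([batch_loss_t([c]).item() for c in val])) if val else np.nan
        )
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "skipped_patches": n_skipped,
            }
        )
        if val and val_loss < best[0]:
            best = (val_loss, _nn.get_state(params))
    if val and config.refine_epochs > 0:
        _nn.set_state(params, best[1])
    return net, history


# ---------------------------------------------------------------------------
# end-to-end prediction
# ---------------------------------------------------------------------------


def predict_prepared(
    cast: PreparedCast,
    coarse_net: CoarseNet,
    refine_net: RefineNet,
    pipeline: PipelineConfig,
    label_template: np.ndarray | None = None,
) -> tuple[LandmarkSet, LandmarkSet]:
    """Two-stage prediction on a preprocessed cast.

    Returns ``(refined, coarse_only)`` — both 12 FDI-labeled points in
    cast-frame millimetres; ``coarse_only`` is the resolved cluster
    centroids before refinement, useful for ablation.
    """
    out = coarse_forward(cast.cloud, coarse_net, cast.get_structure(coarse_net))
    cand = make_candidates(cast.cloud, out, pipeline.coarse.n_candidates)
    labeling = dbscan_cluster(
        cand,
        pipeline.cluster.eps_mm * cast.transform.scale,
        pipeline.cluster.min_samples,
    )
    try:
        centroids = resolve_to_12(labeling, cand)
    except DetectionFailureError as exc:
        raise DetectionFailureError(
            f"cast {cast.cast_id}: {exc}", achieved=exc.achieved
        ) from exc
    coarse_lms_norm = assign_fdi_labels(centroids, cast.cast_id, label_template)
    centers = coarse_lms_norm.points.copy()
    if label_template is not None:
        # teeth the coarse stage missed: search around the population prior
        far = (
            np.linalg.norm(centers - label_template.positions, axis=1)
            > pipeline.cluster.template_fallback_mm * cast.transform.scale
        )
        centers[far] = label_template.positions[far]
    graph = cast.get_graph(pipeline.preprocess.knn_k)
    final = np.empty((12, 3))
    for j in range(12):
        patch = geodesic_ball(
            cast.cloud, graph, centers[j],
            pipeline.cluster.ball_radius_mm, cast.transform,
        )
        std = standardize_patch(patch, refine_net.config)
        prob = refine_forward(std, refine_net)
        final[j] = extract_landmark(std, prob, cast.transform)
    refined = LandmarkSet(coarse_lms_norm.labels, final, cast.cast_id)
    coarse_only = cast.transform.invert_landmarks(coarse_lms_norm)
    return refined, coarse_only


def predict(
    mesh: DentalCastMesh,
    coarse_net: CoarseNet,
    refine_net: RefineNet,
    pipeline: PipelineConfig,
) -> LandmarkSet:
    """Full chain: mesh -> cloud -> normalize -> coarse -> cluster -> refine.

    Deterministic given the weights: sampling starts and tie-breaks are
    all fixed, and no randomness is used at inference.
    """
    cast = prepare_cast(mesh, None, pipeline.preprocess.n_points)
    refined, _ = predict_prepared(cast, coarse_net, refine_net, pipeline)  # rank-order labels
    return refined
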