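"""Coarse landmark-proposal stage.

A hierarchical point-cloud encoder (three set-abstraction levels with
increasing query radii 0.025, 0.1, 0.2 in normalized units) extracts
multiscale features from the [N x 6] cloud, feature propagation brings
them back to full resolution, and two parallel per-point heads predict
(a) the distance from each point to its nearest landmark and (b) the
directional offset that carries the point onto that landmark. The points
with the smallest predicted distances, displaced by their predicted
offsets, form the candidate set (256 at full scale).

Training is driven by a composite loss: Huber distance supervision (with
the offset residual folded in), a symmetric squared chamfer loss between
candidates and true landmarks, and a hinge separation loss that penalizes
candidate collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .core import ConfigError, FrameError, LandmarkSet, PointCloud6D
from ._nn import Tensor

__all__ = [
    "CoarseNetConfig",
    "CoarseNet",
    "CoarseOutput",
    "coarse_forward",
    "coarse_targets",
    "make_candidates",
    "distance_loss",
    "chamfer_loss",
    "separation_loss",
    "coarse_total_loss",
    "coarse_training_loss",
]


@dataclass(frozen=True)
class CoarseNetConfig:
    sa_radii: tuple = (0.025, 0.1, 0.2)  # normalized units
    sa_npoints: tuple = (4096, 1024, 256)
    sa_nsample: tuple = (32, 32, 32)
    mlp_widths: tuple = ((64, 64, 128), (128, 128, 256), (256, 256, 512))
    fp_widths: tuple = ((256, 256), (256, 128), (128, 128, 128))
    head_width: int = 256
    n_candidates: int = 256
    in_channels: int = 6
    separation_margin: float = 0.05  # normalized units
    loss_weights: tuple = (1.0, 1.0, 0.1)  # distance, chamfer, separation
    offset_weight: float = 1.0
    #: Gaussian focus (normalized units) concentrating offset supervision on
    #: points near a landmark — exactly the points eligible as candidates;
    #: far-field offsets otherwise dominate the Huber term. None = uniform.
    offset_focus_sigma: float | None = None
    #: Concatenate a global max-pooled descriptor of the coarsest level to
    #: the per-point trunk before the heads; the arch layout is strongly
    #: stereotyped, so global context anchors the distance/offset fields.
    global_context: bool = False
    huber_delta: float = 1.0
    dtype: str = "float32"

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.sa_radii, self.sa_radii[1:])):
            raise ConfigError("sa_radii must be strictly increasing")
        if not all(a > b for a, b in zip(self.sa_npoints, self.sa_npoints[1:])):
            raise ConfigError("sa_npoints must be strictly decreasing")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class CoarseOutput:
    """Per-point predictions in normalized units."""

    pred_distance: np.ndarray  # (N,), non-negative
    pred_offset: np.ndarray  # (N, 3)


class CoarseNet:
    """Parameter container + forward pass of the coarse stage."""

    def __init__(self, config: CoarseNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.PCG64(seed))
        dtype = config.np_dtype
        ch = config.in_channels
        self.sa_layers = []
        sa_out = []
        for widths in config.mlp_widths:
            self.sa_layers.append(_nn.init_mlp(rng, 3 + ch, widths, dtype))
            ch = widths[-1]
            sa_out.append(ch)
        self.fp_layers = []
        skip = sa_out[-2::-1] + [config.in_channels]  # finer-level widths
        ch_up = sa_out[-1]
        for widths, skip_ch in zip(config.fp_widths, skip):
            self.fp_layers.append(_nn.init_mlp(rng, ch_up + skip_ch, widths, dtype))
            ch_up = widths[-1]
        hw = config.head_width
        head_in = ch_up + (sa_out[-1] if config.global_context else 0)
        self.head_dist = _nn.init_mlp(rng, head_in, (hw, 1), dtype)
        self.head_off = _nn.init_mlp(rng, head_in, (hw, 3), dtype)

    @property
    def params(self) -> dict[str, Tensor]:
        return _nn.collect_params(
            {
                "sa": self.sa_layers,
                "fp": self.fp_layers,
                "hd": self.head_dist,
                "ho": self.head_off,
            }
        )

    def structure(self, cloud: PointCloud6D) -> _nn.HierStructure:
        c = self.config
        return _nn.build_hier_structure(
            cloud.positions, c.sa_npoints, c.sa_radii, c.sa_nsample
        )

    def forward_t(
        self, cloud: PointCloud6D, structure: _nn.HierStructure | None = None
    ) -> tuple[Tensor, Tensor, _nn.HierStructure]:
        """Tape-building forward pass; returns (distance, offset) tensors."""
        c = self.config
        if cloud.frame != "normalized":
            raise FrameError("coarse stage expects a normalized-frame cloud")
        if structure is None:
            structure = self.structure(cloud)
        dtype = c.np_dtype
        if cloud.features.shape[1] != c.in_channels:
            raise ConfigError(
                f"expected {c.in_channels} input channels, got {cloud.features.shape[1]}"
            )
        feats = _nn.const(cloud.features, dtype=dtype)
        skips = [feats]
        for s, layers in zip(structure.sa, self.sa_layers):
            feats = _nn.apply_sa(feats, s, layers, dtype)
            skips.append(feats)
        up = skips[-1]
        for i, (s, layers) in enumerate(zip(structure.fp, self.fp_layers)):
            up = _nn.apply_fp(up, skips[-2 - i], s, layers)
        if c.global_context:
            g = _nn.maxpool(skips[-1], axis=0)
            up = _nn.concat([up, _nn.tile_rows(g, up.data.shape[0])], axis=-1)
        d_hidden = _nn.apply_mlp(up, self.head_dist[:-1])
        dist = _nn.softplus(_nn.linear(d_hidden, *self.head_dist[-1]))
        o_hidden = _nn.apply_mlp(up, self.head_off[:-1])
        off = _nn.linear(o_hidden, *self.head_off[-1])
        return dist, off, structure


def coarse_forward(
    cloud: PointCloud6D,
    net: CoarseNet,
    structure: _nn.HierStructure | None = None,
) -> CoarseOutput:
    """Run the coarse network; deterministic for fixed weights and input."""
    dist, off, _ = net.forward_t(cloud, structure)
    return CoarseOutput(
        np.asarray(dist.data, dtype=np.float64)[:, 0],
        np.asarray(off.data, dtype=np.float64),
    )


def coarse_targets(
    cloud: PointCloud6D, landmarks: LandmarkSet
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-landmark supervision: distance and offset per point.

    For every cloud point p, its nearest landmark l defines
    true_distance = ||l - p|| and true_offset = l - p, so p + true_offset
    lands exactly on a landmark.
    """
    if cloud.frame != "normalized":
        raise FrameError("targets are built in the normalized frame")
    p = cloud.positions
    l = landmarks.points
    d2 = ((p[:, None, :] - l[None, :, :]) ** 2).sum(-1)
    nearest = d2.argmin(axis=1)
    true_offset = l[nearest] - p
    true_distance = np.sqrt(d2[np.arange(len(p)), nearest])
    return true_distance, true_offset


def make_candidates(
    cloud: PointCloud6D, out: CoarseOutput, n: int = 256
) -> np.ndarray:
    """Displace the n smallest-predicted-distance points by their offsets.

    Ties in predicted distance break to the lowest point index.
    """
    if n > len(cloud):
        raise ConfigError(f"cannot make {n} candidates from {len(cloud)} points")
    sel = np.argsort(out.pred_distance, kind="stable")[:n]
    return cloud.positions[sel] + out.pred_offset[sel]


# ---------------------------------------------------------------------------
# losses (reference NumPy forms; the training path mirrors them on the tape)
# ---------------------------------------------------------------------------


def distance_loss(
    pred_distance: np.ndarray, true_distance: np.ndarray, delta: float = 1.0
) -> float:
    """Smooth-L1 (Huber) loss averaged over points."""
    r = np.asarray(pred_distance, float) - np.asarray(true_distance, float)
    absr = np.abs(r)
    return float(
        np.where(absr <= delta, 0.5 * r**2, delta * (absr - 0.5 * delta)).mean()
    )


def chamfer_loss(candidates: np.ndarray, landmarks: np.ndarray) -> float:
    """Symmetric squared chamfer: mean nearest-squared-distance both ways."""
    c = np.atleast_2d(np.asarray(candidates, float))
    l = np.atleast_2d(np.asarray(landmarks, float))
    d2 = ((c[:, None, :] - l[None, :, :]) ** 2).sum(-1)
    return float(d2.min(axis=1).mean() + d2.min(axis=0).mean())


def separation_loss(candidates: np.ndarray, margin: float = 0.05) -> float:
    """Mean over unordered candidate pairs of max(0, margin - dist)^2."""
    if margin <= 0:
        raise ConfigError("margin must be > 0")
    c = np.asarray(candidates, float)
    n = len(c)
    if n < 2:
        return 0.0
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
    h = np.maximum(margin - d, 0.0)
    np.fill_diagonal(h, 0.0)
    return float((h**2).sum() / 2.0 / (n * (n - 1) / 2.0))


def coarse_total_loss(
    out: CoarseOutput,
    targets: tuple[np.ndarray, np.ndarray],
    candidates: np.ndarray,
    landmarks: LandmarkSet | np.ndarray,
    weights: tuple = (1.0, 1.0, 0.1),
    offset_weight: float = 1.0,
    margin: float = 0.05,
    delta: float = 1.0,
) -> tuple[float, dict]:
    """Weighted composite loss with a per-component breakdown for logging."""
    if any(w < 0 for w in weights) or offset_weight < 0:
        raise ConfigError("loss weights must be >= 0")
    lpts = landmarks.points if isinstance(landmarks, LandmarkSet) else landmarks
    true_d, true_off = targets
    parts = {
        "distance": distance_loss(out.pred_distance, true_d, delta),
        "offset": distance_loss(out.pred_offset.ravel(), true_off.ravel(), delta),
        "chamfer": chamfer_loss(candidates, lpts),
        "separation": separation_loss(candidates, margin),
    }
    total = (
        weights[0] * parts["distance"]
        + offset_weight * parts["offset"]
        + weights[1] * parts["chamfer"]
        + weights[2] * parts["separation"]
    )
    return float(total), parts


def coarse_training_loss(
    dist_t: Tensor,
    off_t: Tensor,
    cloud: PointCloud6D,
    targets: tuple[np.ndarray, np.ndarray],
    landmarks: LandmarkSet,
    config: CoarseNetConfig,
) -> Tensor:
    """Differentiable composite loss on the autodiff tape.

    Mirrors :func:`coarse_total_loss`; candidate selection indices are
    treated as constants (gradients flow through the selected offsets).
    """
    dtype = config.np_dtype
    true_d, true_off = targets
    w_d, w_c, w_s = config.loss_weights
    loss = _nn.scale(
        _nn.huber_mean(dist_t, true_d.astype(dtype)[:, None], config.huber_delta), w_d
    )
    if config.offset_focus_sigma is not None:
        w = np.exp(-((true_d / config.offset_focus_sigma) ** 2))[:, None]
        # renormalize so the effective sample size stays the point count
        w = (w / w.mean()).astype(dtype)
    else:
        w = None
    loss = _nn.add(
        loss,
        _nn.scale(
            _nn.huber_mean(off_t, true_off.astype(dtype), config.huber_delta, weights=w),
            config.offset_weight,
        ),
    )
    n = min(config.n_candidates, len(cloud))
    sel = np.argsort(dist_t.data[:, 0], kind="stable")[:n]
    cand = _nn.add(
        _nn.gather(off_t, sel), _nn.const(cloud.positions[sel], dtype=dtype)
    )
    lm = _nn.const(landmarks.points, dtype=dtype)
    d2 = _nn.sqdist(cand, lm)
    chamfer = _nn.add(
        _nn.mean_all(_nn.minreduce(d2, axis=1)), _nn.mean_all(_nn.minreduce(d2, axis=0))
    )
    loss = _nn.add(loss, _nn.scale(chamfer, w_c))
    sep = _nn.separation_hinge_mean(cand, config.separation_margin)
    return _nn.add(loss, _nn.scale(sep, w_s))
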