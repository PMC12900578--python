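"""Patch-level refinement stage.

Each 6 mm geodesic patch is standardized to a fixed point count, passed
through a small hierarchical encoder-decoder (three set-abstraction and
three feature-propagation levels), and scored with a per-point softmax
probability map. The final landmark is the patch point with the highest
predicted probability, snapped to the cloud and mapped back to cast-frame
millimetres — never an interpolated coordinate.

Supervision is a Gaussian heatmap centred on the true landmark
(sigma = 1 mm by default) with softmax cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from ._nn import Tensor
from .core import ConfigError, SupervisionGapError
from .geometry import LocalPatch
from .preprocess import NormalizationTransform, fps_indices

__all__ = [
    "RefineNetConfig",
    "RefineNet",
    "PatchProbabilityMap",
    "standardize_patch",
    "refine_forward",
    "heatmap_target",
    "refine_loss",
    "extract_landmark",
]


@dataclass(frozen=True)
class RefineNetConfig:
    patch_points: int = 1024
    sa_radii: tuple = (0.05, 0.1, 0.2)  # normalized units, within-patch
    sa_npoints: tuple = (256, 64, 16)
    sa_nsample: tuple = (16, 16, 16)
    mlp_widths: tuple = ((32, 32, 64), (64, 64, 128), (128, 128, 256))
    fp_widths: tuple = ((128, 128), (128, 64), (64, 64, 64))
    head_width: int = 64
    heatmap_sigma: float = 1.0  # mm
    in_channels: int = 6
    dtype: str = "float32"

    def __post_init__(self):
        if self.patch_points < 64:
            raise ConfigError("patch_points must be >= 64")
        if self.heatmap_sigma <= 0:
            raise ConfigError("heatmap_sigma must be > 0")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class PatchProbabilityMap:
    """Per-patch-point probabilities summing to one."""

    probs: np.ndarray  # (m,)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1 or len(self.probs) == 0:
            raise ConfigError("probability map must be a non-empty vector")
        if (self.probs < -1e-9).any() or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ConfigError("probabilities must be in [0, 1] and sum to 1")


def standardize_patch(patch: LocalPatch, config: RefineNetConfig) -> LocalPatch:
    """Resample a patch to exactly ``patch_points`` members, re-centred.

    Larger patches are farthest-point downsampled; smaller ones are padded
    by deterministic cyclic repetition (duplicates share a parent index,
    and their probabilities are merged again on extraction). Positions are
    re-centred on the patch centre.
    """
    m = config.patch_points
    if len(patch) == 0:
        raise ConfigError("cannot standardize an empty patch")
    if len(patch) > m:
        keep = fps_indices(patch.positions, m)
    else:
        keep = np.resize(np.arange(len(patch)), m)
    return LocalPatch(
        indices=patch.indices[keep],
        positions=patch.positions[keep] - patch.center,
        normals=patch.normals[keep],
        center=patch.center.copy(),
        radius_mm=patch.radius_mm,
    )


class RefineNet:
    """Parameter container + forward pass of the refinement stage."""

    def __init__(self, config: RefineNetConfig, seed: int = 0):
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
        skip = sa_out[-2::-1] + [config.in_channels]
        ch_up = sa_out[-1]
        for widths, skip_ch in zip(config.fp_widths, skip):
            self.fp_layers.append(_nn.init_mlp(rng, ch_up + skip_ch, widths, dtype))
            ch_up = widths[-1]
        self.head = _nn.init_mlp(rng, ch_up, (config.head_width, 1), dtype)

    @property
    def params(self) -> dict[str, Tensor]:
        return _nn.collect_params(
            {"sa": self.sa_layers, "fp": self.fp_layers, "head": self.head}
        )

    def structure(self, patch: LocalPatch) -> _nn.HierStructure:
        c = self.config
        return _nn.build_hier_structure(
            patch.positions, c.sa_npoints, c.sa_radii, c.sa_nsample
        )

    def logits_t(
        self, patches: list[LocalPatch], structures=None
    ) -> tuple[Tensor, list]:
        """Batched forward over standardized patches -> (B, P) logits.

        All patches must be standardized to the same size; their grouping
        structures are merged into one flat index set so the whole batch
        runs through a single chain of dense operations.
        """
        c = self.config
        P = c.patch_points
        for p in patches:
            if len(p) != P:
                raise ConfigError("patches must be standardized before the forward pass")
        if structures is None:
            structures = [self.structure(p) for p in patches]
        dtype = c.np_dtype
        feats_np = np.concatenate(
            [np.concatenate([p.positions, p.normals], axis=1) for p in patches]
        ).astype(dtype)
        feats = _nn.const(feats_np)
        B = len(patches)
        skips = [feats]
        prev_n = P
        for li, layers in enumerate(self.sa_layers):
            rel = np.concatenate([s.sa[li].rel_xyz for s in structures]).astype(dtype)
            idx = np.concatenate(
                [s.sa[li].group_idx + b * prev_n for b, s in enumerate(structures)]
            )
            grouped = _nn.concat([_nn.const(rel), _nn.gather(feats, idx)], axis=-1)
            feats = _nn.maxpool(_nn.apply_mlp(grouped, layers), axis=1)
            prev_n = len(structures[0].sa[li].xyz)
            skips.append(feats)
        up = skips[-1]
        n_levels = [P] + [len(s.xyz) for s in structures[0].sa]
        for fi, layers in enumerate(self.fp_layers):
            coarse_n = n_levels[len(self.sa_layers) - fi]
            idx = np.concatenate(
                [s.fp[fi].idx + b * coarse_n for b, s in enumerate(structures)]
            )
            w = np.concatenate([s.fp[fi].w for s in structures]).astype(dtype)
            interp = _nn.weighted_gather_sum(up, idx, w)
            up = _nn.apply_mlp(
                _nn.concat([interp, skips[len(self.sa_layers) - fi - 1]], axis=-1),
                layers,
            )
        h = _nn.apply_mlp(up, self.head[:-1])
        logits = _nn.linear(h, *self.head[-1])  # (B*P, 1)
        # reshape to (B, P) on the tape
        flat = logits

        def bw(g):
            _nn._acc(flat, g.reshape(-1, 1))

        out = Tensor(flat.data.reshape(B, P), (flat,), bw)
        return out, structures


def refine_forward(
    patch: LocalPatch, net: RefineNet, structure=None
) -> PatchProbabilityMap:
    """Probability map over one standardized patch (softmax of the logits)."""
    logits, _ = net.logits_t([patch], [structure] if structure is not None else None)
    z = logits.data[0].astype(np.float64)
    z = z - z.max()
    p = np.exp(z)
    return PatchProbabilityMap(p / p.sum())


def heatmap_target(
    patch: LocalPatch,
    true_landmark: np.ndarray,
    sigma_mm: float,
    transform: NormalizationTransform,
) -> PatchProbabilityMap:
    """Gaussian supervision map exp(-d^2 / 2 sigma^2), normalized to sum 1.

    ``d`` is the straight-line distance in millimetres from each patch
    point to the true landmark (both in the normalized frame; distances
    are converted via ``transform.scale``).
    """
    true_landmark = np.asarray(true_landmark, dtype=np.float64)
    absolute = patch.positions + patch.center
    d_mm = np.linalg.norm(absolute - true_landmark, axis=1) / transform.scale
    w = np.exp(-(d_mm**2) / (2.0 * sigma_mm**2))
    total = w.sum()
    if w.max() < 1e-12:
        raise SupervisionGapError(
            f"true landmark is {d_mm.min():.2f} mm from the nearest patch point; "
            "patch cannot be supervised"
        )
    return PatchProbabilityMap(w / total)


def refine_loss(pred: PatchProbabilityMap, target: PatchProbabilityMap) -> float:
    """Cross-entropy -sum(target * log(pred + 1e-12))."""
    if len(pred.probs) != len(target.probs):
        raise ConfigError("probability maps must cover the same patch")
    return float(-(target.probs * np.log(pred.probs + 1e-12)).sum())


def extract_landmark(
    patch: LocalPatch,
    prob: PatchProbabilityMap,
    transform: NormalizationTransform,
    mode: str = "argmax",
) -> np.ndarray:
    """Highest-probability patch point, mapped back to cast-frame mm.

    Probabilities on padded duplicate points are merged by parent index
    first — by *mean*, since duplicates are identical inputs and carry
    identical per-point probabilities, so averaging undoes the padding
    multiplicity without disturbing the argmax. Ties break to the lowest
    parent index. The result is always an existing cloud point (snapped,
    never interpolated).
    """
    if len(prob.probs) != len(patch):
        raise ConfigError("probability map does not match the patch")
    if mode == "weighted":
        # ablation mode: probability-weighted centroid, sub-point resolution
        absolute = (prob.probs[:, None] * (patch.positions + patch.center)).sum(0)
        return transform.invert(absolute[None, :])[0]
    if mode != "argmax":
        raise ConfigError(f"unknown extraction mode {mode!r}")
    parents, inverse = np.unique(patch.indices, return_inverse=True)
    merged = np.bincount(inverse, weights=prob.probs) / np.bincount(inverse)
    best_parent = parents[int(np.argmax(merged))]
    member = int(np.flatnonzero(patch.indices == best_parent)[0])
    absolute = patch.positions[member] + patch.center
    return transform.invert(absolute[None, :])[0]
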