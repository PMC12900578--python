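"""Pipeline configuration: nested per-stage sections and the two profiles.

``full`` mirrors the study-scale constants (24,000-point clouds, 256
candidates, 1,024-point patches); ``scaled_down`` shrinks every point
budget and halves channel widths so the entire two-stage pipeline trains
on one CPU in minutes, which is the default for tests and examples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

from .coarse import CoarseNetConfig
from .core import ConfigError
from .refine import RefineNetConfig

__all__ = [
    "PreprocessConfig",
    "ClusterConfig",
    "TrainingConfig",
    "PipelineConfig",
]


@dataclass(frozen=True)
class PreprocessConfig:
    n_points: int = 24_000  # farthest-point-sampling budget
    knn_k: int = 8  # neighbour graph degree for geodesics


@dataclass(frozen=True)
class ClusterConfig:
    eps_mm: float = 3.0  # DBSCAN radius, physical mm (converted per cast)
    min_samples: int = 4
    ball_radius_mm: float = 6.0  # geodesic patch radius
    #: If a label's matched centroid is farther than this from its
    #: training-template position, centre the refinement patch on the
    #: template position instead (the coarse stage missed that tooth).
    template_fallback_mm: float = 4.0


@dataclass(frozen=True)
class TrainingConfig:
    coarse_epochs: int = 50
    refine_epochs: int = 50
    coarse_lr: float = 0.001
    refine_lr: float = 0.002
    grad_clip_norm: float = 0.5  # refinement stage only
    batch_size: int = 2  # casts per optimization step
    seed: int = 0
    split_fractions: tuple = (251 / 377, 63 / 377, 63 / 377)
    oracle_patches: bool = True  # centre training patches on ground truth
    #: Radius (mm) of random offsets applied to oracle patch centres during
    #: refinement training. Inference patches are centred on coarse cluster
    #: centroids, not on the truth, so exact ground-truth centring would let
    #: the scorer collapse to "pick the centre point"; the jitter matches
    #: the training and inference patch distributions.
    oracle_center_jitter_mm: float = 2.0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        if self.coarse_lr <= 0 or self.refine_lr <= 0:
            raise ConfigError("learning rates must be > 0")
        if self.coarse_epochs < 0 or self.refine_epochs < 0:
            raise ConfigError("epochs must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    coarse: CoarseNetConfig = field(default_factory=CoarseNetConfig)
    refine: RefineNetConfig = field(default_factory=RefineNetConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    profile: str = "full"
    seed: int = 0
    cast_target_vertices: int = 80_000  # synthetic generator density

    @classmethod
    def full(cls, seed: int = 0) -> "PipelineConfig":
        return cls(seed=seed, training=TrainingConfig(seed=seed))

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "PipelineConfig":
        """CPU-sized profile: 2,048 points, 64 candidates, 256-point patches."""
        return cls(
            preprocess=PreprocessConfig(n_points=2048),
            coarse=CoarseNetConfig(
                sa_npoints=(512, 128, 32),
                sa_nsample=(16, 16, 16),
                mlp_widths=((32, 32, 64), (64, 64, 128), (128, 128, 256)),
                fp_widths=((128, 128), (128, 64), (64, 64, 64)),
                head_width=128,
                n_candidates=64,
                global_context=True,
            ),
            refine=RefineNetConfig(
                patch_points=256,
                sa_npoints=(64, 16, 8),
                sa_nsample=(8, 8, 8),
                mlp_widths=((16, 16, 32), (32, 32, 64), (64, 64, 128)),
                fp_widths=((64, 64), (64, 32), (32, 32, 32)),
                head_width=32,
            ),
            cluster=ClusterConfig(min_samples=2),
            training=TrainingConfig(seed=seed, coarse_lr=0.005),
            profile="scaled_down",
            seed=seed,
            cast_target_vertices=12_000,
        )

    @classmethod
    def from_profile(cls, profile: str, seed: int = 0) -> "PipelineConfig":
        if profile == "full":
            return cls.full(seed)
        if profile == "scaled_down":
            return cls.scaled_down(seed)
        raise ConfigError(f"unknown profile {profile!r}")

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, training=replace(self.training, seed=seed))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
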