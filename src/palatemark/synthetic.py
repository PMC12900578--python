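"""Parametric synthetic maxillary-cast generator with exact landmark ground truth.

Real annotated casts are not publicly deposited, so this module generates
stand-in geometry: a palatal dome bounded by a parabolic alveolar ridge
carrying six tooth bumps per side, each with a small gingival-margin
concavity on its palatal flank. The surface is an analytic height field
over the arch's parameter domain, so the twelve ground-truth landmarks
(the dimple centre of each concavity — the analogue of the most apical
point on the palatal gingival margin) are known in closed form and never
require an annotation step.

Conventions: millimetres; pre-pose canonical frame has +x toward the
patient-right quadrant (FDI 1x), incisors at negative y, occlusal up (+z).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DentalCastMesh,
    FDI_LABELS,
    LandmarkSet,
    PalatemarkError,
)

__all__ = [
    "CastShapeParams",
    "generate_cast",
    "generate_dataset",
    "perturb_landmarks",
    "DEFAULT_REPEAT_SD",
]

#: Isotropic per-session annotation noise (mm) whose two-session mean pairwise
#: distance sqrt(2)*sd*2*sqrt(2/pi) ≈ 0.34 mm emulates expert intraexaminer
#: repeat-annotation error.
DEFAULT_REPEAT_SD = 0.15

# relative mesiodistal widths, central incisor -> first molar; the molar is
# deliberately widest so its gingival concavity is shallowest relative to
# its extent (molar landmarks are the hardest in real dentitions too)
_TOOTH_REL_WIDTHS = np.array([1.0, 1.0, 1.1, 1.1, 1.2, 1.6])


@dataclass(frozen=True)
class CastShapeParams:
    """Shape and sampling parameters of one synthetic cast.

    ``arch_width`` is the midline-to-ridge half-width of the parabolic
    arch, so the cast's transverse extent is roughly twice it plus margins;
    this keeps the transverse axis the statistically widest, which the
    canonical-orientation step relies on.
    """

    arch_width: float = 36.0  # mm, midline to ridge at the posterior end
    arch_depth: float = 42.0  # mm, antero-posterior apex-to-molar depth
    palate_depth: float = 14.0  # mm, dome depression below the ridge
    tooth_bump_height: float = 5.0  # mm
    n_teeth_per_side: int = 6
    surface_noise_sd: float = 0.05  # mm, vertical Gaussian roughness
    target_vertices: int = 12_000
    rigid_pose: tuple | None = None  # ((rx, ry, rz) deg, (tx, ty, tz) mm); None -> sampled
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arch_width", "arch_depth", "palate_depth", "tooth_bump_height"):
            if getattr(self, name) <= 0:
                raise PalatemarkError(f"{name} must be > 0")
        if self.n_teeth_per_side != 6:
            raise PalatemarkError("n_teeth_per_side is fixed at 6")
        if self.target_vertices < 500:
            raise PalatemarkError(
                "target_vertices < 500 cannot resolve 12 gingival concavities"
            )
        if self.surface_noise_sd < 0:
            raise PalatemarkError("surface_noise_sd must be >= 0")


class _ArchModel:
    """Closed-form arch geometry: parabola y = -D/2 + D (x/W)^2."""

    def __init__(self, p: CastShapeParams):
        self.p = p
        self.W = p.arch_width
        self.D = p.arch_depth
        self.a = 2.0 * self.D / self.W**2  # slope coefficient: y' = a x
        # ridge/gum profile
        self.ridge_height = 3.0
        self.ridge_sigma = 4.0
        self.gm_offset = 2.5  # palatal-side offset of the gingival margin (mm)
        self.dent_depth = 1.5
        self.dent_sigma_d = 1.2
        self.dome_start = 4.0
        self.dome_sigma = 6.0
        # tooth layout along the (half-)arc
        L = self.arc_length(self.W)
        u_start, u_end = 0.06 * L, 0.94 * L
        widths = _TOOTH_REL_WIDTHS * (u_end - u_start) / _TOOTH_REL_WIDTHS.sum()
        centers = u_start + np.cumsum(widths) - widths / 2.0
        self.tooth_centers = centers  # anterior (central incisor) -> molar
        self.tooth_widths = widths

    # -- parameterization ---------------------------------------------------

    def y_arc(self, x):
        return -self.D / 2.0 + self.D * (x / self.W) ** 2

    def arc_length(self, x):
        """Exact arc length of the parabola from the apex to |x|."""
        ax = self.a * np.abs(x)
        return (np.abs(x) * np.sqrt(1.0 + ax**2) + np.arcsinh(ax) / self.a) / 2.0

    def x_from_arc(self, s: float) -> float:
        """Invert arc length by Newton iteration (monotone, quadratic)."""
        x = float(s)
        for _ in range(60):
            fx = self.arc_length(x) - s
            dfx = np.sqrt(1.0 + (self.a * x) ** 2)
            step = fx / dfx
            x -= step
            if abs(step) < 1e-13:
                break
        return x

    def cross_coord(self, x, y):
        """Signed pseudo-distance from the arch curve; >0 is palatal (inner)."""
        slope = self.a * x
        return (y - self.y_arc(x)) / np.sqrt(1.0 + slope**2)

    def signed_arc(self, x):
        return np.sign(x) * self.arc_length(x)

    # -- height field -------------------------------------------------------

    def height(self, x, y):
        """Analytic surface height z(x, y)."""
        d = self.cross_coord(x, y)
        u = self.signed_arc(x)
        z = self.ridge_height * np.exp(-(d**2) / (2.0 * self.ridge_sigma**2))
        # palatal dome: saturating depression on the inner side
        inner = np.maximum(d - self.dome_start, 0.0)
        z = z - self.p.palate_depth * (1.0 - np.exp(-(inner**2) / (2.0 * self.dome_sigma**2)))
        # tooth bumps and gingival-margin dents, mirrored on both sides
        for c, w in zip(self.tooth_centers, self.tooth_widths):
            sig_t = 0.35 * w
            sig_u = 0.30 * w
            for s in (+1.0, -1.0):
                du = u - s * c
                z = z + self.p.tooth_bump_height * np.exp(
                    -(du**2) / (2.0 * sig_t**2) - (d**2) / (2.0 * self.ridge_sigma**2)
                )
                z = z - self.dent_depth * np.exp(
                    -(du**2) / (2.0 * sig_u**2)
                    - ((d - self.gm_offset) ** 2) / (2.0 * self.dent_sigma_d**2)
                )
        return z

    # -- landmarks ----------------------------------------------------------

    def landmarks(self) -> LandmarkSet:
        """Ground truth at the analytic dent centres (u_i, gm_offset)."""
        pts = np.empty((12, 3))
        for j, label in enumerate(FDI_LABELS):
            quadrant, tooth = int(label[0]), int(label[1])
            c = self.tooth_centers[tooth - 1]  # tooth 1 = central incisor
            sign = +1.0 if quadrant == 1 else -1.0
            x = sign * self.x_from_arc(c)
            slope = self.a * x
            y = self.y_arc(x) + self.gm_offset * np.sqrt(1.0 + slope**2)
            pts[j] = (x, y, self.height(x, y))
        return LandmarkSet(FDI_LABELS, pts)


def _rotation_matrix(angles_deg) -> np.ndarray:
    rx, ry, rz = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def generate_cast(params: CastShapeParams) -> tuple[DentalCastMesh, LandmarkSet]:
    """Generate one synthetic cast mesh and its exact landmark ground truth.

    Deterministic: the same ``params`` (including ``seed``) yield bit-identical
    vertices, faces, and landmarks.
    """
    p = params
    rng = np.random.default_rng(np.random.PCG64(p.seed))
    arch = _ArchModel(p)
    margin = 6.0
    xmax = p.arch_width + margin + 2.0
    ymin = -p.arch_depth / 2.0 - margin - 2.0
    ymax = p.arch_depth / 2.0

    # estimate the in-domain area fraction on a probe grid, then pick grid
    # dimensions so the masked vertex count lands near target_vertices
    px = np.linspace(-xmax, xmax, 160)
    py = np.linspace(ymin, ymax, 160)
    PX, PY = np.meshgrid(px, py, indexing="ij")
    frac = float(np.mean(_in_domain(arch, PX, PY, margin, ymax)))
    lx, ly = 2 * xmax, ymax - ymin
    nx = int(round(np.sqrt(p.target_vertices / frac * lx / ly)))
    ny = int(round(nx * ly / lx))

    gx = np.linspace(-xmax, xmax, nx)
    gy = np.linspace(ymin, ymax, ny)
    hx, hy = gx[1] - gx[0], gy[1] - gy[0]
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    # jitter interior grid nodes so the triangulation is not a perfect lattice
    JX = X + rng.uniform(-0.25, 0.25, X.shape) * hx
    JY = Y + rng.uniform(-0.25, 0.25, Y.shape) * hy
    mask = _in_domain(arch, JX, JY, margin, ymax)

    Z = np.zeros_like(JX)
    Z[mask] = arch.height(JX[mask], JY[mask])
    if p.surface_noise_sd > 0:
        Z = Z + rng.normal(0.0, p.surface_noise_sd, Z.shape)

    index = -np.ones(X.shape, dtype=np.int64)
    index[mask] = np.arange(int(mask.sum()))
    verts = np.column_stack([JX[mask], JY[mask], Z[mask]])

    # two CCW triangles per fully-interior grid cell -> consistent +z winding
    m00 = mask[:-1, :-1]
    m10 = mask[1:, :-1]
    m01 = mask[:-1, 1:]
    m11 = mask[1:, 1:]
    cell = m00 & m10 & m01 & m11
    i0 = index[:-1, :-1][cell]
    i1 = index[1:, :-1][cell]
    i2 = index[1:, 1:][cell]
    i3 = index[:-1, 1:][cell]
    faces = np.concatenate(
        [np.column_stack([i0, i1, i2]), np.column_stack([i0, i2, i3])]
    )
    # drop boundary vertices that ended up in no complete cell
    used = np.zeros(len(verts), dtype=bool)
    used[faces.ravel()] = True
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    verts = verts[used]
    faces = remap[faces]

    landmarks = arch.landmarks()

    pose = p.rigid_pose
    if pose is None:
        angles = rng.uniform(-20.0, 20.0, 3)
        translation = rng.uniform(-10.0, 10.0, 3)
    else:
        angles, translation = np.asarray(pose[0], float), np.asarray(pose[1], float)
    R = _rotation_matrix(angles)
    verts = verts @ R.T + translation
    lm_pts = landmarks.points @ R.T + translation

    cast_id = f"synthetic-{p.seed}"
    mesh = DentalCastMesh(verts, faces, cast_id=cast_id)
    return mesh, LandmarkSet(FDI_LABELS, lm_pts, cast_id=cast_id)


def _in_domain(arch: _ArchModel, x, y, margin: float, ymax: float):
    return (arch.cross_coord(x, y) >= -margin) & (y <= ymax)


def generate_dataset(
    n: int,
    base_params: CastShapeParams | None = None,
    seed: int = 0,
) -> list[tuple[DentalCastMesh, LandmarkSet]]:
    """Generate ``n`` casts with jittered shapes and independent poses.

    Each length parameter is multiplied by an independent Uniform(0.9, 1.1)
    draw per cast; poses are sampled per cast. Reproducible from ``seed``.
    """
    if n < 1:
        raise PalatemarkError("n must be >= 1")
    base = base_params or CastShapeParams()
    root = np.random.default_rng(np.random.PCG64(seed))
    out = []
    for i in range(n):
        f = root.uniform(0.9, 1.1, 4)
        cast_seed = int(root.integers(0, 2**31 - 1))
        params = replace(
            base,
            arch_width=base.arch_width * f[0],
            arch_depth=base.arch_depth * f[1],
            palate_depth=base.palate_depth * f[2],
            tooth_bump_height=base.tooth_bump_height * f[3],
            rigid_pose=None,
            seed=cast_seed,
        )
        mesh, lms = generate_cast(params)
        mesh.cast_id = f"synthetic-{seed}-{i:04d}"
        lms.cast_id = mesh.cast_id
        out.append((mesh, lms))
    return out


def perturb_landmarks(landmarks: LandmarkSet, sd: float, seed: int = 0) -> LandmarkSet:
    """Add isotropic Gaussian noise of standard deviation ``sd`` mm per axis.

    Emulates a repeat annotation session for reliability studies; labels
    are unchanged.
    """
    if sd < 0:
        raise PalatemarkError("sd must be >= 0")
    rng = np.random.default_rng(np.random.PCG64(seed))
    noise = rng.normal(0.0, sd, landmarks.points.shape) if sd > 0 else 0.0
    return landmarks.with_points(landmarks.points + noise)
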