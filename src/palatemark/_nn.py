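"""Reverse-mode autograd over NumPy arrays and point-network building blocks.

The two landmarking networks are hierarchical point-cloud encoders
(set-abstraction levels: sample centres, group neighbours in a query ball,
shared per-point perceptrons, max-pool per group) with feature-propagation
decoders (inverse-distance interpolation plus skip connections). This
module provides the tensor engine they are built from: a small tape-based
autograd whose primitives are deliberately coarse-grained (fused linear
layers, gather/scatter, pooled reductions) so a forward/backward pass is a
short chain of large BLAS calls.

Grouping structure (sampling indices, ball-query neighbourhoods,
interpolation weights) depends only on point positions, never on weights,
so it is precomputed once per cloud and reused across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .preprocess import fps_indices

# ---------------------------------------------------------------------------
# autograd engine
# ---------------------------------------------------------------------------


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.grad = None
        self._parents = parents
        self._bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad:
        t.grad = g if t.grad is None else t.grad + g


def const(x, dtype=None) -> Tensor:
    return Tensor(np.asarray(x, dtype=dtype))


def parameter(x) -> Tensor:
    return Tensor(np.asarray(x), requires_grad=True)


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _acc(a, g)
        _acc(b, g)

    return Tensor(a.data + b.data, (a, b), bw)


def scale(x: Tensor, s: float) -> Tensor:
    def bw(g):
        _acc(x, g * s)

    return Tensor(x.data * s, (x,), bw)


def linear(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Dense layer over the trailing axis: (..., K) -> (..., N)."""
    xd = x.data
    lead = xd.shape[:-1]
    xf = xd.reshape(-1, xd.shape[-1])
    out = xf @ W.data + b.data

    def bw(g):
        gf = g.reshape(-1, g.shape[-1])
        if x.requires_grad:
            _acc(x, (gf @ W.data.T).reshape(xd.shape))
        _acc(W, xf.T @ gf)
        _acc(b, gf.sum(axis=0))

    return Tensor(out.reshape(*lead, out.shape[-1]), (x, W, b), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        _acc(x, g * mask)

    return Tensor(x.data * mask, (x,), bw)


def softplus(x: Tensor) -> Tensor:
    xd = x.data
    out = np.where(xd > 30, xd, np.log1p(np.exp(np.minimum(xd, 30))))

    def bw(g):
        _acc(x, g / (1.0 + np.exp(-xd)))

    return Tensor(out.astype(xd.dtype), (x,), bw)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: x (N, C), idx any int shape -> (idx.shape, C)."""

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx.ravel(), g.reshape(-1, g.shape[-1]))
            _acc(x, gx)

    return Tensor(x.data[idx], (x,), bw)


def maxpool(x: Tensor, axis: int) -> Tensor:
    arg = x.data.argmax(axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(arg, axis), axis).squeeze(axis)

    def bw(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis)
        _acc(x, gx)

    return Tensor(out, (x,), bw)


def minreduce(x: Tensor, axis: int) -> Tensor:
    arg = x.data.argmin(axis=axis)
    out = np.take_along_axis(x.data, np.expand_dims(arg, axis), axis).squeeze(axis)

    def bw(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, np.expand_dims(arg, axis), np.expand_dims(g, axis), axis)
        _acc(x, gx)

    return Tensor(out, (x,), bw)


def mean_all(x: Tensor) -> Tensor:
    inv = 1.0 / x.data.size

    def bw(g):
        _acc(x, np.full_like(x.data, g * inv))

    return Tensor(np.asarray(x.data.mean(), dtype=x.data.dtype), (x,), bw)


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for p, gp in zip(parts, np.split(g, splits, axis=axis)):
            _acc(p, gp)

    return Tensor(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), bw)


def sqdist(a: Tensor, b: Tensor) -> Tensor:
    """Pairwise squared distances: a (n, 3), b (m, 3) -> (n, m)."""
    ad, bd = a.data, b.data
    D = (
        (ad**2).sum(1)[:, None]
        + (bd**2).sum(1)[None, :]
        - 2.0 * ad @ bd.T
    )
    np.maximum(D, 0.0, out=D)

    def bw(g):
        if a.requires_grad:
            _acc(a, 2.0 * (g.sum(1)[:, None] * ad - g @ bd))
        if b.requires_grad:
            _acc(b, 2.0 * (g.sum(0)[:, None] * bd - g.T @ ad))

    return Tensor(D, (a, b), bw)


def huber_mean(
    pred: Tensor,
    target: np.ndarray,
    delta: float = 1.0,
    weights: np.ndarray | None = None,
) -> Tensor:
    """Smooth-L1 (Huber) loss averaged over all elements.

    ``weights`` (broadcastable to the residual shape) rescale each
    element's contribution; the normalizer stays the element count so a
    weight of 1 everywhere reduces to the plain mean.
    """
    r = pred.data - target
    absr = np.abs(r)
    quad = absr <= delta
    vals = np.where(quad, 0.5 * r**2, delta * (absr - 0.5 * delta))
    inv = 1.0 / r.size
    if weights is not None:
        vals = vals * weights

    def bw(g):
        gr = g * inv * np.clip(r, -delta, delta)
        if weights is not None:
            gr = gr * weights
        _acc(pred, np.broadcast_to(gr, pred.data.shape).astype(pred.data.dtype))

    return Tensor(np.asarray(vals.mean(), dtype=pred.data.dtype), (pred,), bw)


def separation_hinge_mean(c: Tensor, margin: float) -> Tensor:
    """Mean over unordered pairs of max(0, margin - ||ci - cj||)^2."""
    cd = c.data
    n = len(cd)
    if n < 2:
        return Tensor(np.asarray(0.0, dtype=cd.dtype))
    D2 = ((cd[:, None, :] - cd[None, :, :]) ** 2).sum(-1)
    d = np.sqrt(np.maximum(D2, 0.0))
    h = np.maximum(margin - d, 0.0)
    np.fill_diagonal(h, 0.0)
    n_pairs = n * (n - 1) / 2.0
    loss = (h**2).sum() / 2.0 / n_pairs

    def bw(g):
        if c.requires_grad:
            W = h / np.maximum(d, 1e-6)  # zero where hinge inactive
            gc = (-2.0 / n_pairs) * (W.sum(1)[:, None] * cd - W @ cd)
            _acc(c, g * gc)

    return Tensor(np.asarray(loss, dtype=cd.dtype), (c,), bw)


def log_softmax(x: Tensor, axis: int = 0) -> Tensor:
    xd = x.data
    m = xd.max(axis=axis, keepdims=True)
    s = xd - m
    lse = np.log(np.exp(s).sum(axis=axis, keepdims=True))
    y = s - lse

    def bw(g):
        _acc(x, g - np.exp(y) * g.sum(axis=axis, keepdims=True))

    return Tensor(y, (x,), bw)


def nll(logp: Tensor, target: np.ndarray) -> Tensor:
    """Cross entropy -sum(target * logp) against a fixed target map."""

    def bw(g):
        _acc(logp, -g * target)

    return Tensor(np.asarray(-(target * logp.data).sum(), dtype=logp.data.dtype), (logp,), bw)


def tile_rows(x: Tensor, n: int) -> Tensor:
    """Broadcast a (C,) vector to (n, C); gradients sum over the rows."""

    def bw(g):
        _acc(x, g.sum(axis=0))

    return Tensor(np.broadcast_to(x.data[None, :], (n, x.data.shape[-1])).copy(), (x,), bw)


def weighted_gather_sum(feat: Tensor, idx: np.ndarray, w: np.ndarray) -> Tensor:
    """Interpolate rows: out[n] = sum_k w[n, k] * feat[idx[n, k]]."""
    out = (feat.data[idx] * w[..., None]).sum(axis=1)

    def bw(g):
        if feat.requires_grad:
            gf = np.zeros_like(feat.data)
            np.add.at(gf, idx.ravel(), (w[..., None] * g[:, None, :]).reshape(-1, g.shape[-1]))
            _acc(feat, gf)

    return Tensor(out, (feat,), bw)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def init_mlp(rng: np.random.Generator, in_ch: int, widths, dtype) -> list:
    """He-initialized stack of dense layers; returns [(W, b), ...]."""
    layers = []
    for w in widths:
        std = np.sqrt(2.0 / in_ch)
        W = parameter(rng.normal(0.0, std, (in_ch, w)).astype(dtype))
        b = parameter(np.zeros(w, dtype=dtype))
        layers.append((W, b))
        in_ch = w
    return layers


def apply_mlp(x: Tensor, layers, final_relu: bool = True) -> Tensor:
    for i, (W, b) in enumerate(layers):
        x = linear(x, W, b)
        if final_relu or i < len(layers) - 1:
            x = relu(x)
    return x


def collect_params(tree, prefix="") -> dict[str, Tensor]:
    """Flatten a nested structure of [(W, b), ...] lists into a name->Tensor map."""
    out: dict[str, Tensor] = {}
    if isinstance(tree, Tensor):
        out[prefix] = tree
    elif isinstance(tree, (list, tuple)):
        for i, item in enumerate(tree):
            out.update(collect_params(item, f"{prefix}.{i}" if prefix else str(i)))
    elif isinstance(tree, dict):
        for k, v in tree.items():
            out.update(collect_params(v, f"{prefix}.{k}" if prefix else k))
    return out


def get_state(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in params.items()}


def set_state(params: dict[str, Tensor], state: dict[str, np.ndarray]) -> None:
    for k, v in params.items():
        v.data = state[k].astype(v.data.dtype, copy=True)


# ---------------------------------------------------------------------------
# grouping structure (precomputed per cloud)
# ---------------------------------------------------------------------------


@dataclass
class SAStructure:
    """Ball-query grouping for one set-abstraction level."""

    center_idx: np.ndarray  # (np,) indices into the previous level
    group_idx: np.ndarray  # (np, ns) indices into the previous level
    rel_xyz: np.ndarray  # (np, ns, 3) neighbour offsets from the centre
    xyz: np.ndarray  # (np, 3) centre coordinates


@dataclass
class FPStructure:
    """Inverse-distance 3-NN interpolation from a coarse to a fine level."""

    idx: np.ndarray  # (n_fine, k)
    w: np.ndarray  # (n_fine, k), rows sum to 1


@dataclass
class HierStructure:
    xyz_levels: list[np.ndarray]  # [input xyz, level-1 centres, ...]
    sa: list[SAStructure]
    fp: list[FPStructure]  # coarsest->finest, len == len(sa)


def build_hier_structure(
    xyz: np.ndarray, npoints, radii, nsamples
) -> HierStructure:
    """Precompute FPS centres, ball-query groups and FP interpolation.

    Deterministic: FPS start is the farthest-from-centroid point; ball
    neighbours are the nearest within the radius, padded by repeating the
    centre itself when fewer than ``nsample`` fall inside.
    """
    xyz = np.asarray(xyz, dtype=np.float64)
    levels = [xyz]
    sa_structs = []
    prev = xyz
    for npoint, radius, ns in zip(npoints, radii, nsamples):
        npoint = min(npoint, len(prev))
        centers = fps_indices(prev, npoint)
        cxyz = prev[centers]
        tree = cKDTree(prev)
        k = min(ns, len(prev))
        d, idx = tree.query(cxyz, k=k)
        if k == 1:
            d, idx = d[:, None], idx[:, None]
        if k < ns:  # pad columns
            d = np.concatenate([d, np.repeat(d[:, :1], ns - k, axis=1)], axis=1)
            idx = np.concatenate([idx, np.repeat(idx[:, :1], ns - k, axis=1)], axis=1)
        outside = d > radius
        idx = np.where(outside, idx[:, :1], idx)
        rel = prev[idx] - cxyz[:, None, :]
        sa_structs.append(SAStructure(centers, idx, rel, cxyz))
        levels.append(cxyz)
        prev = cxyz
    fp_structs = []
    for lvl in range(len(sa_structs), 0, -1):  # coarsest -> finest
        coarse, fine = levels[lvl], levels[lvl - 1]
        k = min(3, len(coarse))
        tree = cKDTree(coarse)
        d, idx = tree.query(fine, k=k)
        if k == 1:
            d, idx = d[:, None], idx[:, None]
        w = 1.0 / (d**2 + 1e-10)
        w = w / w.sum(axis=1, keepdims=True)
        fp_structs.append(FPStructure(idx, w))
    return HierStructure(levels, sa_structs, fp_structs)


def apply_sa(feats: Tensor, s: SAStructure, layers, dtype) -> Tensor:
    """One set-abstraction level: group, shared MLP, max-pool."""
    grouped = concat([const(s.rel_xyz, dtype=dtype), gather(feats, s.group_idx)], axis=-1)
    h = apply_mlp(grouped, layers)
    return maxpool(h, axis=1)


def apply_fp(coarse_feats: Tensor, skip_feats: Tensor, s: FPStructure, layers) -> Tensor:
    """One feature-propagation level: interpolate, skip-concat, MLP."""
    interp = weighted_gather_sum(coarse_feats, s.idx, s.w.astype(coarse_feats.data.dtype))
    return apply_mlp(concat([interp, skip_feats], axis=-1), layers)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: dict[str, Tensor], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data, dtype=np.float64) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def clip_global_norm(self, max_norm: float) -> float:
        """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
        total = np.sqrt(
            sum(float((p.grad**2).sum()) for p in self.params.values() if p.grad is not None)
        )
        if np.isfinite(max_norm) and total > max_norm > 0:
            factor = max_norm / (total + 1e-12)
            for p in self.params.values():
                if p.grad is not None:
                    p.grad = p.grad * factor
        return total

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
            p.data = p.data - (self.lr * update).astype(p.data.dtype)
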