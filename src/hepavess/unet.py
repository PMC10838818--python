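"""Anisotropic 5-level U-Net for vessel probability maps, in pure numpy.

Clinical CT stacks are anisotropic: in-plane pixels are much finer than the
slice thickness.  The architecture here respects that by splitting every 3D
convolution into a 2D in-plane (3×3×1) convolution followed by a 1D
across-plane (1×1×3) convolution, and by keeping the two shallowest levels
purely in-plane (2D convolutions, in-plane-only pooling).  The across-plane
receptive field is therefore smaller than the in-plane one by construction.

The implementation is a compact explicit-backprop network (forward, reverse
gradients, Adam), sized for *micro-scale* training on synthetic phantoms on
a single CPU — enough to produce genuine learned probability maps to feed
the connection post-processing, not a clinical-scale model.  Training
minimizes a weighted soft-Dice loss with inverse-class-frequency weights,
which keeps thin, rare vessel voxels from being drowned out by background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError, StateError
from .volume import Volume, Mask, resample

__all__ = [
    "AUNetSpec",
    "TrainConfig",
    "AUNet",
    "build_model",
    "weighted_dice_loss",
    "train_micro",
    "predict_volume",
]

_EPS = 1e-6


@dataclass
class AUNetSpec:
    """Architecture description: 5 levels, anisotropic by construction.

    Levels 1–2 use only in-plane convolutions and in-plane pooling; levels
    3–5 use the 2D-then-1D decomposition of a 3D convolution and isotropic
    pooling.
    """

    channels: tuple[int, ...] = (8, 16, 32, 64, 128)

    def __post_init__(self) -> None:
        if len(self.channels) != 5:
            raise ParameterError("the anisotropic U-Net has exactly 5 levels")
        if any(c < 1 for c in self.channels):
            raise ParameterError("channel counts must be positive")

    @property
    def pool_factors(self) -> tuple[tuple[int, int, int], ...]:
        # pools between levels 1→2, 2→3, 3→4, 4→5
        return ((2, 2, 1), (2, 2, 1), (2, 2, 2), (2, 2, 2))

    @property
    def total_pool(self) -> tuple[int, int, int]:
        f = np.prod(np.asarray(self.pool_factors), axis=0)
        return tuple(int(x) for x in f)


@dataclass
class TrainConfig:
    """Micro-training settings (CPU-feasible phantom scale)."""

    patch: tuple[int, int, int] = (32, 32, 8)
    epochs: int = 6
    lr: float = 1e-3
    bce_weight: float = 0.5  # auxiliary cross-entropy share of the objective
    weight_mode: str = "inverse_freq"  # or "uniform"
    target_spacing: float = 0.8  # mm: 0.8 = fine model, 2.0 = coarse model
    patches_per_case: int = 4
    seed: int = 0

    def validate(self, spec: AUNetSpec) -> None:
        for p, f in zip(self.patch, spec.total_pool):
            if p % f != 0:
                raise ParameterError(
                    f"patch size {self.patch} must be divisible by the total "
                    f"pooling factor {spec.total_pool}"
                )
        if self.weight_mode not in ("inverse_freq", "uniform"):
            raise ParameterError("weight_mode must be inverse_freq or uniform")


# ---------------------------------------------------------------- layers


class _Conv:
    """Shared-weight convolution over listed voxel offsets (same padding)."""

    def __init__(self, cin, cout, offsets, rng, kind, level):
        self.offsets = offsets
        self.kind = kind  # '2d' | '1z' | '1x1'
        self.level = level
        fan_in = cin * len(offsets)
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in), (cout, cin, len(offsets))).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)

    def _pad(self):
        off = np.asarray(self.offsets)
        return [(int(-off[:, a].min()), int(off[:, a].max())) for a in range(3)]

    def forward(self, x):
        self.x = x
        pads = self._pad()
        # edge padding keeps constant inputs exactly constant (no border
        # imprint), so tiled prediction shows no seams on flat regions
        xp = np.pad(x, [(0, 0)] + [tuple(p) for p in pads], mode="edge")
        _, X, Y, Z = x.shape
        out = np.zeros((self.W.shape[0], X, Y, Z), dtype=np.float32)
        self._slices = []
        for n, (dx, dy, dz) in enumerate(self.offsets):
            sl = (
                slice(None),
                slice(dx + pads[0][0], dx + pads[0][0] + X),
                slice(dy + pads[1][0], dy + pads[1][0] + Y),
                slice(dz + pads[2][0], dz + pads[2][0] + Z),
            )
            self._slices.append(sl)
            out += np.einsum("oi,ixyz->oxyz", self.W[:, :, n], xp[sl], optimize=True)
        self._xp = xp
        return out + self.b[:, None, None, None]

    def backward(self, g):
        pads = self._pad()
        dxp = np.zeros_like(self._xp)
        self.dW = np.empty_like(self.W)
        for n, sl in enumerate(self._slices):
            self.dW[:, :, n] = np.einsum(
                "oxyz,ixyz->oi", g, self._xp[sl], optimize=True
            )
            dxp[sl] += np.einsum("oi,oxyz->ixyz", self.W[:, :, n], g, optimize=True)
        self.db = g.sum(axis=(1, 2, 3))
        # fold edge-pad gradients back onto the border voxels they mirror
        for a, (p0, p1) in enumerate(pads):
            ax = a + 1
            if p0:
                lead = [slice(None)] * 4
                lead[ax] = slice(0, p0)
                tgt = [slice(None)] * 4
                tgt[ax] = slice(p0, p0 + 1)
                dxp[tuple(tgt)] += dxp[tuple(lead)].sum(axis=ax, keepdims=True)
            if p1:
                trail = [slice(None)] * 4
                trail[ax] = slice(dxp.shape[ax] - p1, None)
                tgt = [slice(None)] * 4
                tgt[ax] = slice(dxp.shape[ax] - p1 - 1, dxp.shape[ax] - p1)
                dxp[tuple(tgt)] += dxp[tuple(trail)].sum(axis=ax, keepdims=True)
        sl = tuple(
            [slice(None)]
            + [slice(p[0], dxp.shape[a + 1] - p[1] or None) for a, p in enumerate(pads)]
        )
        return dxp[sl]

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


def _conv2d(cin, cout, rng, level):
    offs = [(dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]
    return _Conv(cin, cout, offs, rng, "2d", level)


def _conv1z(cin, cout, rng, level):
    return _Conv(cin, cout, [(0, 0, -1), (0, 0, 0), (0, 0, 1)], rng, "1z", level)


def _conv1x1(cin, cout, rng, level):
    return _Conv(cin, cout, [(0, 0, 0)], rng, "1x1", level)


class _ReLU:
    kind = "relu"
    level = None

    def forward(self, x):
        self.m = x > 0
        return x * self.m

    def backward(self, g):
        return g * self.m

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool:
    kind = "pool"

    def __init__(self, factors, level):
        self.f = factors
        self.level = level

    def forward(self, x):
        c, X, Y, Z = x.shape
        fx, fy, fz = self.f
        v = x.reshape(c, X // fx, fx, Y // fy, fy, Z // fz, fz)
        v = v.transpose(0, 1, 3, 5, 2, 4, 6).reshape(
            c, X // fx, Y // fy, Z // fz, fx * fy * fz
        )
        self.arg = v.argmax(axis=-1)
        self.in_shape = x.shape
        return np.take_along_axis(v, self.arg[..., None], axis=-1)[..., 0]

    def backward(self, g):
        c, X, Y, Z = self.in_shape
        fx, fy, fz = self.f
        v = np.zeros((c, X // fx, Y // fy, Z // fz, fx * fy * fz), dtype=g.dtype)
        np.put_along_axis(v, self.arg[..., None], g[..., None], axis=-1)
        v = v.reshape(c, X // fx, Y // fy, Z // fz, fx, fy, fz)
        return v.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, X, Y, Z)

    def params(self):
        return []

    def grads(self):
        return []


class _Upsample:
    kind = "up"

    def __init__(self, factors, level):
        self.f = factors
        self.level = level

    def forward(self, x):
        fx, fy, fz = self.f
        return np.repeat(np.repeat(np.repeat(x, fx, 1), fy, 2), fz, 3)

    def backward(self, g):
        c, X, Y, Z = g.shape
        fx, fy, fz = self.f
        v = g.reshape(c, X // fx, fx, Y // fy, fy, Z // fz, fz)
        return v.sum(axis=(2, 4, 6))

    def params(self):
        return []

    def grads(self):
        return []


class _Sigmoid:
    kind = "sigmoid"
    level = None

    def forward(self, x):
        self.y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self.y

    def backward(self, g):
        return g * self.y * (1 - self.y)

    def params(self):
        return []

    def grads(self):
        return []


# ----------------------------------------------------------------- model


class AUNet:
    """Anisotropic U-Net handle: forward pass, backprop, Adam updates."""

    def __init__(self, spec: AUNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels
        self.down_blocks = []
        cin = 1
        for lvl in range(5):
            block = [_conv2d(cin, ch[lvl], rng, lvl + 1), _ReLU()]
            if lvl >= 2:
                block += [_conv1z(ch[lvl], ch[lvl], rng, lvl + 1), _ReLU()]
            self.down_blocks.append(block)
            cin = ch[lvl]
        self.pools = [
            _MaxPool(f, lvl + 1) for lvl, f in enumerate(spec.pool_factors)
        ]
        self.ups = []
        self.up_blocks = []
        for lvl in range(3, -1, -1):  # decoder back to level 1
            self.ups.append(_Upsample(spec.pool_factors[lvl], lvl + 1))
            block = [_conv2d(ch[lvl + 1] + ch[lvl], ch[lvl], rng, lvl + 1), _ReLU()]
            if lvl >= 2:
                block += [_conv1z(ch[lvl], ch[lvl], rng, lvl + 1), _ReLU()]
            self.up_blocks.append(block)
        self.head = _conv1x1(ch[0], 1, rng, 1)
        self.head.b[:] = -2.0  # start near background: rare-foreground prior
        self.out_act = _Sigmoid()
        self.trained = False
        self.patch = None  # set by training
        self._adam_state = None

    # -- plumbing

    def layers(self):
        out = []
        for b in self.down_blocks:
            out += b
        out += self.pools
        for u, b in zip(self.ups, self.up_blocks):
            out += [u] + b
        out += [self.head, self.out_act]
        return out

    def _run_block(self, block, x):
        for layer in block:
            x = layer.forward(x)
        return x

    def _back_block(self, block, g):
        for layer in reversed(block):
            g = layer.backward(g)
        return g

    def forward(self, patch: np.ndarray) -> np.ndarray:
        """Probability patch for a (X, Y, Z) input patch; shape-preserving."""
        if patch.ndim != 3:
            raise ParameterError("forward expects a 3D patch")
        for p, f in zip(patch.shape, self.spec.total_pool):
            if p % f != 0:
                raise ParameterError(
                    f"patch shape {patch.shape} not divisible by pooling "
                    f"factors {self.spec.total_pool}"
                )
        x = patch[None].astype(np.float32)
        skips = []
        for lvl in range(4):
            x = self._run_block(self.down_blocks[lvl], x)
            skips.append(x)
            x = self.pools[lvl].forward(x)
        x = self._run_block(self.down_blocks[4], x)
        self._concat_channels = []
        for i, lvl in enumerate(range(3, -1, -1)):
            x = self.ups[i].forward(x)
            skip = skips[lvl]
            self._concat_channels.append(skip.shape[0])
            x = np.concatenate([skip, x], axis=0)
            x = self._run_block(self.up_blocks[i], x)
        x = self.head.forward(x)
        return self.out_act.forward(x)[0]

    def backward(self, dprob: np.ndarray) -> None:
        g = self.out_act.backward(dprob[None].astype(np.float32))
        self._backward_core(g)

    def backward_logits(self, dlogit: np.ndarray) -> None:
        """Backprop from a gradient w.r.t. the pre-sigmoid logits.

        Loss terms whose logit gradient is known in closed form (e.g.
        cross-entropy, where the sigmoid derivative cancels) enter here so
        output saturation cannot zero them out.
        """
        self._backward_core(dlogit[None].astype(np.float32))

    def _backward_core(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        skip_grads = {}
        for i, lvl in enumerate(range(3, -1, -1)):
            pass
        # reverse the decoder
        for i in range(3, -1, -1):
            lvl = 3 - i
            g = self._back_block(self.up_blocks[i], g)
            cs = self._concat_channels[i]
            skip_grads[lvl] = g[:cs]
            g = self.ups[i].backward(g[cs:])
        # reverse the encoder
        g = self._back_block(self.down_blocks[4], g)
        for lvl in range(3, -1, -1):
            g = self.pools[lvl].backward(g)
            g = g + skip_grads[lvl]
            g = self._back_block(self.down_blocks[lvl], g)

    def adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        layers = [l for l in self.layers() if l.params()]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [[np.zeros_like(p) for _, p in l.params()] for l in layers],
                "v": [[np.zeros_like(p) for _, p in l.params()] for l in layers],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for li, layer in enumerate(layers):
            for pi, ((_, p), g) in enumerate(zip(layer.params(), layer.grads())):
                m = st["m"][li][pi]
                v = st["v"][li][pi]
                m[:] = beta1 * m + (1 - beta1) * g
                v[:] = beta2 * v + (1 - beta2) * g**2
                mh = m / (1 - beta1**t)
                vh = v / (1 - beta2**t)
                p -= lr * mh / (np.sqrt(vh) + eps)

    def receptive_field(self) -> tuple[int, int, int]:
        """Receptive-field extent (voxels) per axis through the encoder."""
        rf = np.ones(3, dtype=int)
        jump = np.ones(3, dtype=int)
        for lvl in range(5):
            for layer in self.down_blocks[lvl]:
                if isinstance(layer, _Conv):
                    off = np.asarray(layer.offsets)
                    k = off.max(0) - off.min(0) + 1
                    rf += (k - 1) * jump
            if lvl < 4:
                f = np.asarray(self.pools[lvl].f)
                rf += (f - 1) * jump
                jump *= f
        return tuple(int(x) for x in rf)


def build_model(spec: AUNetSpec | None = None, seed: int = 0) -> AUNet:
    """Construct an untrained anisotropic U-Net."""
    return AUNet(spec or AUNetSpec(), seed=seed)


# ------------------------------------------------------------------ loss


def weighted_dice_loss(
    pred: np.ndarray,
    target: np.ndarray,
    w: np.ndarray | None = None,
    eps: float = _EPS,
    return_grad: bool = False,
):
    """Weighted soft-Dice complement: 1 − (2·Σw·p·t + ε)/(Σw·p + Σw·t + ε).

    With uniform weights this is the ordinary soft Dice loss; inverse class
    frequency weights compensate the extreme foreground/background
    imbalance of thin vessels.  Always in [0, 1].
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ParameterError("pred and target shapes must match")
    if w is None:
        w = np.ones_like(pred)
    w = np.asarray(w, dtype=np.float64)
    if w.shape != pred.shape:
        raise ParameterError("weight shape must match pred")
    if np.any(w < 0):
        raise ParameterError("weights must be >= 0")
    num = 2.0 * np.sum(w * pred * target) + eps
    den = np.sum(w * pred) + np.sum(w * target) + eps
    loss = 1.0 - num / den
    if not return_grad:
        return float(loss)
    dpred = -(2.0 * w * target * den - num * w) / den**2
    return float(loss), dpred.astype(np.float32)


# -------------------------------------------------------------- training


def _normalize(data: np.ndarray) -> np.ndarray:
    """Robust intensity normalization shared by training and prediction."""
    med = np.median(data)
    hi = np.quantile(data, 0.999)
    return ((data - med) / max(hi - med, 1e-3)).astype(np.float32)


def _case_arrays(case, spacing: float):
    img = resample(case.image, spacing, order=1)
    msk = resample(case.vessel_mask, spacing, order=0)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(img.shape, msk.shape))
    return _normalize(img.data[sl]), msk.data[sl].astype(np.float32)


def _sample_patch(x, t, patch, rng):
    fg = np.argwhere(t > 0)
    shape = np.asarray(x.shape)
    patch = np.asarray(patch)
    if len(fg):
        c = fg[rng.integers(len(fg))]
    else:
        c = shape // 2
    lo = np.clip(c - patch // 2, 0, np.maximum(shape - patch, 0))
    hi = lo + patch
    pad = np.maximum(patch - shape, 0)
    if np.any(pad > 0):
        x = np.pad(x, [(0, p) for p in pad])
        t = np.pad(t, [(0, p) for p in pad])
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    return x[sl], t[sl]


def _patch_weights(t: np.ndarray, mode: str) -> np.ndarray:
    if mode == "uniform":
        return np.ones_like(t)
    n = t.size
    nf = float(t.sum())
    if nf == 0 or nf == n:
        return np.ones_like(t)
    w = np.where(t > 0, n / (2 * nf), n / (2 * (n - nf)))
    return w.astype(np.float32)


def train_micro(cases, cfg: TrainConfig, spec: AUNetSpec | None = None):
    """Seeded micro-training on phantom cases; returns (model, log).

    The last case is held out; the rest are trained on with foreground-
    centred patches and per-patch inverse-class-frequency Dice weights.
    The log records the per-epoch mean loss and the holdout case index.
    """
    cases = list(cases)
    if len(cases) < 2:
        raise DataError("micro-training needs at least 2 cases (train/holdout)")
    spec = spec or AUNetSpec()
    cfg.validate(spec)
    rng = np.random.default_rng(cfg.seed)
    model = build_model(spec, seed=cfg.seed)
    model.patch = tuple(cfg.patch)
    train = [_case_arrays(c, cfg.target_spacing) for c in cases[:-1]]
    log = {"epoch_loss": [], "holdout_index": len(cases) - 1,
           "target_spacing": cfg.target_spacing}
    for _ in range(cfg.epochs):
        losses = []
        for x, t in train:
            for _ in range(cfg.patches_per_case):
                xp, tp = _sample_patch(x, t, cfg.patch, rng)
                pred = model.forward(xp)
                w = _patch_weights(tp, cfg.weight_mode)
                loss, dpred = weighted_dice_loss(pred, tp, w, return_grad=True)
                # compound objective: weighted Dice plus an auxiliary
                # weighted cross-entropy whose logit gradient w*(p - t)
                # survives sigmoid saturation (Dice alone can die in the
                # all-foreground corner)
                dlogit = dpred * pred * (1.0 - pred)
                if cfg.bce_weight > 0:
                    wsum = float(w.sum())
                    dlogit = dlogit + cfg.bce_weight * w * (pred - tp) / wsum
                model.backward_logits(dlogit.astype(np.float32))
                model.adam_step(cfg.lr)
                losses.append(loss)
        log["epoch_loss"].append(float(np.mean(losses)))
    model.trained = True
    return model, log


def predict_volume(
    model: AUNet,
    v: Volume,
    target_spacing: float,
    overlap: int = 8,
    allow_untrained: bool = False,
) -> Volume:
    """Tiled whole-volume prediction on the working grid.

    The volume is resampled to ``target_spacing``, tiled into model-sized
    patches with the given overlap, and overlapping predictions are
    averaged.  Raises :class:`StateError` for an untrained model unless
    explicitly allowed (useful for baseline comparisons).
    """
    if not model.trained and not allow_untrained:
        raise StateError("model is untrained; train_micro first")
    patch = np.asarray(model.patch or (32, 32, 8))
    work = resample(v, target_spacing, order=1)
    x = _normalize(work.data)
    shape = np.asarray(x.shape)
    pad = np.maximum(patch - shape, 0)
    # also round padded shape up so strides tile exactly
    stride = np.maximum(patch - overlap, 1)
    padded = shape + pad
    padded = np.ceil(np.maximum(padded - patch, 0) / stride).astype(int) * stride + patch
    xpad = np.pad(x, [(0, int(p - s)) for p, s in zip(padded, shape)])
    acc = np.zeros(xpad.shape, dtype=np.float32)
    cnt = np.zeros(xpad.shape, dtype=np.float32)
    starts = [
        list(range(0, int(padded[a] - patch[a]) + 1, int(stride[a])))
        for a in range(3)
    ]
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = tuple(slice(s, s + p) for s, p in zip((sx, sy, sz), patch))
                acc[sl] += model.forward(xpad[sl])
                cnt[sl] += 1.0
    prob = acc / np.maximum(cnt, 1.0)
    prob = prob[tuple(slice(0, s) for s in shape)]
    return Volume(np.clip(prob, 0.0, 1.0), work.spacing, work.origin)
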