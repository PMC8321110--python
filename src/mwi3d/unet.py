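"""U-Net enhancement of multi-frequency CSI reconstructions.

The network learns the mapping G from the 10-channel stack of CSI images
(real and imaginary parts at five frequencies) to the true real
permittivity volume.  Architecture: an encoder of ``depth`` levels, each
a 3^d convolution + ReLU followed by 2x max-pooling, with the filter
count doubling per level from ``base_filters`` (32, 64, ... , 512 at the
bottleneck for the default depth 4); a symmetric decoder with 2x
transposed convolutions and skip concatenations; a linear 1x1 output
convolution.  Weights are real-valued and Glorot-initialized; training
minimizes the pixel-wise mean squared error

    L = (1 / LMN) sum_xyz (I_GT - I_CNN)^2

(the "as printed" form without a square root; a square-root variant is
exposed separately) with Adam, batches of 10, and k-fold cross
validation so that every phantom is predicted exactly once by a model
that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .csi import ReconstructionStack

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "UNet",
    "stack_channels",
    "unstack_channels",
    "build_network",
    "loss_mse",
    "loss_rms",
    "train_network",
    "predict",
    "crossvalidate",
]


@dataclass(frozen=True)
class NetworkConfig:
    """U-Net hyperparameters; defaults are the full-size network."""

    depth: int = 4
    kernel: int = 3
    base_filters: int = 32
    in_channels: int = 10

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1 or self.kernel % 2 != 1:
            raise ValueError("depth/base_filters >= 1 and odd kernel required")

    def filters_at(self, level: int) -> int:
        """Filter count at encoder level (1-based): base * 2^(level-1)."""
        return self.base_filters * 2 ** (level - 1)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam, batches of 10, 200 epochs, 4 folds."""

    batch_size: int = 10
    epochs: int = 200
    folds: int = 4
    seed: int = 0
    lr: float = 1e-3
    betas: tuple = (0.9, 0.999)
    augment_symmetry: bool = True  # random 90-degree rotations / flips

    def __post_init__(self):
        if self.folds < 2 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("folds >= 2, batch_size >= 1, epochs >= 1")


class UNet:
    """Encoder-decoder with skip connections over 2 or 3 spatial dims."""

    def __init__(self, cfg: NetworkConfig, ndim: int, seed: int = 0):
        self.cfg = cfg
        self.ndim = ndim
        rng = np.random.default_rng(seed)
        d, k = cfg.depth, cfg.kernel
        self.enc, self.enc_relu, self.pools = [], [], []
        ch = cfg.in_channels
        for lvl in range(1, d + 1):
            f = cfg.filters_at(lvl)
            self.enc.append(nn.Conv(ch, f, k, ndim, rng))
            self.enc_relu.append(nn.ReLU())
            self.pools.append(nn.MaxPool(ndim))
            ch = f
        self.bottleneck = nn.Conv(ch, cfg.filters_at(d + 1), k, ndim, rng)
        self.bottleneck_relu = nn.ReLU()
        ch = cfg.filters_at(d + 1)
        self.ups, self.dec, self.dec_relu = [], [], []
        for lvl in range(d, 0, -1):
            f = cfg.filters_at(lvl)
            self.ups.append(nn.UpConv(ch, f, ndim, rng))
            self.dec.append(nn.Conv(2 * f, f, k, ndim, rng))
            self.dec_relu.append(nn.ReLU())
            ch = f
        self.head = nn.Conv(ch, 1, 1, ndim, rng)

    def layers(self):
        return (self.enc + self.enc_relu + self.pools
                + [self.bottleneck, self.bottleneck_relu]
                + self.ups + self.dec + self.dec_relu + [self.head])

    @property
    def n_parameters(self) -> int:
        return sum(v.size for l in self.layers() for _, v, _ in l.params())

    def _check(self, x: np.ndarray):
        if x.ndim != self.ndim + 2 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected (batch, {self.cfg.in_channels}, spatial...) input, "
                f"got {x.shape}")
        step = 2 ** self.cfg.depth
        for s in x.shape[2:]:
            if s % step:
                raise ValueError(
                    f"spatial extent {s} not divisible by 2^depth = {step}; "
                    f"pad to a multiple of {step}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._check(x)
        skips = []
        h = x
        for conv, relu, pool in zip(self.enc, self.enc_relu, self.pools):
            h = relu.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck_relu.forward(self.bottleneck.forward(h))
        for up, conv, relu, skip in zip(self.ups, self.dec, self.dec_relu,
                                        reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([h, skip], axis=1)
            h = relu.forward(conv.forward(h))
        return self.head.forward(h)

    def backward(self, gy: np.ndarray):
        g = self.head.backward(gy)
        gskips = []
        for up, conv, relu in zip(reversed(self.ups), reversed(self.dec),
                                  reversed(self.dec_relu)):
            g = conv.backward(relu.backward(g))
            f = up.out_ch
            gskips.append(g[:, f:])
            g = up.backward(g[:, :f])
        g = self.bottleneck.backward(self.bottleneck_relu.backward(g))
        for conv, relu, pool, gskip in zip(reversed(self.enc),
                                           reversed(self.enc_relu),
                                           reversed(self.pools),
                                           reversed(gskips)):
            g = pool.backward(g) + gskip
            g = conv.backward(relu.backward(g))
        return g


def build_network(cfg: NetworkConfig, ndim: int = 3, seed: int = 0) -> UNet:
    return UNet(cfg, ndim, seed)


def stack_channels(stack: ReconstructionStack) -> np.ndarray:
    """CSI stack -> real channel array (2F, spatial...).

    Channel order is deterministic: ascending frequency, real part before
    imaginary part (f1_re, f1_im, ..., fF_im).
    """
    order = np.argsort(stack.frequencies)
    chans = []
    for i in order:
        v = stack.volumes[i]
        chans.append(v.real)
        chans.append(v.imag)
    return np.stack(chans).astype(np.float64)


def unstack_channels(x: np.ndarray, frequencies) -> ReconstructionStack:
    """Inverse of :func:`stack_channels` (frequencies given ascending)."""
    from .grids import VoxelGrid  # avoid cycle at import time
    freqs = tuple(sorted(frequencies))
    if x.shape[0] != 2 * len(freqs):
        raise ValueError("channel count must be 2 x number of frequencies")
    vols = x[0::2] + 1j * x[1::2]
    grid = VoxelGrid(x.shape[1:], spacing=1.0)
    return ReconstructionStack(grid=grid, frequencies=freqs, volumes=vols)


def loss_mse(pred: np.ndarray, target: np.ndarray) -> float:
    """Pixel-wise mean squared error (no square root)."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((target - pred) ** 2))


def loss_rms(pred: np.ndarray, target: np.ndarray) -> float:
    """Square-root variant of :func:`loss_mse`."""
    return float(np.sqrt(loss_mse(pred, target)))


def _fit_norm(x: np.ndarray, y: np.ndarray) -> dict:
    """Training-set standardization statistics.

    Means are per voxel (and channel), so the deterministic breast
    structure and the systematic part of the reconstruction artifacts
    are absorbed by the normalization and the network trains on the
    per-phantom deviations; scales are per input channel / global.
    """
    ax = (0,) + tuple(range(2, x.ndim))
    return {
        "x_mean": x.mean(axis=0),
        "x_std": x.std(axis=ax, keepdims=True)[0] + 1e-8,
        "y_mean": y.mean(axis=0),
        "y_std": float(y.std()) + 1e-8,
    }


def train_network(model: UNet, x: np.ndarray, y: np.ndarray,
                  cfg: TrainConfig) -> dict:
    """Minibatch Adam training; returns per-epoch mean losses.

    ``x``: (n, C, spatial...), ``y``: (n, 1, spatial...), both in
    permittivity units.  Inputs are standardized per channel and the
    target globally using training-set statistics, which are stored on
    the model and inverted by :func:`predict`; epoch losses are reported
    on the standardized scale.  With ``cfg.augment_symmetry`` each batch
    is presented under a random 90-degree in-plane rotation and optional
    flip — symmetries of the circular breast/probe geometry — which
    regularizes training on small phantom sets at no extra cost.
    """
    if x.shape[0] != y.shape[0]:
        raise ValueError("input/target example counts differ")
    rng = np.random.default_rng(cfg.seed)
    model.norm = _fit_norm(x, y)
    xs = (x - model.norm["x_mean"]) / model.norm["x_std"]
    ys = (y - model.norm["y_mean"]) / model.norm["y_std"]
    opt = nn.Adam(model.layers(), lr=cfg.lr,
                  beta1=cfg.betas[0], beta2=cfg.betas[1])
    n = x.shape[0]
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = xs[idx], ys[idx]
            if cfg.augment_symmetry:
                xb, yb = _random_symmetry(xb, yb, rng)
            opt.zero_grad()
            pred = model.forward(xb)
            diff = pred - yb
            epoch_loss += float(np.mean(diff ** 2)) * len(idx)
            model.backward(2.0 * diff / diff.size)
            opt.step()
        losses.append(epoch_loss / n)
    return {"epoch_loss": losses}


def _random_symmetry(xb: np.ndarray, yb: np.ndarray,
                     rng: np.random.Generator):
    """Random square symmetry of the first two spatial axes."""
    k = int(rng.integers(4))
    if k:
        xb = np.rot90(xb, k, axes=(2, 3))
        yb = np.rot90(yb, k, axes=(2, 3))
    if rng.integers(2):
        xb = np.flip(xb, axis=2)
        yb = np.flip(yb, axis=2)
    return np.ascontiguousarray(xb), np.ascontiguousarray(yb)


def predict(model: UNet, x: np.ndarray) -> np.ndarray:
    """Predicted real-permittivity volumes (n, 1, spatial...), unclamped.

    Applies the standardization fitted at training time (identity for an
    untrained model) and maps the output back to permittivity units.
    """
    single = x.ndim == model.ndim + 1
    xb = x[None] if single else x
    norm = getattr(model, "norm", None)
    if norm is None:
        out = model.forward(xb)
    else:
        out = model.forward((xb - norm["x_mean"]) / norm["x_std"]) \
            * norm["y_std"] + norm["y_mean"]
    return out[0] if single else out


def fold_assignments(n: int, folds: int, seed: int) -> np.ndarray:
    """Seeded shuffle into ``folds`` nearly equal folds; fold id per example."""
    if folds > n:
        raise ValueError("more folds than examples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fid = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        fid[chunk] = f
    return fid


def crossvalidate(x: np.ndarray, y: np.ndarray, net_cfg: NetworkConfig,
                  train_cfg: TrainConfig, ndim: int | None = None) -> dict:
    """k-fold cross validation: every example predicted once, out of fold.

    Returns models, pooled out-of-fold predictions aligned with the input
    order, per-fold training curves and a manifest of fold assignments.
    """
    n = x.shape[0]
    ndim = x.ndim - 2 if ndim is None else ndim
    fid = fold_assignments(n, train_cfg.folds, train_cfg.seed)
    preds = np.empty_like(y, dtype=float)
    models, curves = [], []
    for f in range(train_cfg.folds):
        test = fid == f
        model = build_network(net_cfg, ndim,
                              seed=int(train_cfg.seed * 1000 + f))
        hist = train_network(model, x[~test], y[~test], train_cfg)
        preds[test] = predict(model, x[test])
        models.append(model)
        curves.append(hist["epoch_loss"])
    manifest = {"folds": int(train_cfg.folds), "seed": int(train_cfg.seed),
                "fold_of_example": fid.tolist(),
                "train_sizes": [int((fid != f).sum())
                                for f in range(train_cfg.folds)],
                "test_sizes": [int((fid == f).sum())
                               for f in range(train_cfg.folds)]}
    return {"models": models, "predictions": preds, "fold_of_example": fid,
            "curves": curves, "manifest": manifest}
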