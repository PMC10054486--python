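"""The pixel-wise regression UNet and its masked MAE loss.

An encoder–decoder with skip connections maps a P×P×C multispectral patch
to a P×P×1 biomass patch. The decisive difference from the segmentation
original is the output head: a 1×1 convolution with *identity* activation
(no softmax, no terminal ReLU), so the optimizer minimizes the loss on the
actual regressed values. Negative outputs are possible by design and are
clamped only when physical carbon reports are produced.

Each resolution level is two 3×3 convolutions with ReLU and batch
normalization; downsampling is 2×2 max pooling, upsampling a 2×2 stride-2
transposed convolution, and skip connections concatenate the same-resolution
encoder features into the decoder.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass

import numpy as np

from .nnops import BatchNorm2d, Conv2d, ConvTranspose2, MaxPool2, ReLU

__all__ = ["UNetConfig", "UNet", "build_unet", "masked_mae",
           "masked_mae_grad"]


@dataclass
class UNetConfig:
    """Architecture hyperparameters.

    ``patch_size`` must be divisible by ``2**depth`` so every pooling level
    has an integer spatial size (depth ≤ 4 for 16×16 patches).
    """

    in_channels: int = 10
    depth: int = 4
    base_filters: int = 64
    patch_size: int = 16

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.patch_size % (2 ** self.depth):
            raise ValueError(
                f"patch_size {self.patch_size} not divisible by "
                f"2**depth = {2 ** self.depth}")


class _ConvBlock:
    """Two (conv 3×3 → BN → ReLU) stages at one resolution level."""

    def __init__(self, c_in, c_out, rng):
        self.layers = [Conv2d(c_in, c_out, 3, rng), BatchNorm2d(c_out),
                       ReLU(), Conv2d(c_out, c_out, 3, rng),
                       BatchNorm2d(c_out), ReLU()]

    def forward(self, x, training):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


class UNet:
    """Regressive UNet; see module docstring for the architecture."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, f = config.depth, config.base_filters
        enc_ch = [config.in_channels] + [f * 2 ** i for i in range(d)]
        self.enc = [_ConvBlock(enc_ch[i], enc_ch[i + 1], rng)
                    for i in range(d)]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _ConvBlock(enc_ch[d], f * 2 ** d, rng)
        self.ups, self.dec = [], []
        cur = f * 2 ** d
        for i in reversed(range(d)):
            skip = f * 2 ** i
            self.ups.append(ConvTranspose2(cur, skip, rng))
            self.dec.append(_ConvBlock(2 * skip, skip, rng))
            cur = skip
        self.head = Conv2d(cur, 1, k=1, rng=rng)

    # -- plumbing ----------------------------------------------------------
    def _blocks(self):
        blocks = self.enc + [self.bottleneck] + self.dec
        layers = [lay for b in blocks for lay in b.layers]
        layers += self.ups + [self.head]
        return layers

    def parameters(self):
        return [p for lay in self._blocks() for p in lay.params()]

    def grads(self):
        return [g for lay in self._blocks() for g in lay.grads()]

    def get_state(self):
        """Deep copy of all learnable parameters and BN running stats."""
        state = [p.copy() for p in self.parameters()]
        stats = [(l.running_mean.copy(), l.running_var.copy())
                 for l in self._blocks() if isinstance(l, BatchNorm2d)]
        return state, stats

    def set_state(self, state):
        params, stats = state
        for p, s in zip(self.parameters(), params):
            p[...] = s
        bns = [l for l in self._blocks() if isinstance(l, BatchNorm2d)]
        for l, (rm, rv) in zip(bns, stats):
            l.running_mean[...] = rm
            l.running_var[...] = rv

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """x: (N, C, P, P) -> (N, 1, P, P)."""
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, "
                f"got {x.shape[1]}")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        return self.head.forward(x, training)

    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(dout)
        dskips = []
        for dec, up, cs in zip(reversed(self.dec), reversed(self.ups),
                               reversed(self._skip_channels)):
            d = dec.backward(d)
            dskips.append(d[:, :cs])
            d = up.backward(d[:, cs:])
        d_bott = self.bottleneck.backward(d)
        d = d_bott
        for block, pool, dskip in zip(reversed(self.enc),
                                      reversed(self.pools),
                                      reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            d = block.backward(d)

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Inference on (N, P, P, C) patches -> (N, P, P) predictions."""
        x = np.moveaxis(patches, 3, 1)
        out = self.forward(x, training=False)
        return out[:, 0]

    # -- persistence -------------------------------------------------------
    def save(self, weights_path, config_path=None):
        params, stats = self.get_state()
        arrays = {f"p{i}": p for i, p in enumerate(params)}
        for i, (rm, rv) in enumerate(stats):
            arrays[f"rm{i}"], arrays[f"rv{i}"] = rm, rv
        np.savez(weights_path, **arrays)
        if config_path is not None:
            with open(config_path, "w") as fh:
                json.dump(asdict(self.config), fh, indent=2)

    @classmethod
    def load(cls, weights_path, config_path):
        with open(config_path) as fh:
            config = UNetConfig(**json.load(fh))
        model = cls(config)
        with np.load(weights_path) as data:
            nparams = len(model.parameters())
            params = [data[f"p{i}"] for i in range(nparams)]
            stats, i = [], 0
            while f"rm{i}" in data:
                stats.append((data[f"rm{i}"], data[f"rv{i}"]))
                i += 1
        model.set_state((params, stats))
        return model


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct the regressor; raises on an invalid configuration."""
    return UNet(config, seed=seed)


def masked_mae(pred: np.ndarray, target: np.ndarray,
               valid_mask: np.ndarray) -> float:
    """Mean absolute error over valid pixels only.

    Values at masked positions never influence the loss, so nodata target
    pixels can carry arbitrary fill values.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape[-1] == 1 and pred.ndim == target.ndim + 1:
        pred = pred[..., 0]
    if target.shape[-1] == 1 and target.ndim == pred.ndim + 1:
        target = target[..., 0]
    if pred.shape != target.shape:
        raise ValueError("pred/target shape mismatch")
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n = valid_mask.sum()
    if n == 0:
        raise ValueError("masked MAE undefined: no valid pixels")
    return float(np.abs(pred[valid_mask] - target[valid_mask]).sum() / n)


def masked_mae_grad(pred: np.ndarray, target: np.ndarray,
                    valid_mask: np.ndarray) -> np.ndarray:
    """Gradient of :func:`masked_mae` w.r.t. ``pred`` (sign / n_valid)."""
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n = valid_mask.sum()
    if n == 0:
        raise ValueError("masked MAE undefined: no valid pixels")
    return np.where(valid_mask, np.sign(pred - target), 0.0) / n
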