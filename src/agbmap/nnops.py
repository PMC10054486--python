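"""Minimal NumPy layers with hand-written backpropagation.

Everything the encoder–decoder regressor needs: 3×3 / 1×1 convolutions
(im2col), batch normalization, ReLU, 2×2 max pooling, 2×2 stride-2
transposed convolution, and an Adam optimizer. Data layout is NCHW
throughout. Each layer caches what its backward pass needs; ``backward``
must be called with the gradient of the loss w.r.t. the layer output and
returns the gradient w.r.t. the input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "ConvTranspose2",
           "Adam", "Layer"]


class Layer:
    """Base class: parameterless layers just override forward/backward."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x, training=True):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, stride 1, 'same' zero padding, with bias.

    Weights are He-normal initialized (ReLU gain) from the supplied RNG.
    """

    def __init__(self, c_in, c_out, k=3, rng=None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x):
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        # (N, C, H, W, k, k) -> (N, H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        N, C, H, W = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(N, H * W, C * k * k)

    def forward(self, x, training=True):
        self.x_shape = x.shape
        self.cols = self._im2col(x)
        N, C, H, W = x.shape
        out = self.cols @ self.W.T + self.b
        return out.transpose(0, 2, 1).reshape(N, self.c_out, H, W)

    def backward(self, dout):
        N, C, H, W = self.x_shape
        k, p = self.k, self.pad
        dflat = dout.reshape(N, self.c_out, H * W).transpose(0, 2, 1)
        self.dW[...] = np.einsum("npf,npc->fc", dflat, self.cols)
        self.db[...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W                       # (N, H*W, C*k*k)
        dcols = dcols.reshape(N, H, W, C, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=True):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) * \
            self.inv_std[None, :, None, None]
        self.m = x.shape[0] * x.shape[2] * x.shape[3]
        self.training = training
        return self.gamma[None, :, None, None] * self.xhat + \
            self.beta[None, :, None, None]

    def backward(self, dout):
        self.dgamma[...] = (dout * self.xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not self.training:
            return dout * g * self.inv_std[None, :, None, None]
        dxhat = dout * g
        m = self.m
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - self.xhat * (dxhat * self.xhat).mean(axis=(0, 2, 3),
                                                   keepdims=True)
        return term * self.inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=True):
        self.mask = x > 0
        return np.where(self.mask, x, 0.0)

    def backward(self, dout):
        return np.where(self.mask, dout, 0.0)


class MaxPool2(Layer):
    """2×2 max pooling, stride 2; ties route the gradient to the first max."""

    def forward(self, x, training=True):
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2) \
              .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        self.arg = xr.argmax(axis=4)
        self.x_shape = x.shape
        return np.take_along_axis(xr, self.arg[..., None], axis=4)[..., 0]

    def backward(self, dout):
        N, C, H, W = self.x_shape
        dxr = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(dxr, self.arg[..., None], dout[..., None], axis=4)
        return dxr.reshape(N, C, H // 2, W // 2, 2, 2) \
                  .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)


class ConvTranspose2(Layer):
    """2×2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_in, c_out, 2, 2))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=True):
        self.x = x
        N, C, H, W = x.shape
        out = np.einsum("nchw,cfij->nfhiwj", x, self.W)
        out = out.reshape(N, self.c_out, 2 * H, 2 * W)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        N, C, H, W = self.x.shape
        d6 = dout.reshape(N, self.c_out, H, 2, W, 2)
        self.dW[...] = np.einsum("nchw,nfhiwj->cfij", self.x, d6)
        self.db[...] = dout.sum(axis=(0, 2, 3))
        return np.einsum("nfhiwj,cfij->nchw", d6, self.W)


class Adam:
    """Adam with the customary defaults (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
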