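"""Neural-network layers built on the autograd engine.

Convolutions use strided window views plus tensordot; their backward pass
scatters through shifted slices, so no per-element indexing is involved.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autograd import Tensor, Parameter

__all__ = [
    "Layer",
    "Dense",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "GlobalAvgPool1d",
    "Upsample2d",
    "AvgPool2d",
    "glorot",
]


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Layer):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Non-trainable state (running statistics) for serialization."""
        state: dict[str, np.ndarray] = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Layer):
                for sk, sv in v.state_arrays().items():
                    state[f"{k}.{sk}"] = sv
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Layer):
                        for sk, sv in item.state_arrays().items():
                            state[f"{k}.{i}.{sk}"] = sv
        return state


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Parameter(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Layer):
    """1-D convolution on (B, C, L) tensors, zero-padded."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
    ):
        self.stride = stride
        self.kernel = kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in, fan_out = c_in * kernel, c_out * kernel
        self.W = Parameter(glorot(rng, (c_out, c_in, kernel), fan_in, fan_out))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        W, b, st, K, pad = self.W, self.b, self.stride, self.kernel, self.pad
        O, C, _ = W.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
        B, _, Lp = xp.shape
        Lo = (Lp - K) // st + 1
        s0, s1, s2 = xp.strides
        win = as_strided(xp, (B, C, K, Lo), (s0, s1, s2, s2 * st))
        # contiguous im2col buffer, shared by forward and weight gradient
        cols = np.ascontiguousarray(win.transpose(0, 3, 1, 2)).reshape(B * Lo, C * K)
        Wmat = W.data.reshape(O, C * K)
        out_data = (cols @ Wmat.T).reshape(B, Lo, O).transpose(0, 2, 1) + b.data[None, :, None]

        def bw(g):  # g: (B, O, Lo)
            g2 = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * Lo, O)
            if W.requires_grad:
                W._accum((g2.T @ cols).reshape(W.data.shape))
            if b.requires_grad:
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ Wmat).reshape(B, Lo, C, K)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, :, k : k + Lo * st : st] += gcols[:, :, :, k].transpose(0, 2, 1)
                x._accum(gxp[:, :, pad : Lp - pad] if pad else gxp)

        rg = x.requires_grad or W.requires_grad
        return Tensor(out_data, requires_grad=rg, parents=(x, W, b), backward=bw)


class Conv2d(Layer):
    """2-D convolution on (B, C, H, W) tensors, zero-padded ('same' default)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
    ):
        self.stride = stride
        self.kernel = kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in, fan_out = c_in * kernel * kernel, c_out * kernel * kernel
        self.W = Parameter(glorot(rng, (c_out, c_in, kernel, kernel), fan_in, fan_out))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        W, b, st, K, pad = self.W, self.b, self.stride, self.kernel, self.pad
        O, C, _, _ = W.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        B, _, Hp, Wp = xp.shape
        Ho, Wo = (Hp - K) // st + 1, (Wp - K) // st + 1
        s0, s1, s2, s3 = xp.strides
        win = as_strided(xp, (B, C, K, K, Ho, Wo), (s0, s1, s2, s3, s2 * st, s3 * st))
        cols = np.ascontiguousarray(win.transpose(0, 4, 5, 1, 2, 3)).reshape(
            B * Ho * Wo, C * K * K
        )
        Wmat = W.data.reshape(O, C * K * K)
        out_data = (cols @ Wmat.T).reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)
        out_data += b.data[None, :, None, None]

        def bw(g):  # g: (B, O, Ho, Wo)
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, O)
            if W.requires_grad:
                W._accum((g2.T @ cols).reshape(W.data.shape))
            if b.requires_grad:
                b._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ Wmat).reshape(B, Ho, Wo, C, K, K)
                gxp = np.zeros_like(xp)
                for ki in range(K):
                    for kj in range(K):
                        gxp[:, :, ki : ki + Ho * st : st, kj : kj + Wo * st : st] += (
                            gcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                        )
                x._accum(gxp[:, :, pad : Hp - pad, pad : Wp - pad] if pad else gxp)

        rg = x.requires_grad or W.requires_grad
        return Tensor(out_data, requires_grad=rg, parents=(x, W, b), backward=bw)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        nd = x.data.ndim
        axes = tuple(i for i in range(nd) if i != 1)
        shape = [1] * nd
        shape[1] = -1
        if train:
            mu = x.mean(axis=axes[0], keepdims=True)
            for ax in axes[1:]:
                mu = mu.mean(axis=ax, keepdims=True)
            diff = x - mu
            var = (diff * diff).mean(axis=axes[0], keepdims=True)
            for ax in axes[1:]:
                var = var.mean(axis=ax, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
            xhat = diff * ((var + self.eps) ** -0.5)
        else:
            dt = x.data.dtype
            mu = self.running_mean.reshape(shape).astype(dt)
            sd = np.sqrt(self.running_var + self.eps).reshape(shape).astype(dt)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class GlobalAvgPool1d(Layer):
    def __call__(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)


class AvgPool2d(Layer):
    """2x2 average pooling."""

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=5).mean(axis=3)


class Upsample2d(Layer):
    """Nearest-neighbour 2x upsampling."""

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

        def bw(g):
            if x.requires_grad:
                x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

        return Tensor(out_data, requires_grad=x.requires_grad, parents=(x,), backward=bw)
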