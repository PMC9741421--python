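"""The branching sensor-to-image reconstruction network.

Two paths share the measurement tensor and the auxiliary scalars
(modulation frequency, phantom diameter):

* background predictor ("block B") — strided 1-D convolutions whose first
  stride equals the detector count, global average pooling to 16 units,
  aux concatenation, two dense layers and a softplus head giving the two
  strictly positive background coefficients;
* domain transform ("block A") — a deep 1-D convolutional encoder-decoder
  (per-source strided collection, bottleneck gated multiplicatively by an
  aux embedding, additive skip) producing 16 x N_s features, two dense
  layers, a circular mask, and a residual U-net refining the initial
  64 x 64 x 2 contrast image to [0, 1].

The absolute-coefficient image is contrast (denormalized) x background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..mesh import circular_mask
from .autograd import Tensor, concat
from .layers import (
    Layer,
    Dense,
    Conv1d,
    Conv2d,
    BatchNorm,
    GlobalAvgPool1d,
    AvgPool2d,
    Upsample2d,
)

__all__ = ["NetworkConfig", "LossWeights", "ReconNet", "assemble_network", "loss_Q"]


@dataclass(frozen=True)
class NetworkConfig:
    n_sources: int = 16
    n_detectors: int = 15
    grid_size: int = 64
    blockB_channels: tuple[int, int] = (16, 16)
    blockB_pooled: int = 16
    blockB_fc: int = 32
    blockA_widths: tuple[int, int] = (16, 64)
    blockA_features: int = 16  # per-source features out of block A (16 x N_s)
    blockA_fc: int = 512
    aux_embedding_size: int = 128
    unet_widths: tuple[int, int, int] = (32, 64, 128)
    kernel_1d: int = 3
    kernel_2d: int = 3
    dtype: str = "float64"
    seed: int = 0
    # default parameter spans used to min-max scale the aux inputs
    aux_frequency_range: tuple[float, float] = (10.0, 100.0)
    aux_diameter_range: tuple[float, float] = (60.0, 150.0)
    # softplus head bias is initialized so the untrained background outputs
    # sit at these range midpoints
    background_init: tuple[float, float] = (0.0175, 1.75)

    def __post_init__(self) -> None:
        if self.n_detectors != self.n_sources - 1:
            raise ValueError(
                "ring probe requires n_detectors = n_sources - 1 "
                f"(got {self.n_detectors} vs {self.n_sources})"
            )
        if self.blockB_channels[-1] != self.blockB_pooled:
            raise ValueError("block B's last convolution width must equal the pooled size")
        if self.n_sources % 2:
            raise ValueError("n_sources must be even (encoder halves the length)")
        if self.grid_size % 4:
            raise ValueError("grid_size must be divisible by 4 (two U-net levels)")

    @classmethod
    def small(cls, n_sources: int = 16, seed: int = 0) -> "NetworkConfig":
        """Reduced-width configuration for CPU-scale experiments."""
        return cls(
            n_sources=n_sources,
            n_detectors=n_sources - 1,
            blockB_channels=(8, 16),
            blockA_widths=(8, 32),
            blockA_fc=256,
            aux_embedding_size=64,
            unet_widths=(8, 16, 32),
            dtype="float32",
            seed=seed,
        )


@dataclass(frozen=True)
class LossWeights:
    w_ima: float = 1.0
    w_ims: float = 1.0
    w_a: float = 100.0**2
    w_s: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_ima, self.w_ims, self.w_a, self.w_s) < 0:
            raise ValueError("loss weights must be nonnegative")


class _BackgroundPath(Layer):
    """Block B: measurements + aux -> 2 positive background coefficients."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        c1, c2 = cfg.blockB_channels
        nd = cfg.n_detectors
        self.conv1 = Conv1d(2, c1, kernel=nd, stride=nd, pad=0, rng=rng)
        self.conv2 = Conv1d(c1, c2, kernel=cfg.kernel_1d, rng=rng)
        self.pool = GlobalAvgPool1d()
        self.fc1 = Dense(cfg.blockB_pooled + 2, cfg.blockB_fc, rng)
        self.fc2 = Dense(cfg.blockB_fc, 2, rng)
        # inverse softplus of the configured midpoints
        self.fc2.b.data[:] = np.log(np.expm1(np.asarray(cfg.background_init)))

    def __call__(self, meas: Tensor, aux: Tensor, train: bool) -> Tensor:
        h = self.conv1(meas).relu()
        h = self.conv2(h).relu()
        h = self.pool(h)  # (B, 16)
        h = concat([h, aux], axis=1)
        h = self.fc1(h).relu()
        return self.fc2(h).softplus()


class _DomainTransform(Layer):
    """Block A: measurements + aux -> masked initial contrast image."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        w1, w2 = cfg.blockA_widths
        k, nd = cfg.kernel_1d, cfg.n_detectors
        nf = cfg.blockA_features
        emb = cfg.aux_embedding_size
        self.conv1 = Conv1d(2, w1, k, rng)
        self.bn1 = BatchNorm(w1)
        self.conv2 = Conv1d(w1, w1, k, rng)
        self.bn2 = BatchNorm(w1)
        self.conv3 = Conv1d(w1, w2, k, rng)
        self.bn3 = BatchNorm(w2)
        self.collect = Conv1d(w2, w2, kernel=nd, stride=nd, pad=0, rng=rng)
        self.enc = Conv1d(w2, w2, k, rng, stride=2)
        self.mid1 = Conv1d(w2, emb, k, rng)
        self.bn_mid = BatchNorm(emb)
        self.aux_embed = Dense(2, emb, rng)
        self.mid2 = Conv1d(emb, w2, k, rng)
        self.dec = Conv1d(w2, nf, k, rng)
        self.fc1 = Dense(nf * cfg.n_sources, cfg.blockA_fc, rng)
        self.fc2 = Dense(cfg.blockA_fc, 2 * cfg.grid_size**2, rng)
        self.grid_size = cfg.grid_size
        self.mask = circular_mask(cfg.grid_size).astype(float)

    def __call__(self, meas: Tensor, aux: Tensor, train: bool) -> Tensor:
        h = self.bn1(self.conv1(meas), train).elu()
        h = self.bn2(self.conv2(h), train).elu()
        h = self.bn3(self.conv3(h), train).leaky_relu()
        h = self.collect(h).leaky_relu()  # (B, w2, N_s)
        e = self.enc(h).leaky_relu()  # (B, w2, N_s/2)
        m = self.bn_mid(self.mid1(e), train).leaky_relu()
        gate = self.aux_embed(aux).sigmoid()  # (B, emb)
        B, emb = gate.shape
        m = m * gate.reshape(B, emb, 1)  # per-channel bottleneck gating
        m = self.mid2(m).leaky_relu() + e  # additive skip
        h = self.dec(m).leaky_relu()  # (B, nf, N_s/2) -> upsample
        h = _upsample1d(h)  # (B, nf, N_s)
        B = h.shape[0]
        flat = h.reshape(B, -1)  # 16 x N_s features
        z = self.fc1(flat).leaky_relu()
        img = self.fc2(z).reshape(B, 2, self.grid_size, self.grid_size)
        return img * self.mask[None, None]


def _upsample1d(x: Tensor) -> Tensor:
    B, C, L = x.shape
    out_data = np.repeat(x.data, 2, axis=2)

    def bw(g):
        if x.requires_grad:
            x._accum(g.reshape(B, C, L, 2).sum(axis=3))

    return Tensor(out_data, requires_grad=x.requires_grad, parents=(x,), backward=bw)


class _UNet(Layer):
    """Three-level residual U-net refining the two-channel contrast image."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        w0, w1, w2 = cfg.unet_widths
        k = cfg.kernel_2d
        self.in0 = Conv2d(2, w0, k, rng)
        self.bn0 = BatchNorm(w0)
        self.in1 = Conv2d(w0, w0, k, rng)
        self.down1 = Conv2d(w0, w1, k, rng)
        self.bn1 = BatchNorm(w1)
        self.down2 = Conv2d(w1, w2, k, rng)
        self.bn2 = BatchNorm(w2)
        self.up2 = Conv2d(w2, w1, k, rng)
        self.mix1 = Conv2d(w1, w1, k, rng)
        self.up1 = Conv2d(w1, w0, k, rng)
        self.mix0 = Conv2d(w0, w0, k, rng)
        self.out = Conv2d(w0, 2, k, rng)
        self.pool = AvgPool2d()
        self.upsample = Upsample2d()
        self.mask = circular_mask(cfg.grid_size).astype(float)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        e0 = self.in1(self.bn0(self.in0(x), train).leaky_relu()).leaky_relu()
        e1 = self.bn1(self.down1(self.pool(e0)), train).leaky_relu()
        b = self.bn2(self.down2(self.pool(e1)), train).leaky_relu()
        d1 = self.up2(self.upsample(b)).leaky_relu() + e1
        d1 = self.mix1(d1).leaky_relu()
        d0 = self.up1(self.upsample(d1)).leaky_relu() + e0
        d0 = self.mix0(d0).leaky_relu()
        out = self.out(d0) + x  # additive input-output skip
        return out.sigmoid() * self.mask[None, None]


class ReconNet(Layer):
    """Full branching model.  Call returns (contrast images, backgrounds)."""

    def __init__(self, config: NetworkConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.background_path = _BackgroundPath(config, rng)
        self.domain_transform = _DomainTransform(config, rng)
        self.unet = _UNet(config, rng)
        dt = np.dtype(config.dtype)
        if dt == np.float32:  # float32 graph for CPU-scale training speed
            for p in self.parameters():
                p.data = p.data.astype(dt)
            self.domain_transform.mask = self.domain_transform.mask.astype(dt)
            self.unet.mask = self.unet.mask.astype(dt)
        # per-feature input standardization, fitted on the training split
        n_feat = config.n_sources * config.n_detectors
        self.input_mean = np.zeros((2, n_feat))
        self.input_std = np.ones((2, n_feat))

    # -- input plumbing ----------------------------------------------------

    def fit_normalization(self, inputs: np.ndarray) -> None:
        """Store training-set standardization statistics.

        ``inputs`` is (N, N_s, N_d, 2) raw measurement data.
        """
        flat = self._to_channels(inputs)
        self.input_mean = flat.mean(axis=0)
        std = flat.std(axis=0)
        self.input_std = np.where(std < 1e-12, 1.0, std)

    def _to_channels(self, inputs: np.ndarray) -> np.ndarray:
        n = inputs.shape[0]
        cfg = self.config
        return inputs.transpose(0, 3, 1, 2).reshape(n, 2, cfg.n_sources * cfg.n_detectors)

    def prepare_inputs(self, inputs: np.ndarray, aux: np.ndarray):
        """Normalize raw (N, N_s, N_d, 2) measurements and (N, 2) aux scalars."""
        cfg = self.config
        x = (self._to_channels(inputs) - self.input_mean) / self.input_std
        f_lo, f_hi = cfg.aux_frequency_range
        d_lo, d_hi = cfg.aux_diameter_range
        a = np.column_stack(
            [
                (aux[:, 0] - f_lo) / (f_hi - f_lo),
                (aux[:, 1] - d_lo) / (d_hi - d_lo),
            ]
        )
        dt = np.dtype(cfg.dtype)
        return x.astype(dt), a.astype(dt)

    # -- forward -----------------------------------------------------------

    def __call__(self, meas: Tensor, aux: Tensor, train: bool = True):
        background = self.background_path(meas, aux, train)
        initial = self.domain_transform(meas, aux, train)
        contrast = self.unet(initial, train)
        return contrast, background

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = super().state_arrays()
        state["input_mean"] = self.input_mean
        state["input_std"] = self.input_std
        return state

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()


def assemble_network(config: NetworkConfig) -> ReconNet:
    """Build the branching network; raises on inconsistent configuration."""
    return ReconNet(config)


def loss_Q(
    pred_contrast: Tensor,
    pred_background: Tensor,
    truth_contrast: np.ndarray,
    truth_background: np.ndarray,
    mask: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> Tensor:
    """Weighted sum of MSEs over contrast images and background coefficients.

    Image MSEs average over the pixels inside the circular mask (and the
    batch); background MSEs average over the batch.
    """
    if pred_contrast.shape[-2:] != mask.shape:
        raise ValueError("mask does not match image grid")
    if pred_contrast.shape[0] != pred_background.shape[0]:
        raise ValueError("batch size mismatch")
    n_masked = int(mask.sum())
    B = pred_contrast.shape[0]
    dt = pred_contrast.data.dtype
    m = mask.astype(dt)[None, None]
    diff = (pred_contrast - np.asarray(truth_contrast, dtype=dt)) * m
    per_channel = (diff * diff).sum(axis=3).sum(axis=2).sum(axis=0) * (1.0 / (B * n_masked))
    mse_ca = per_channel.reshape(2)  # (2,)
    bdiff = pred_background - np.asarray(truth_background, dtype=dt)
    mse_bg = (bdiff * bdiff).mean(axis=0)
    w_img = np.array([weights.w_ima, weights.w_ims], dtype=dt)
    w_bg = np.array([weights.w_a, weights.w_s], dtype=dt)
    return (mse_ca * w_img).sum() + (mse_bg * w_bg).sum()
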