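"""The sleep-signal encoder: multi-scale 1-D convolutions with CBAM attention.

Two parallel convolutional branches read each 30-s epoch.  The small-kernel
branch (kernel 64 at 100 Hz = a 0.64-s window, stride 8) resolves fast
rhythms such as alpha (8-13 Hz) and sleep spindles; the large-kernel branch
(kernel 512 = 5.12 s, stride 64) captures slow delta activity (0.5-4 Hz)
dominant in deep sleep.  Each branch is gated by a convolutional block
attention module (CBAM): channel attention first reweights feature maps
(what matters), then spatial attention reweights positions along time
(where it matters).  Branch outputs are flattened, concatenated, linearly
projected to the shared embedding dimension and L2-normalized, so the
cosine similarity against label embeddings reduces to a dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (Conv1d, Linear, Module, Tensor, concat, conv1d,
                       maxpool1d)
from .io_edf import SAMPLES_PER_EPOCH


@dataclass
class EncoderConfig:
    """Hyperparameters of the EEG encoder.

    At the canonical 100 Hz rate the default kernels correspond to receptive
    windows of small_kernel/rate = 0.64 s and large_kernel/rate = 5.12 s.
    """

    small_kernel: int = 64
    small_stride: int = 8
    large_kernel: int = 512
    large_stride: int = 64
    filters: int = 64
    reduction_ratio: int = 8
    spatial_kernel: int = 7
    embed_dim: int = 128
    leaky_relu_slope: float = 0.01
    sampling_rate: float = 100.0
    # post-CBAM refinement convolutions (kernel, same padding, stride 1)
    refine_kernel: int = 8
    small_pool1: int = 8
    small_pool2: int = 4
    large_pool1: int = 4
    large_pool2: int = 2

    @property
    def small_window_s(self) -> float:
        return self.small_kernel / self.sampling_rate

    @property
    def large_window_s(self) -> float:
        return self.large_kernel / self.sampling_rate

    def validate(self) -> None:
        if self.filters // self.reduction_ratio < 1:
            raise ValueError("reduction_ratio larger than channel count")
        if self.small_kernel == 64 and self.large_kernel == 512 \
                and self.sampling_rate == 100.0:
            assert abs(self.small_window_s - 0.64) < 1e-12
            assert abs(self.large_window_s - 5.12) < 1e-12


class ChannelAttention(Module):
    """Channel gate: shared two-layer MLP over position-pooled descriptors.

    Average and max pooling collapse the position axis to two per-channel
    descriptors; a shared squeeze (w0) / expand (w1) MLP scores them and a
    sigmoid of the summed scores gates each channel.
    """

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator):
        if channels // reduction_ratio < 1:
            raise ValueError(
                f"reduction_ratio {reduction_ratio} larger than channel count {channels}"
            )
        hidden = channels // reduction_ratio
        self.w0 = Linear(channels, hidden, rng)
        self.w1 = Linear(hidden, channels, rng)

    def __call__(self, F: Tensor) -> Tensor:
        avg = F.mean(axis=-1)                       # (B, C)
        mx = F.max(axis=-1)                         # (B, C)
        score = self.w1(self.w0(avg).relu()) + self.w1(self.w0(mx).relu())
        return score.sigmoid().reshape(F.shape[0], F.shape[1], 1)


class SpatialAttention(Module):
    """Spatial gate: width-7 convolution over channel-pooled maps."""

    def __init__(self, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("spatial kernel must be odd for same-padding")
        self.conv = Conv1d(2, 1, kernel, stride=1, padding=kernel // 2, rng=rng)
        self.kernel = kernel

    def __call__(self, F: Tensor) -> Tensor:
        if F.shape[-1] < self.kernel:
            raise ValueError(
                f"position axis length {F.shape[-1]} shorter than spatial kernel "
                f"{self.kernel}"
            )
        avg = F.mean(axis=1, keepdims=True)         # (B, 1, L)
        mx = F.max(axis=1, keepdims=True)           # (B, 1, L)
        pooled = concat([avg, mx], axis=1)          # (B, 2, L)
        return self.conv(pooled).sigmoid()          # (B, 1, L)


class CBAM(Module):
    """Sequential channel then spatial attention; shape-preserving."""

    def __init__(self, channels: int, reduction_ratio: int, spatial_kernel: int,
                 rng: np.random.Generator):
        self.channel = ChannelAttention(channels, reduction_ratio, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)

    def __call__(self, F: Tensor) -> Tensor:
        F_prime = self.channel(F) * F
        F_dprime = self.spatial(F_prime) * F_prime
        return F_dprime


# ---- functional surface (operates on plain arrays, for direct use) --------

def channel_attention(F: np.ndarray, module: ChannelAttention) -> np.ndarray:
    """Channel attention map for a (batch, channels, positions) feature map."""
    return module(Tensor(np.asarray(F, dtype=np.float64))).data


def apply_channel_attention(F: np.ndarray, Mc: np.ndarray) -> np.ndarray:
    """F' = Mc ⊗ F (pointwise, broadcast over positions)."""
    F = np.asarray(F, dtype=np.float64)
    Mc = np.asarray(Mc, dtype=np.float64)
    out = Mc * F
    if out.shape != F.shape:
        raise ValueError(f"attention map shape {Mc.shape} does not broadcast to {F.shape}")
    return out


def spatial_attention(F_prime: np.ndarray, module: SpatialAttention) -> np.ndarray:
    """Spatial attention map for a (batch, channels, positions) feature map."""
    return module(Tensor(np.asarray(F_prime, dtype=np.float64))).data


class _Branch(Module):
    def __init__(self, kernel: int, stride: int, pool1: int, pool2: int,
                 cfg: EncoderConfig, rng: np.random.Generator):
        self.conv1 = Conv1d(1, cfg.filters, kernel, stride=stride, rng=rng)
        self.cbam = CBAM(cfg.filters, cfg.reduction_ratio, cfg.spatial_kernel, rng)
        pad = cfg.refine_kernel // 2
        self.conv2 = Conv1d(cfg.filters, cfg.filters, cfg.refine_kernel,
                            stride=1, padding=pad, rng=rng)
        self.conv3 = Conv1d(cfg.filters, cfg.filters, cfg.refine_kernel,
                            stride=1, padding=pad, rng=rng)
        self.pool1 = pool1
        self.pool2 = pool2
        self.slope = cfg.leaky_relu_slope
        # output length arithmetic for the flattened feature size
        L = (SAMPLES_PER_EPOCH - kernel) // stride + 1
        L = L // pool1
        L = L + 2 * pad - cfg.refine_kernel + 1
        L = L + 2 * pad - cfg.refine_kernel + 1
        self.out_len = (L // pool2) * cfg.filters

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x).leaky_relu(self.slope)
        h = self.cbam(h)
        h = maxpool1d(h, self.pool1)
        h = self.conv2(h).leaky_relu(self.slope)
        h = self.conv3(h).leaky_relu(self.slope)
        h = maxpool1d(h, self.pool2)
        return h.reshape(h.shape[0], -1)


class EEGEncoder(Module):
    """Dual-branch convolutional encoder producing unit-norm embeddings."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        self.small = _Branch(config.small_kernel, config.small_stride,
                             config.small_pool1, config.small_pool2, config, rng)
        self.large = _Branch(config.large_kernel, config.large_stride,
                             config.large_pool1, config.large_pool2, config, rng)
        flat = self.small.out_len + self.large.out_len
        self.proj = Linear(flat, config.embed_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (batch, 3000) -> unit-norm embeddings (batch, embed_dim)."""
        if x.shape[-1] != SAMPLES_PER_EPOCH:
            raise ValueError(
                f"epochs must have {SAMPLES_PER_EPOCH} samples, got {x.shape[-1]}"
            )
        xb = x.reshape(x.shape[0], 1, SAMPLES_PER_EPOCH)
        feats = concat([self.small(xb), self.large(xb)], axis=-1)
        return self.proj(feats).l2_normalize(axis=-1)


def encode_epochs(batch, encoder: EEGEncoder) -> np.ndarray:
    """Encode epochs (SignalEpoch collection or (n, 3000) array) to embeddings."""
    arr = _batch_to_array(batch)
    return encoder(Tensor(arr)).data


def _batch_to_array(batch) -> np.ndarray:
    if isinstance(batch, np.ndarray):
        arr = np.atleast_2d(batch)
    else:
        arr = np.stack([np.asarray(getattr(ep, "samples", ep), dtype=np.float64)
                        for ep in batch])
    if arr.shape[-1] != SAMPLES_PER_EPOCH:
        raise ValueError(
            f"epochs must have {SAMPLES_PER_EPOCH} samples, got {arr.shape[-1]}"
        )
    return arr
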