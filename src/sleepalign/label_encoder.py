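"""The label encoder: a small pre-norm transformer over a class token.

Each categorical stage label is looked up in a learned 5-row embedding table
(the "label data"), projected to the hidden width, and prepended with a
learnable class token c.  The two-token sequence passes through K identical
pre-norm residual blocks,

    psi~ = MHA(Norm(psi)) + psi
    psi  = MLP(Norm(psi~)) + psi~

where MHA is multi-head self-attention and the MLP is two linear layers with
a ReLU and dropout in between.  The final state of the class token, linearly
projected to the shared embedding dimension and L2-normalized, is the label
embedding L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (LayerNorm, Linear, Module, Tensor, concat, dropout,
                       softmax)
from .io_edf import StageLabel

N_STAGES = 5


@dataclass
class TransformerConfig:
    layers: int = 4
    hidden_dim: int = 128
    heads: int = 4
    mlp_ratio: float = 4.0
    dropout: float = 0.1
    embed_dim: int = 128

    def validate(self) -> None:
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")
        if self.layers < 1:
            raise ValueError("need at least one transformer layer")


class MultiHeadAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.heads = heads
        self.dim = dim

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H, dh = self.heads, self.dim // self.heads

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh)), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.wo(out)


class FeedForward(Module):
    def __init__(self, dim: int, mlp_ratio: float, p_drop: float,
                 rng: np.random.Generator):
        hidden = int(round(dim * mlp_ratio))
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.p_drop = p_drop

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        return self.fc2(dropout(self.fc1(x).relu(), self.p_drop, rng))


class TransformerBlock(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.norm1 = LayerNorm(cfg.hidden_dim)
        self.mha = MultiHeadAttention(cfg.hidden_dim, cfg.heads, rng)
        self.norm2 = LayerNorm(cfg.hidden_dim)
        self.mlp = FeedForward(cfg.hidden_dim, cfg.mlp_ratio, cfg.dropout, rng)

    def __call__(self, psi: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        psi = self.mha(self.norm1(psi)) + psi
        psi = self.mlp(self.norm2(psi), rng) + psi
        return psi


class LabelEncoder(Module):
    """Maps stage codes to unit-norm label embeddings L."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        h = config.hidden_dim
        bound = 1.0 / np.sqrt(h)
        # 5-row lookup table standing in for the categorical "label data"
        self.table = Tensor(rng.uniform(-bound, bound, (N_STAGES, h)),
                            requires_grad=True)
        self.w_tran = Linear(h, h, rng)          # projection to the hidden dim
        self.cls = Tensor(rng.uniform(-bound, bound, (h,)), requires_grad=True)
        self.blocks = [TransformerBlock(config, rng) for _ in range(config.layers)]
        self.out_proj = Linear(h, config.embed_dim, rng)

    def __call__(self, codes, rng: np.random.Generator | None = None) -> Tensor:
        """codes: iterable of stage codes -> (n, embed_dim) unit-norm embeddings.

        ``rng`` enables dropout (training); inference passes None and the
        forward pass is then a pure function of (codes, weights).
        """
        codes = np.asarray([int(c) for c in codes])
        if codes.ndim != 1 or np.any((codes < 0) | (codes >= N_STAGES)):
            raise ValueError(f"invalid stage codes: {codes}")
        n = codes.size
        y_tilde = self.w_tran(self.table[codes]).reshape(n, 1, -1)
        c = self.cls.reshape(1, 1, -1) + Tensor(np.zeros((n, 1, self.config.hidden_dim)))
        psi = concat([c, y_tilde], axis=1)       # psi_0 = [c; y~]
        for block in self.blocks:
            psi = block(psi, rng)
        return self.out_proj(psi[:, 0, :]).l2_normalize(axis=-1)


def embed_label(y: StageLabel | int, encoder: LabelEncoder) -> np.ndarray:
    """Embedding of a single stage label (inference: dropout disabled)."""
    return encoder([int(y)]).data[0]


def label_prototype_table(encoder: LabelEncoder) -> np.ndarray:
    """(5, embed_dim) matrix whose row i is the embedding of stage code i."""
    return encoder(np.arange(N_STAGES)).data
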