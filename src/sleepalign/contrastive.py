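"""Contrastive pairing of signal and label embeddings.

Training follows the CLIP recipe: a batch of (epoch, stage) pairs is encoded
by the two encoders, the temperature-scaled cosine-similarity matrix between
signal embeddings S and label embeddings L is formed, and a symmetric
cross-entropy pulls matched pairs onto the diagonal — the signal→label
direction classifies each row against its own column, the label→signal
direction does the same over columns, and the two are averaged.

With only five stages a uniformly random batch would repeat labels, turning
off-diagonal cells into false negatives; the default batching is therefore
stratified — one randomly drawn epoch per distinct stage, so every
off-diagonal cell is a true negative.  An optional multi-positive masked
variant supports repeated labels.

Inference is nearest-prototype: each epoch's embedding is scored by cosine
against the five cached label embeddings and the best-scoring stage wins
(ties break toward the lowest stage code).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, SGD, Tensor, logsumexp
from .eeg_encoder import EEGEncoder, EncoderConfig, _batch_to_array
from .io_edf import StageLabel
from .label_encoder import (LabelEncoder, N_STAGES, TransformerConfig,
                            label_prototype_table)
from .preprocess import EpochDataset

logger = logging.getLogger(__name__)

CHECKPOINT_MAGIC = "sleepalign-checkpoint-v1"


@dataclass
class TrainConfig:
    steps: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    batch_stages: int = 5
    temperature: str = "learnable"   # "learnable" or "fixed:<value>"
    temperature_init: float = 14.3   # ~1/0.07, the CLIP convention
    optimizer: str = "adam"
    stratified: bool = True          # False: random batches + multi-positive mask
    batch_size: int = 5              # used only when stratified is False


# ---------------------------------------------------------------------------
# similarity and loss
# ---------------------------------------------------------------------------

def cosine_similarity(s: np.ndarray, l: np.ndarray) -> float:
    """cos<S, L> = S·L / (||S|| ||L||), in [-1, 1]."""
    s = np.asarray(s, dtype=np.float64)
    l = np.asarray(l, dtype=np.float64)
    ns, nl = np.linalg.norm(s), np.linalg.norm(l)
    if ns == 0 or nl == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(s, l) / (ns * nl))


def similarity_matrix(S_batch, L_batch, tau: float = 1.0):
    """Temperature-scaled pairwise cosine matrix; entry (i,j) = tau·cos<S_i,L_j>.

    Accepts arrays or Tensors; returns the same kind.  For Tensor inputs the
    rows are assumed unit-norm (the encoders normalize), so the cosine is the
    dot product and gradients flow through it.
    """
    if isinstance(S_batch, Tensor) or isinstance(L_batch, Tensor):
        S, L = Tensor.as_tensor(S_batch), Tensor.as_tensor(L_batch)
        if S.shape[0] == 0 or L.shape[0] == 0:
            raise ValueError("empty batch")
        return (S @ L.transpose(1, 0)) * tau
    S = np.atleast_2d(np.asarray(S_batch, dtype=np.float64))
    L = np.atleast_2d(np.asarray(L_batch, dtype=np.float64))
    if S.shape[0] == 0 or L.shape[0] == 0:
        raise ValueError("empty batch")
    Sn = S / np.linalg.norm(S, axis=1, keepdims=True)
    Ln = L / np.linalg.norm(L, axis=1, keepdims=True)
    tau_val = tau.data if isinstance(tau, Tensor) else tau
    return tau_val * (Sn @ Ln.T)


def contrastive_loss(M, positive_mask: np.ndarray | None = None):
    """Symmetric cross-entropy over a square similarity matrix.

    Signal direction: each row i is a softmax classification whose correct
    class is column i; label direction: the same over columns.  The loss is
    the mean of the two directions.  Accepts a Tensor (returns a Tensor, for
    training) or an array (returns a float).

    ``positive_mask`` (bool, same shape) marks multiple positives per
    row/column; when given, each direction averages -log of the total
    softmax mass on the positives.
    """
    is_tensor = isinstance(M, Tensor)
    Mt = Tensor.as_tensor(M)
    n, m = Mt.shape
    if n != m:
        raise ValueError(f"similarity matrix must be square, got {n}x{m}")
    loss = _directional_ce(Mt, positive_mask) + \
        _directional_ce(Mt.transpose(1, 0),
                        None if positive_mask is None else positive_mask.T)
    loss = loss * 0.5
    return loss if is_tensor else float(loss.data)


def _directional_ce(M: Tensor, positive_mask: np.ndarray | None) -> Tensor:
    n = M.shape[0]
    lse = logsumexp(M, axis=-1)                       # (n,)
    if positive_mask is None:
        idx = np.arange(n)
        pos = M[idx, idx]
    else:
        # log of total softmax mass on the positives of each row
        neg_inf = np.where(positive_mask, 0.0, -np.inf)
        pos = logsumexp(M + Tensor(neg_inf), axis=-1)
    return (lse - pos).mean()


# ---------------------------------------------------------------------------
# the dual-encoder model
# ---------------------------------------------------------------------------

class ContrastiveStager:
    """Both encoders plus the learnable temperature; the trainable unit."""

    def __init__(self, encoder_config: EncoderConfig | None = None,
                 transformer_config: TransformerConfig | None = None,
                 train_config: TrainConfig | None = None,
                 seed: int = 0):
        self.encoder_config = encoder_config or EncoderConfig()
        self.transformer_config = transformer_config or TransformerConfig(
            embed_dim=self.encoder_config.embed_dim)
        if self.transformer_config.embed_dim != self.encoder_config.embed_dim:
            raise ValueError("encoder and label-encoder embed_dim must match")
        self.train_config = train_config or TrainConfig(seed=seed)
        rng = np.random.default_rng(seed)
        self.eeg_encoder = EEGEncoder(self.encoder_config, rng)
        self.label_encoder = LabelEncoder(self.transformer_config, rng)
        temp = self.train_config.temperature
        if temp.startswith("fixed:"):
            self._fixed_tau = float(temp.split(":", 1)[1])
            self.log_tau = None
        else:
            self._fixed_tau = None
            self.log_tau = Tensor(np.log(self.train_config.temperature_init),
                                  requires_grad=True)
        self._prototypes: np.ndarray | None = None

    # ---- parameters -----------------------------------------------------
    def parameters(self) -> dict[str, Tensor]:
        params = {f"eeg.{k}": v for k, v in self.eeg_encoder.parameters().items()}
        params.update({f"label.{k}": v
                       for k, v in self.label_encoder.parameters().items()})
        if self.log_tau is not None:
            params["log_tau"] = self.log_tau
        return params

    @property
    def tau(self) -> float:
        if self.log_tau is not None:
            return float(np.exp(self.log_tau.data))
        return self._fixed_tau

    def _tau_tensor(self):
        return self.log_tau.exp() if self.log_tau is not None else self._fixed_tau

    # ---- inference -------------------------------------------------------
    def prototypes(self, refresh: bool = False) -> np.ndarray:
        """Cached (5, d_e) label-prototype table."""
        if self._prototypes is None or refresh:
            self._prototypes = label_prototype_table(self.label_encoder)
        return self._prototypes

    def predict(self, epochs) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-prototype classification.

        Returns (codes, scores): codes (n,) int stage codes, scores (n, 5)
        cosine similarities against the five prototypes in code order.
        Elementwise: the prediction for an epoch does not depend on the other
        epochs in the call.
        """
        arr = _batch_to_array(epochs)
        protos = self.prototypes()
        scores = np.empty((arr.shape[0], N_STAGES))
        for start in range(0, arr.shape[0], 256):   # bounded working memory
            chunk = arr[start:start + 256]
            S = self.eeg_encoder(Tensor(chunk)).data
            scores[start:start + 256] = S @ protos.T
        codes = scores.argmax(axis=1)                # ties -> lowest stage code
        return codes, scores


# ---------------------------------------------------------------------------
# training (the "pre-learning" loop)
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    loss_trace: np.ndarray
    model: ContrastiveStager


def train(dataset: EpochDataset, model: ContrastiveStager,
          config: TrainConfig | None = None) -> TrainResult:
    """Train both encoders (and the temperature) by symmetric cross-entropy.

    Each step draws a stratified batch (one random epoch per distinct stage),
    encodes signals and labels, forms the temperature-scaled similarity
    matrix, applies the symmetric contrastive loss, and updates every weight.
    Fully reproducible given the config seed.
    """
    config = config or model.train_config
    rng = np.random.default_rng(config.seed)
    labels = dataset.labels()
    signals = dataset.signals()
    present = set(int(c) for c in np.unique(labels))
    required = list(range(config.batch_stages))
    missing = [StageLabel(c).name for c in required if c not in present]
    if missing:
        raise ValueError(f"dataset lacks epochs for stage(s): {missing}")
    by_stage = {c: np.nonzero(labels == c)[0] for c in required}

    params = model.parameters()
    if config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate)
    elif config.optimizer == "sgd":
        opt = SGD(params, lr=config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    trace = np.empty(config.steps)
    for step in range(config.steps):
        if config.stratified:
            stages = np.array(required)
            rng.shuffle(stages)
            idx = np.array([rng.choice(by_stage[int(c)]) for c in stages])
            batch_labels = stages
            mask = None
        else:
            idx = rng.choice(len(labels), size=config.batch_size, replace=False)
            batch_labels = labels[idx]
            mask = batch_labels[:, None] == batch_labels[None, :]
        S = model.eeg_encoder(Tensor(signals[idx]))
        L = model.label_encoder(batch_labels, rng=rng)
        M = similarity_matrix(S, L, model._tau_tensor())
        loss = contrastive_loss(M, positive_mask=mask)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace[step] = loss.item()
        if step % 50 == 0:
            logger.info("step %d: loss %.4f (tau %.2f)", step, trace[step], model.tau)

    model.prototypes(refresh=True)
    return TrainResult(loss_trace=trace, model=model)


# ---------------------------------------------------------------------------
# checkpoints — self-describing npz: configs + all weights + prototypes
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: ContrastiveStager,
                    loss_trace: np.ndarray | None = None) -> None:
    meta = {
        "magic": CHECKPOINT_MAGIC,
        "encoder_config": vars(model.encoder_config),
        "transformer_config": vars(model.transformer_config),
        "train_config": vars(model.train_config),
    }
    arrays = {f"param::{k}": v.data for k, v in model.parameters().items()}
    arrays["prototypes"] = model.prototypes()
    if loss_trace is not None:
        arrays["loss_trace"] = np.asarray(loss_trace)
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> ContrastiveStager:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("magic") != CHECKPOINT_MAGIC:
            raise ValueError(f"not a sleepalign checkpoint: {path}")
        model = ContrastiveStager(
            encoder_config=EncoderConfig(**meta["encoder_config"]),
            transformer_config=TransformerConfig(**meta["transformer_config"]),
            train_config=TrainConfig(**meta["train_config"]),
            seed=meta["train_config"].get("seed", 0),
        )
        params = model.parameters()
        for key in z.files:
            if key.startswith("param::"):
                name = key[len("param::"):]
                if name not in params:
                    raise ValueError(f"checkpoint parameter {name!r} does not "
                                     "match the model architecture")
                params[name].data = z[key]
        model._prototypes = z["prototypes"] if "prototypes" in z.files else None
    return model
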