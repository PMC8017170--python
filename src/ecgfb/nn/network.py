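"""The frame-block classifier: residual CNN trunk + attention-based BiLSTM.

One binary classifier per abnormality (binary relevance).  The CNN trunk is
applied to every frame of a block with shared weights:

    Conv1D -> BN -> ReLU -> max-pool(3)
    -> dense block 1 (two Conv1D+BN with an identity shortcut added before
       the second ReLU)
    -> dense block 2 (same, but the shortcut carries Conv1D+BN to adapt
       channels and stride)
    -> global average pooling

yielding one embedding per frame.  The F_n embeddings form the sequence
consumed by a bidirectional LSTM; additive attention pools the BiLSTM
outputs into a context vector, and a single sigmoid unit trained with
binary cross-entropy produces the class probability.

Layer-census convention: the "13 layers" of the trunk are its 6 Conv1D,
6 batch-norm and 1 max-pool layers; global average pooling is counted as
the interface to the sequence model rather than a trunk layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..preprocess import FrameBlock
from .layers import (
    AdditiveAttention, BatchNorm, BiLSTM, Conv1D, Dense, GlobalAvgPool,
    Layer, MaxPool1D, Param, ReLU, bce_with_logits, sigmoid, F32,
)
from .optim import Adam


class ConstructionError(ValueError):
    """Raised when a model and its input disagree on shape."""


class TrainingError(RuntimeError):
    """Raised on degenerate training sets or divergence."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The published description fixes the topology but not the per-layer
    sizes; these defaults are this package's own choices and every field is
    overridable.
    """

    frame_count: int = 10
    frame_length: int = 2000
    leads: int = 12
    initial_filters: int = 32
    initial_kernel: int = 16
    initial_stride: int = 2
    block1_filters: int = 32
    block1_kernel: int = 7
    block2_filters: int = 64
    block2_kernel: int = 5
    block2_stride: int = 2
    pool_size: int = 3
    lstm_units: int = 64
    attention_dim: int = 64
    threshold: float = 0.5
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stopping_patience: int = 5
    early_stopping_min_epochs: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        for name in ("initial_filters", "block1_filters", "block2_filters",
                     "lstm_units", "attention_dim", "frame_count",
                     "frame_length", "leads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def small(self) -> "ModelConfig":
        """Reduced-width preset (same topology) for CPU-scale experiments."""
        return replace(self, initial_filters=12, block1_filters=12,
                       block2_filters=24, lstm_units=16, attention_dim=16)

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return (self.frame_count, self.frame_length, self.leads)


class _ResBlockIdentity(Layer):
    """Dense block 1: two Conv1D+BN with an identity shortcut.

    The input is added to the second BN's output before the final ReLU, so
    the block learns a residual on top of the identity map.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        self.conv1 = Conv1D(channels, channels, kernel, 1, rng)
        self.bn1 = BatchNorm(channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(channels, channels, kernel, 1, rng)
        self.bn2 = BatchNorm(channels)
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        return self.relu_out.forward(y + x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        return (dmain + d).astype(F32)


class _ResBlockProjection(Layer):
    """Dense block 2: residual block whose shortcut is Conv1D+BN.

    The projection adapts channel count and stride so the two branches can
    be summed.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, rng: np.random.Generator):
        self.conv1 = Conv1D(in_channels, out_channels, kernel, stride, rng)
        self.bn1 = BatchNorm(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(out_channels, out_channels, kernel, 1, rng)
        self.bn2 = BatchNorm(out_channels)
        self.short_conv = Conv1D(in_channels, out_channels, 1, stride, rng)
        self.short_bn = BatchNorm(out_channels)
        self.relu_out = ReLU()

    def params(self) -> list[Param]:
        return (self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params()
                + self.short_conv.params() + self.short_bn.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        s = self.short_bn.forward(self.short_conv.forward(x, train), train)
        return self.relu_out.forward(y + s, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(d)))))
        dshort = self.short_conv.backward(self.short_bn.backward(d))
        return (dmain + dshort).astype(F32)


class ModelHandle:
    """A built (possibly trained) per-class classifier.

    The forward pass is deterministic given fixed parameters; outputs are
    probabilities in (0, 1).  ``history`` records per-epoch training and
    validation loss once :func:`train` has run.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.stem_conv = Conv1D(c.leads, c.initial_filters, c.initial_kernel,
                                c.initial_stride, rng)
        self.stem_bn = BatchNorm(c.initial_filters)
        self.stem_relu = ReLU()
        self.pool = MaxPool1D(c.pool_size)
        if c.block1_filters != c.initial_filters:
            raise ConstructionError(
                "dense block 1 uses an identity shortcut; block1_filters "
                f"({c.block1_filters}) must equal initial_filters ({c.initial_filters})"
            )
        self.block1 = _ResBlockIdentity(c.block1_filters, c.block1_kernel, rng)
        self.block2 = _ResBlockProjection(c.block1_filters, c.block2_filters,
                                          c.block2_kernel, c.block2_stride, rng)
        self.gap = GlobalAvgPool()
        self.bilstm = BiLSTM(c.block2_filters, c.lstm_units, rng)
        self.attention = AdditiveAttention(2 * c.lstm_units, c.attention_dim, rng)
        self.head = Dense(2 * c.lstm_units, 1, rng)
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self.trained = False

    # -- structure ---------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in (self.stem_conv, self.stem_bn, self.block1, self.block2,
                      self.bilstm, self.attention, self.head):
            out.extend(layer.params())
        return out

    def trunk_layer_census(self) -> dict[str, int]:
        """Count the CNN-trunk layers under the documented convention.

        Conv1D + BatchNorm + max-pool layers of the per-frame trunk; the
        global average pooling that hands the embedding sequence to the
        BiLSTM is not counted as a trunk layer.
        """
        conv = 1 + 2 + 3   # stem, block1 mains, block2 mains + projection
        bn = 1 + 2 + 3
        pool = 1
        return {"conv": conv, "batch_norm": bn, "max_pool": pool,
                "total": conv + bn + pool}

    # -- forward / backward ------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        expect = self.config.input_shape
        if x.ndim != 4 or x.shape[1:] != expect:
            raise ConstructionError(
                f"input blocks of shape {x.shape[1:] if x.ndim == 4 else x.shape} "
                f"do not match model input shape {expect}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch of blocks shaped (B, F_n, F_l, leads)."""
        x = np.asarray(x, dtype=F32)
        self._check_shape(x)
        B, Fn, Fl, C = x.shape
        frames = x.reshape(B * Fn, Fl, C)
        y = self.stem_relu.forward(self.stem_bn.forward(
            self.stem_conv.forward(frames, train), train), train)
        y = self.pool.forward(y, train)
        y = self.block1.forward(y, train)
        y = self.block2.forward(y, train)
        emb = self.gap.forward(y, train)                  # (B*Fn, d)
        seq = emb.reshape(B, Fn, -1)
        hs = self.bilstm.forward(seq, train)
        ctx = self.attention.forward(hs, train)
        return self.head.forward(ctx, train).ravel()

    def _backward(self, dlogits: np.ndarray, batch: int) -> None:
        d = self.head.backward(dlogits.reshape(-1, 1))
        d = self.attention.backward(d)
        d = self.bilstm.backward(d)
        d = d.reshape(batch * self.config.frame_count, -1)
        d = self.gap.backward(d)
        d = self.block2.backward(d)
        d = self.block1.backward(d)
        d = self.pool.backward(d)
        d = self.stem_bn.backward(self.stem_relu.backward(d))
        self.stem_conv.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in (0, 1), evaluation mode (running BN stats)."""
        probs = []
        # chunk to bound im2col memory
        for start in range(0, len(x), 64):
            probs.append(sigmoid(self.forward_logits(x[start:start + 64], train=False)))
        return np.concatenate(probs)


def build_model(config: ModelConfig = ModelConfig()) -> ModelHandle:
    """Construct the untrained per-class classifier."""
    return ModelHandle(config)


def attention_pool(sequence: np.ndarray,
                   attention: AdditiveAttention | None = None,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Attention-pool a single sequence (T, d) -> (context, weights).

    Weights are the softmax of the additive attention scores: non-negative
    and summing to one; the context is the weights' weighted sum of steps.
    Uses the supplied (possibly trained) attention layer, or a freshly
    initialised one under ``seed``.
    """
    seq = np.asarray(sequence, dtype=F32)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError(f"sequence must be a non-empty (T, d) matrix, got shape {seq.shape}")
    if attention is None:
        attention = AdditiveAttention(seq.shape[1], max(seq.shape[1], 1),
                                      np.random.default_rng(seed))
    context = attention.forward(seq[None], train=False)[0]
    return context, attention.last_weights[0]


def _stack_blocks(blocks: list[FrameBlock] | np.ndarray) -> np.ndarray:
    if isinstance(blocks, np.ndarray):
        return blocks.astype(F32, copy=False)
    return np.stack([b.data for b in blocks]).astype(F32)


def train(model: ModelHandle,
          blocks: list[FrameBlock] | np.ndarray,
          labels: np.ndarray,
          val_blocks: list[FrameBlock] | np.ndarray | None = None,
          val_labels: np.ndarray | None = None,
          config: ModelConfig | None = None) -> ModelHandle:
    """Train ``model`` in place by Adam on binary cross-entropy.

    The seed fixes shuffling (initialisation was fixed at construction);
    per-epoch training and validation losses land in ``model.history``.
    Early stopping watches validation loss when a validation set is given.
    """
    cfg = config or model.config
    x = _stack_blocks(blocks)
    y = np.asarray(labels, dtype=F32).ravel()
    if len(x) != len(y):
        raise TrainingError(f"{len(x)} blocks but {len(y)} labels")
    if len(np.unique(y)) < 2:
        raise TrainingError("training set must contain both classes")
    xv = _stack_blocks(val_blocks) if val_blocks is not None else None
    yv = np.asarray(val_labels, dtype=F32).ravel() if val_labels is not None else None

    opt = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    best_val, patience_left = np.inf, cfg.early_stopping_patience
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(x), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            logits = model.forward_logits(x[idx], train=True)
            loss, dlogits = bce_with_logits(logits, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model._backward(dlogits, len(idx))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.history["train_loss"].append(epoch_loss / n_batches)
        if xv is not None:
            vlogits = np.concatenate([
                model.forward_logits(xv[s:s + 64], train=False)
                for s in range(0, len(xv), 64)
            ])
            vloss, _ = bce_with_logits(vlogits, yv)
            model.history["val_loss"].append(vloss)
            if vloss < best_val - 1e-5:
                best_val, patience_left = vloss, cfg.early_stopping_patience
            elif epoch + 1 >= cfg.early_stopping_min_epochs:
                # eval-mode val loss is unreliable while batch-norm running
                # statistics are still settling; never stop during warm-up
                patience_left -= 1
                if patience_left <= 0:
                    break
    model.trained = True
    return model


def predict(model: ModelHandle,
            blocks: list[FrameBlock] | np.ndarray,
            threshold: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(probabilities, 0/1 calls); a probability equal to the threshold is positive."""
    thr = model.config.threshold if threshold is None else threshold
    probs = model.predict_proba(_stack_blocks(blocks))
    return probs, (probs >= thr).astype(int)


def multilabel_predict(models: dict[str, ModelHandle],
                       blocks: list[FrameBlock] | np.ndarray,
                       vocabulary: tuple[str, ...] | None = None,
                       threshold: float | None = None) -> list[set[str]]:
    """Binary-relevance union: each record's label set is every class whose
    binary model calls positive.  Empty sets are legal."""
    classes = tuple(vocabulary) if vocabulary is not None else tuple(models)
    missing = [c for c in classes if c not in models]
    if missing:
        raise KeyError(f"no trained model for class(es) {missing}")
    x = _stack_blocks(blocks)
    out: list[set[str]] = [set() for _ in range(len(x))]
    for cls in classes:
        _, calls = predict(models[cls], x, threshold)
        for i, call in enumerate(calls):
            if call:
                out[i].add(cls)
    return out
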