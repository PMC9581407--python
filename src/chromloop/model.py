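"""The two-channel convolutional loop classifier and its training protocol.

Architecture: three blocks of [3x3 convolution -> batch norm -> ReLU ->
dropout 0.2] over the 2-channel w x w input (w = 23 by default), one global
average pooling collapsing each final feature map to a scalar, then two
64-unit dense layers (each batch-normalized with ReLU) and a single sigmoid
output giving the loop probability. Trained with mean binary cross-entropy
under Adam (lr 0.001, batch 128), with per-epoch validation PRAUC used for
best-checkpoint selection and early stopping.

Chromosome-level splits follow the leave-one-chromosome-out protocol: one
chromosome is held out entirely for testing, and the rest are partitioned
80/20 (by chromosome, not by window) into training and validation sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score

from . import nn
from .samples import SampleWindow

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LoopClassifier",
    "init_model",
    "bce_loss",
    "loco_split",
    "train",
    "predict",
]

NORMALIZATION_ID = "log10p1-unitmax-per-window"

_PROB_EPS = 1e-7


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Default kernels (9, 9, 7) with valid (unpadded) convolutions shrink the
    23 x 23 window to a 1 x 1 final feature map (23 -> 15 -> 7 -> 1), making
    the classifier center-referenced: a loop signature is only recognized
    when centered on the scored pixel, which is what lets pooled candidate
    clusters resolve to the true loop pixel. ``padding="same"`` restores
    shape-preserving convolutions for experimentation.
    """

    window_size: int = 23
    in_channels: int = 2
    filters: tuple[int, int, int] = (32, 64, 128)
    kernels: tuple[int, int, int] = (9, 9, 7)
    padding: str = "valid"
    dropout: float = 0.2
    fc_width: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        self.filters = tuple(self.filters)
        self.kernels = tuple(self.kernels)
        if len(self.filters) != 3 or len(self.kernels) != 3:
            raise ValueError("exactly three convolutional blocks are required")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.window_size % 2 != 1 or self.window_size < 3:
            raise ValueError("window_size must be an odd integer >= 3")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        if self.padding == "valid":
            size = self.window_size
            for k in self.kernels:
                size = size - k + 1
            if size < 1:
                raise ValueError(
                    f"kernels {self.kernels} exhaust the {self.window_size}-bin window"
                )


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 128
    max_epochs: int = 30
    patience: int = 5
    val_fraction: float = 0.2
    test_chrom: str | None = None
    # exponential moving average of weights; the averaged model is what gets
    # validated and checkpointed (0 evaluates the raw weights instead)
    ema_decay: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class LoopClassifier:
    """Trained (or trainable) CNN; holds config, layers, and training history."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.normalization = NORMALIZATION_ID
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        c = config
        chans = (c.in_channels,) + c.filters
        pad = 0 if c.padding == "valid" else None
        layers = []
        for b in range(3):
            layers += [
                nn.Conv2d(chans[b], chans[b + 1], c.kernels[b], rng, pad=pad),
                nn.BatchNorm2d(chans[b + 1]),
                nn.ReLU(),
                nn.Dropout(c.dropout),
            ]
        layers.append(nn.GlobalAvgPool())
        layers += [
            nn.Dense(c.filters[-1], c.fc_width, rng),
            nn.BatchNorm1d(c.fc_width),
            nn.ReLU(),
            nn.Dense(c.fc_width, c.fc_width, rng),
            nn.BatchNorm1d(c.fc_width),
            nn.ReLU(),
            nn.Dense(c.fc_width, 1, rng),
        ]
        self.layers = layers

    # -- forward / predict --------------------------------------------------

    def forward_logits(self, x: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        # convolutional stack runs channels-last internally
        out = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1)
        )
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        dout = dlogits.astype(np.float32)[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)



    def update_bn_stats(self, x: np.ndarray, max_samples: int = 4096) -> None:
        """Recompute batch-norm population statistics with dropout disabled
        (one clean pass over up to ``max_samples`` windows).

        Batch statistics collected during training are taken downstream of
        active dropout, whose noise inflates them relative to inference-time
        activations; with small datasets that miscalibrates the network.
        """
        x = np.asarray(x[:max_samples], dtype=np.float32)
        out = np.ascontiguousarray(x.transpose(0, 2, 3, 1))
        for layer in self.layers:
            if isinstance(layer, nn._BatchNorm):
                saved = layer.momentum
                layer.momentum = 1.0
                out = layer.forward(out, train=True)
                layer.momentum = saved
            else:
                out = layer.forward(out, train=False)

    def predict_array(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Probabilities for a (N, 2, w, w) array, inference mode, batched."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels or \
                x.shape[2] != self.config.window_size or x.shape[3] != self.config.window_size:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, {self.config.window_size}, "
                f"{self.config.window_size}) windows, got {x.shape}"
            )
        probs = np.empty(len(x), dtype=np.float64)
        for s in range(0, len(x), batch_size):
            z = self.forward_logits(x[s : s + batch_size], train=False)
            probs[s : s + batch_size] = nn.sigmoid(z)
        return np.clip(probs, _PROB_EPS, 1 - _PROB_EPS)

    # -- bookkeeping ---------------------------------------------------------

    def parameter_count(self) -> int:
        return sum(int(p.size) for l in self.layers for p in l.params.values())

    def _state(self) -> list[dict]:
        state = []
        for l in self.layers:
            d = {k: v.copy() for k, v in l.params.items()}
            if isinstance(l, nn._BatchNorm):
                d["running_mean"] = l.running_mean.copy()
                d["running_var"] = l.running_var.copy()
            state.append(d)
        return state

    def _load_state(self, state: list[dict]) -> None:
        for l, d in zip(self.layers, state):
            for k in l.params:
                l.params[k] = d[k].copy()
            if isinstance(l, nn._BatchNorm):
                l.running_mean = d["running_mean"].copy()
                l.running_var = d["running_var"].copy()

    def save(self, path: str) -> None:
        """Single-file checkpoint: parameters + config + normalization id + history."""
        arrays = {}
        for li, d in enumerate(self._state()):
            for k, v in d.items():
                arrays[f"layer{li}.{k}"] = v
        meta = json.dumps({
            "config": asdict(self.config),
            "normalization": self.normalization,
            "history": self.history,
        })
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "LoopClassifier":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg = ModelConfig(**{**meta["config"],
                                 "filters": tuple(meta["config"]["filters"]),
                                 "kernels": tuple(meta["config"]["kernels"])})
            model = cls(cfg)
            model.normalization = meta["normalization"]
            model.history = meta["history"]
            state: list[dict] = [dict() for _ in model.layers]
            for key in z.files:
                if key == "__meta__":
                    continue
                li, name = key.split(".", 1)
                state[int(li[5:])][name] = z[key]
            model._load_state(state)
        return model


def init_model(config: ModelConfig) -> LoopClassifier:
    """Untrained classifier with deterministic (seeded) initialization."""
    return LoopClassifier(config)


def bce_loss(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean binary cross-entropy, natural log; predictions are clamped to
    [1e-7, 1 - 1e-7] away from the boundaries."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(predictions, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    p = np.clip(p, _PROB_EPS, 1 - _PROB_EPS)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))


def loco_split(
    chromosomes: list[str],
    test_chrom: str,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Leave-one-chromosome-out split: (train, validation, test) chromosome lists.

    The test set is exactly ``{test_chrom}``; the remaining chromosomes are
    shuffled by ``seed`` and ``round(val_fraction * m)`` of them go to
    validation (floored at one whenever at least two remain, so training
    always has a validation signal), the rest to training.
    """
    if test_chrom not in chromosomes:
        raise ValueError(f"test chromosome {test_chrom!r} not among {chromosomes}")
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    rest = [c for c in chromosomes if c != test_chrom]
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(rest)))
    rest = [rest[k] for k in order]
    m = len(rest)
    n_val = int(round(val_fraction * m))
    if m >= 2:
        n_val = min(max(1, n_val), m - 1)
    return rest[n_val:], rest[:n_val], [test_chrom]


def _stack(windows: list[SampleWindow]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.stacked() for s in windows]).astype(np.float32)
    y = np.array([s.label for s in windows], dtype=np.float64)
    return x, y


def train(
    model: LoopClassifier,
    train_windows: list[SampleWindow],
    val_windows: list[SampleWindow],
    tc: TrainConfig,
) -> LoopClassifier:
    """Minimize BCE with Adam; keep the epoch with the best validation PRAUC
    (ties broken by lower validation loss).

    Shuffles each epoch with a ``tc.seed``-derived generator; stops at
    ``tc.max_epochs`` or after ``tc.patience`` epochs without validation
    improvement; records per-epoch train/validation loss and validation PRAUC
    in ``model.history``. The validated (and finally returned) parameters are
    an exponential moving average of the per-epoch weights, which smooths the
    decision boundary when epochs are only a few optimizer steps; batch-norm
    statistics are recomputed with dropout disabled before every validation
    pass.
    """
    if not train_windows or not val_windows:
        raise ValueError("training and validation sets must be non-empty")
    xt, yt = _stack(train_windows)
    xv, yv = _stack(val_windows)
    if len(np.unique(yt)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.layers, lr=tc.learning_rate)
    best_key, best_state, best_epoch, since_best = None, None, -1, 0
    ema: list[dict] | None = None
    model.history = []

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(xt))
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(xt), tc.batch_size):
            idx = order[s : s + tc.batch_size]
            z = model.forward_logits(xt[idx], train=True, rng=rng)
            epoch_loss += nn.bce_with_logits(z, yt[idx])
            model.backward(nn.bce_with_logits_grad(z, yt[idx]))
            opt.step()
            n_batches += 1

        raw_state = model._state()
        if tc.ema_decay > 0:
            if ema is None:
                ema = [{k: v.copy() for k, v in d.items()} for d in raw_state]
            else:
                a = tc.ema_decay
                for de, dr in zip(ema, raw_state):
                    for k in de:
                        de[k] = (a * de[k] + (1 - a) * dr[k]).astype(dr[k].dtype)
            model._load_state(ema)
        model.update_bn_stats(xt)
        pv = model.predict_array(xv)
        val_loss = bce_loss(yv, pv)
        val_prauc = float(average_precision_score(yv, pv))
        eval_state = model._state()  # EMA weights + recalibrated BN stats
        if tc.ema_decay > 0:
            model._load_state(raw_state)  # resume optimization from raw weights

        model.history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n_batches,
            "val_loss": val_loss,
            "val_prauc": val_prauc,
        })
        key = (val_prauc, -val_loss)
        if best_key is None or key > best_key:
            best_key, best_state, best_epoch, since_best = key, eval_state, epoch, 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break

    model._load_state(best_state)
    model.best_epoch = best_epoch
    model.best_val_prauc = best_key[0]
    return model


def predict(model: LoopClassifier, windows: list[SampleWindow]) -> np.ndarray:
    """One probability in (0, 1) per window (inference mode, deterministic)."""
    if not windows:
        return np.zeros(0)
    for s in windows:
        if s.w != model.config.window_size:
            raise ValueError(f"window size {s.w} != model's {model.config.window_size}")
    x, _ = _stack(windows)
    return model.predict_array(x)
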