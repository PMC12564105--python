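"""CA-SeqNet: channel-attention 1-D convolutional artifact classifier.

The backbone is seven repeated (Conv1d -> BatchNorm1d -> ReLU -> MaxPool1d)
units whose channel widths follow the first three blocks of the classic
16-layer deep CNN (64, 64, 128, 128, 256, 256, 256; kernel 3, same
padding, pool 2).  A GAP+GMP channel-attention gate rescales the final
feature map, and two FC-ReLU-dropout units plus a linear layer produce
softmax probabilities over the three classes (0 cardiac, 1 blink,
2 non-artifact).

Training follows a fixed recipe: Adam at 1e-3 with the learning rate
multiplied by 0.1 every 10 epochs, batch size 16, multiclass
cross-entropy, and a single master seed (default 42) driving weight
initialization, batch shuffling and dropout, so runs are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .preprocessing import ICADecomposition

LABEL_CARDIAC = 0
LABEL_BLINK = 1
LABEL_NONE = 2


@dataclass
class ModelConfig:
    input_length: int = 10_000
    conv_channels: tuple = (64, 64, 128, 128, 256, 256, 256)
    kernel_size: int = 3
    pool_size: int = 2
    frd_hidden: tuple = (256, 64)
    dropout_rate: float = 0.5
    n_classes: int = 3

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 7:
            raise ValueError("the backbone is defined as seven conv units")
        if self.n_classes != 3:
            raise ValueError("the classifier distinguishes exactly 3 classes")

    @property
    def feature_length(self) -> int:
        L = self.input_length
        for _ in self.conv_channels:
            L //= self.pool_size
        return L


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 16
    lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 10
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "lr", "lr_decay_factor", "lr_decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class CASeqNet:
    """The classifier network (forward/backward over the layer stack)."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 42):
        self.config = config or ModelConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 1])
        )
        cfg = self.config
        self.layers: list[nn.Layer] = []
        cin = 1
        for cout in cfg.conv_channels:
            self.layers += [
                nn.Conv1d(cin, cout, cfg.kernel_size, rng),
                nn.BatchNorm1d(cout),
                nn.ReLU(),
                nn.MaxPool1d(cfg.pool_size),
            ]
            cin = cout
        self.attention = nn.ChannelAttention(cin, rng)
        self.layers.append(self.attention)
        self.layers.append(nn.Flatten())
        fan = cin * cfg.feature_length
        for hidden in cfg.frd_hidden:
            self.layers += [
                nn.Dense(fan, hidden, rng),
                nn.ReLU(),
                nn.Dropout(cfg.dropout_rate, self._dropout_rng),
            ]
            fan = hidden
        self.layers.append(nn.Dense(fan, cfg.n_classes, rng))

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Class probabilities for a batch.

        ``x`` may be ``(batch, input_length)`` or a single series of
        ``input_length`` points; inputs are expected standardized (zero
        mean, unit variance per waveform).
        """
        x = np.asarray(x, dtype=nn.DTYPE)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected input length {self.config.input_length}, got {x.shape[1]}"
            )
        out = x[:, :, None]  # channels-last: (batch, length, 1)
        for layer in self.layers:
            out = layer.forward(out, train)
        probs = nn.softmax(out)
        return probs[0] if single else probs

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Argmax class labels in inference mode (deterministic)."""
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        labels = []
        for start in range(0, x.shape[0], batch_size):
            probs = self.forward(x[start : start + batch_size], train=False)
            labels.append(np.argmax(probs, axis=1))
        return np.concatenate(labels)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        bn_state = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, nn.BatchNorm1d):
                bn_state[f"rm{i}"] = layer.running_mean
                bn_state[f"rv{i}"] = layer.running_var
        meta = json.dumps({"config": asdict(self.config), "seed": self.seed})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays, **bn_state)

    @classmethod
    def load(cls, path) -> "CASeqNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = meta["config"]
            cfg["conv_channels"] = tuple(cfg["conv_channels"])
            cfg["frd_hidden"] = tuple(cfg["frd_hidden"])
            model = cls(ModelConfig(**cfg), seed=meta["seed"])
            for i, p in enumerate(model.params()):
                p[...] = data[f"p{i}"]
            for i, layer in enumerate(model.layers):
                if isinstance(layer, nn.BatchNorm1d):
                    layer.running_mean[...] = data[f"rm{i}"]
                    layer.running_var[...] = data[f"rv{i}"]
        return model


def standardize(waveforms: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance scaling of each waveform."""
    w = np.asarray(waveforms, dtype=np.float64)
    single = w.ndim == 1
    if single:
        w = w[None, :]
    mean = w.mean(axis=1, keepdims=True)
    std = w.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    out = (w - mean) / std
    return out[0] if single else out


@dataclass
class TrainedModel:
    """A trained network plus its configs and per-epoch history."""

    network: CASeqNet
    model_config: ModelConfig
    train_config: TrainConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict(x)


def evaluate_loss_accuracy(
    model: CASeqNet, waveforms: np.ndarray, labels: np.ndarray,
    batch_size: int = 64,
) -> tuple[float, float]:
    """Inference-mode mean cross-entropy and accuracy on a labeled set."""
    losses, correct = [], 0
    for start in range(0, waveforms.shape[0], batch_size):
        xb = waveforms[start : start + batch_size]
        yb = labels[start : start + batch_size]
        probs = model.forward(xb, train=False)
        losses.append(nn.cross_entropy(probs, yb) * len(yb))
        correct += int((np.argmax(probs, axis=1) == yb).sum())
    n = waveforms.shape[0]
    return float(np.sum(losses) / n), correct / n


def train(
    train_waveforms: np.ndarray,
    train_labels: np.ndarray,
    test_waveforms: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train the classifier with the fixed recipe.

    Waveforms are standardized internally.  The returned history has one
    row per epoch with the learning rate, mean training loss and (when a
    test set is given) inference-mode test loss/accuracy.
    """
    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    Xtr = standardize(train_waveforms).astype(nn.DTYPE)
    ytr = np.asarray(train_labels, dtype=np.int64)
    has_test = test_waveforms is not None
    if has_test:
        Xte = standardize(test_waveforms).astype(nn.DTYPE)
        yte = np.asarray(test_labels, dtype=np.int64)

    model = CASeqNet(mc, seed=tc.seed)
    optimizer = nn.Adam(model.params(), lr=tc.lr)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 2]))

    records = []
    n = Xtr.shape[0]
    for epoch in range(tc.epochs):
        optimizer.lr = tc.lr * tc.lr_decay_factor ** (epoch // tc.lr_decay_every)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            probs = model.forward(xb, train=True)
            loss = nn.cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf training loss at epoch {epoch}, batch {start // tc.batch_size}"
                )
            epoch_loss += loss * len(yb)
            model.backward(nn.cross_entropy_grad(probs, yb))
            optimizer.step(model.grads())
        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "train_loss": epoch_loss / n,
        }
        if has_test:
            te_loss, te_acc = evaluate_loss_accuracy(model, Xte, yte)
            record["test_loss"] = te_loss
            record["test_accuracy"] = te_acc
        records.append(record)
        if verbose:
            print(
                "  ".join(f"{k}={v:.4g}" if k != "epoch" else f"epoch={v}"
                          for k, v in record.items())
            )
    return TrainedModel(model, mc, tc, pd.DataFrame(records))


def predict_components(
    model: TrainedModel | CASeqNet, decomposition: ICADecomposition
) -> tuple[np.ndarray, list[int]]:
    """Classify every component of a decomposition.

    Source waveforms are standardized and, if longer than the model input,
    stride-subsampled to fit (valid for the band-limited pipeline).
    Returns ``(labels, flagged)`` where ``flagged`` lists the component
    indices predicted cardiac (0) or blink (1), i.e. marked for removal.
    """
    net = model.network if isinstance(model, TrainedModel) else model
    sources = decomposition.sources
    L = net.config.input_length
    if sources.shape[1] != L:
        if sources.shape[1] % L:
            raise ValueError(
                f"component length {sources.shape[1]} is not a multiple of "
                f"the model input length {L}"
            )
        sources = sources[:, :: sources.shape[1] // L]
    labels = net.predict(standardize(sources))
    flagged = [i for i, lab in enumerate(labels) if lab in (LABEL_CARDIAC, LABEL_BLINK)]
    return labels, flagged
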