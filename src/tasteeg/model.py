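"""Three-branch 1-D convolutional classifier and an FFT band-power baseline.

The network runs three parallel convolution + max-pool + dropout branches
over the same raw window (three temporal scales), concatenates the
flattened branch outputs, and feeds them through a small dense head
(default 20 -> 16 -> 16 -> 64) to a softmax over the four stimulus
classes.  Training uses Adam with categorical cross-entropy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import DataSplit, WindowMatrix

__all__ = [
    "BranchSpec",
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "bandpower_baseline",
    "save_model",
    "load_model",
]


class ModelError(ValueError):
    """Raised for invalid model configuration or inputs."""


@dataclass(frozen=True)
class BranchSpec:
    """One convolutional branch: conv -> max-pool -> dropout."""

    n_filters: int = 16
    kernel_len: int = 15
    pool_len: int = 4
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.kernel_len < 1 or self.pool_len < 1 or self.n_filters < 1:
            raise ModelError(f"invalid branch spec {self}")
        if not (0 <= self.dropout < 1):
            raise ModelError(f"dropout must be in [0, 1), got {self.dropout}")


#: three temporal scales; kernel lengths are a documented guess and are
#: exposed here as ordinary configuration
DEFAULT_BRANCHES = (
    BranchSpec(n_filters=16, kernel_len=7, pool_len=4, dropout=0.2),
    BranchSpec(n_filters=16, kernel_len=15, pool_len=4, dropout=0.2),
    BranchSpec(n_filters=16, kernel_len=31, pool_len=4, dropout=0.2),
)


@dataclass(frozen=True)
class ModelConfig:
    branches: tuple[BranchSpec, ...] = DEFAULT_BRANCHES
    dense_sizes: tuple[int, ...] = (20, 16, 16, 64)
    dense_dropout: float = 0.2
    n_classes: int = 4
    input_shape: tuple[int, int] = (1028, 2)  # (window_len, n_channels)

    def __post_init__(self) -> None:
        if len(self.branches) != 3:
            raise ModelError(
                f"exactly 3 branches required, got {len(self.branches)}"
            )
        if not self.dense_sizes:
            raise ModelError("dense_sizes must be nonempty")
        if not (0 <= self.dense_dropout < 1):
            raise ModelError(f"dense_dropout must be in [0, 1)")
        window_len = self.input_shape[0]
        for b in self.branches:
            if b.kernel_len > window_len:
                raise ModelError(
                    f"branch kernel {b.kernel_len} longer than input {window_len}"
                )


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    seed: int = 0
    early_stopping: bool = False
    patience: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ModelError("epochs and batch_size must be >= 1")


class ThreeBranchNet:
    """Parallel branches over a shared input, concatenated into a dense head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        window_len, n_channels = config.input_shape
        self.branches: list[nn.Sequential] = []
        branch_widths: list[int] = []
        for spec in config.branches:
            conv_out = window_len - spec.kernel_len + 1
            pooled = conv_out // spec.pool_len
            if pooled < 1:
                raise ModelError(f"branch {spec} collapses the input to length 0")
            self.branches.append(
                nn.Sequential([
                    nn.Conv1D(n_channels, spec.n_filters, spec.kernel_len, rng),
                    nn.LeakyReLU(),
                    nn.MaxPool1D(spec.pool_len),
                    nn.Dropout(spec.dropout, rng),
                    nn.Flatten(),
                ])
            )
            branch_widths.append(pooled * spec.n_filters)
        self._branch_widths = branch_widths
        head_layers: list[nn.Layer] = []
        prev = sum(branch_widths)
        for size in config.dense_sizes:
            head_layers += [nn.Dense(prev, size, rng), nn.LeakyReLU(),
                            nn.Dropout(config.dense_dropout, rng)]
            prev = size
        head_layers.append(nn.Dense(prev, config.n_classes, rng))
        self.head = nn.Sequential(head_layers)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        feats = [b.forward(x, training) for b in self.branches]
        return self.head.forward(np.concatenate(feats, axis=1), training)

    def backward(self, grad: np.ndarray) -> None:
        gcat = self.head.backward(grad)
        offset = 0
        for branch, width in zip(self.branches, self._branch_widths):
            branch.backward(gcat[:, offset : offset + width])
            offset += width

    def params(self) -> list[np.ndarray]:
        out = []
        for b in self.branches:
            out.extend(b.params())
        out.extend(self.head.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for b in self.branches:
            out.extend(b.grads())
        out.extend(self.head.grads())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params())


def build_model(config: ModelConfig, seed: int = 0) -> ThreeBranchNet:
    """Instantiate an untrained network with seeded Glorot initialization."""
    return ThreeBranchNet(config, np.random.default_rng(seed))


@dataclass
class TrainedModel:
    net: ThreeBranchNet
    config: ModelConfig
    class_order: tuple[str, ...]
    history: list[dict] = field(default_factory=list)


def _onehot(labels: np.ndarray, class_order: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    try:
        rows = np.array([index[l] for l in labels])
    except KeyError as exc:
        raise ModelError(f"label {exc.args[0]!r} not in class order {class_order}")
    out = np.zeros((len(labels), len(class_order)), dtype=np.float32)
    out[np.arange(len(labels)), rows] = 1.0
    return out


def _forward_in_batches(net: ThreeBranchNet, x: np.ndarray,
                        batch_size: int = 256) -> np.ndarray:
    chunks = [net.forward(x[i : i + batch_size], training=False)
              for i in range(0, len(x), batch_size)]
    return np.concatenate(chunks, axis=0) if chunks else np.zeros((0, net.config.n_classes))


def train(model: ThreeBranchNet, split: DataSplit, tc: TrainConfig) -> TrainedModel:
    """Train with Adam + categorical cross-entropy; the test side of the
    split serves as the per-epoch validation set in the history."""
    wm = split.train
    if len(wm) == 0:
        raise ModelError("empty training set")
    class_order = tuple(wm.class_order)
    if len(class_order) != model.config.n_classes:
        raise ModelError(
            f"split has {len(class_order)} classes but model expects "
            f"{model.config.n_classes}"
        )
    x = np.ascontiguousarray(wm.windows, dtype=np.float32)
    y = _onehot(wm.labels, class_order)
    x_val = np.ascontiguousarray(split.test.windows, dtype=np.float32)
    y_val = _onehot(split.test.labels, class_order) if len(split.test) else None

    rng = np.random.default_rng(tc.seed)
    optimizer = nn.Adam(model.params(), lr=tc.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    stall = 0
    for epoch in range(tc.epochs):
        order = rng.permutation(len(x))
        losses, hits, seen = [], 0, 0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i : i + tc.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            optimizer.step(model.grads())
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == y[idx].argmax(axis=1)).sum())
            seen += len(idx)
        entry = {
            "epoch": epoch,
            "train_loss": float(np.sum(losses) / seen),
            "train_acc": hits / seen,
        }
        if y_val is not None:
            val_logits = _forward_in_batches(model, x_val)
            val_loss, _ = nn.softmax_cross_entropy(val_logits, y_val)
            entry["val_loss"] = val_loss
            entry["val_acc"] = float(
                (val_logits.argmax(axis=1) == y_val.argmax(axis=1)).mean()
            )
        history.append(entry)
        if tc.early_stopping and y_val is not None:
            if entry["val_loss"] < best_val - 1e-6:
                best_val = entry["val_loss"]
                stall = 0
            else:
                stall += 1
                if stall >= tc.patience:
                    break
    return TrainedModel(net=model, config=model.config,
                        class_order=class_order, history=history)


def predict(tm: TrainedModel, wm: WindowMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and softmax probabilities (dropout off)."""
    if len(wm) == 0:
        return np.array([], dtype=object), np.zeros((0, tm.config.n_classes))
    expected = tm.config.input_shape
    got = wm.windows.shape[1:]
    if tuple(got) != tuple(expected):
        raise ModelError(f"window shape {got} does not match model input {expected}")
    logits = _forward_in_batches(tm.net, np.ascontiguousarray(wm.windows, dtype=np.float32))
    probs = nn.softmax(logits)
    labels = np.array([tm.class_order[i] for i in probs.argmax(axis=1)])
    return labels, probs


# ---------------------------------------------------------------------------
# FFT band-power baseline
# ---------------------------------------------------------------------------

def _bandpower_features(windows: np.ndarray, fs: float,
                        bands: list[tuple[float, float]]) -> np.ndarray:
    """log10 mean periodogram power per (band, channel) for each window."""
    n = windows.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectra = np.abs(np.fft.rfft(windows, axis=1)) ** 2  # (n_windows, n_freq, n_ch)
    feats = []
    for low, high in bands:
        mask = (freqs >= low) & (freqs <= high)
        if not mask.any():
            raise ModelError(f"band ({low}, {high}) Hz contains no FFT bins")
        feats.append(spectra[:, mask, :].mean(axis=1))
    return np.log10(np.concatenate(feats, axis=1) + 1e-12)


def bandpower_baseline(split: DataSplit, bands: list[tuple[float, float]],
                       fs: float = 512.0, seed: int = 0):
    """Multinomial logistic regression on FFT band-power features.

    Returns the same MetricsReport type as the CNN path, for side-by-side
    comparison of learned versus handcrafted spectral features.
    """
    from sklearn.linear_model import LogisticRegression

    from .evaluation import confusion, metrics

    if not bands:
        raise ModelError("band list must be nonempty")
    for low, high in bands:
        if not (0 < low < high < fs / 2):
            raise ModelError(f"band ({low}, {high}) Hz outside (0, {fs / 2})")
    x_train = _bandpower_features(split.train.windows, fs, bands)
    x_test = _bandpower_features(split.test.windows, fs, bands)
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(x_train, split.train.labels)
    predicted = clf.predict(x_test)
    cm = confusion(split.test.labels, predicted, split.train.class_order)
    return metrics(cm)


# ---------------------------------------------------------------------------
# persistence: npz weights + JSON sidecar
# ---------------------------------------------------------------------------

def save_model(tm: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{f"p{i}": p for i, p in enumerate(tm.net.params())})
    sidecar = {
        "class_order": list(tm.class_order),
        "input_shape": list(tm.config.input_shape),
        "dense_sizes": list(tm.config.dense_sizes),
        "dense_dropout": tm.config.dense_dropout,
        "n_classes": tm.config.n_classes,
        "branches": [
            {"n_filters": b.n_filters, "kernel_len": b.kernel_len,
             "pool_len": b.pool_len, "dropout": b.dropout}
            for b in tm.config.branches
        ],
        "history": tm.history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(
        branches=tuple(BranchSpec(**b) for b in sidecar["branches"]),
        dense_sizes=tuple(sidecar["dense_sizes"]),
        dense_dropout=sidecar["dense_dropout"],
        n_classes=sidecar["n_classes"],
        input_shape=tuple(sidecar["input_shape"]),
    )
    net = build_model(config)
    weights = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(net.params()):
        p[...] = weights[f"p{i}"]
    return TrainedModel(net=net, config=config,
                        class_order=tuple(sidecar["class_order"]),
                        history=sidecar["history"])
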