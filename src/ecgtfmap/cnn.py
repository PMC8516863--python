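"""The 2D CNN rhythm classifier over 120 x 120 time-frequency maps.

Architecture (four convolutional groups, then a softmax dense head):

====== ======= ======= ====== ===== =======
group  filters kernel  stride pool  dropout
====== ======= ======= ====== ===== =======
1      128     3 x 3   1      2x2   0.5
2      64      3 x 3   1      2x2   0.5
3      32      2 x 2   1      2x2   0.3
4      16      2 x 2   2      --    0.3
====== ======= ======= ====== ===== =======

Each group is conv → batch-norm → ReLU (→ max-pool) → dropout, with "same"
padding and L2 regularisation (lambda 1.5e-4) on every conv kernel and
bias. Training uses sparse categorical cross-entropy and Adam at learning
rate 0.01 for a fixed number of epochs (no early stopping by default), with
a stratified 80/20 train/test split and k-fold cross-validation (default 5)
over the training portion; the fold with the lowest validation loss is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .features import MAP_SIZE, TimeFrequencyMap
from .io import CLASSES


@dataclass
class ConvGroupSpec:
    filters: int
    kernel: tuple[int, int]
    stride: tuple[int, int] = (1, 1)
    pool: tuple[int, int] | None = (2, 2)
    dropout: float = 0.5


def default_conv_groups() -> list[ConvGroupSpec]:
    return [
        ConvGroupSpec(128, (3, 3), (1, 1), (2, 2), 0.5),
        ConvGroupSpec(64, (3, 3), (1, 1), (2, 2), 0.5),
        ConvGroupSpec(32, (2, 2), (1, 1), (2, 2), 0.3),
        ConvGroupSpec(16, (2, 2), (2, 2), None, 0.3),
    ]


@dataclass
class CnnConfig:
    conv_groups: list[ConvGroupSpec] = field(default_factory=default_conv_groups)
    hidden_dense: list[int] = field(default_factory=list)  # optional extra head
    batch_norm: bool = True
    l2_lambda: float = 0.00015
    n_classes: int = 9
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 32
    input_size: int = MAP_SIZE
    seed: int = 0


@dataclass
class TrainedModel:
    """Layer graph plus learned parameters, class table and history."""

    config: CnnConfig
    net: nn.Sequential
    class_names: list[str] = field(default_factory=lambda: list(CLASSES))
    history: dict = field(default_factory=dict)
    test_indices: np.ndarray | None = None

    def n_params(self) -> int:
        return self.net.n_params()


def _spatial_out(size: int, stride: int, pool: int | None) -> int:
    out = -(-size // stride)  # "same" padding: ceil(size / stride)
    if pool:
        out //= pool
    return out


def expected_param_count(config: CnnConfig) -> int:
    """Closed-form trainable-parameter count from layer arithmetic."""
    total = 0
    c_in = 1
    size = config.input_size
    for g in config.conv_groups:
        kh, kw = g.kernel
        total += kh * kw * c_in * g.filters + g.filters       # conv w + b
        if config.batch_norm:
            total += 2 * g.filters                            # gamma, beta
        size = _spatial_out(size, g.stride[0], g.pool[0] if g.pool else None)
        c_in = g.filters
    d_in = size * size * c_in
    for width in config.hidden_dense:
        total += d_in * width + width
        d_in = width
    total += d_in * config.n_classes + config.n_classes
    return total


def build_model(config: CnnConfig | None = None) -> TrainedModel:
    """Assemble the (untrained) layer graph for 120 x 120 x 1 inputs."""
    config = config or CnnConfig()
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    c_in = 1
    for g in config.conv_groups:
        layers.append(nn.Conv2D(c_in, g.filters, g.kernel, g.stride,
                                l2=config.l2_lambda, rng=rng))
        if config.batch_norm:
            layers.append(nn.BatchNorm(g.filters))
        layers.append(nn.ReLU())
        if g.pool:
            layers.append(nn.MaxPool2x2())
        layers.append(nn.Dropout(g.dropout, rng))
        c_in = g.filters
    layers.append(nn.Flatten())
    size = config.input_size
    for g in config.conv_groups:
        size = _spatial_out(size, g.stride[0], g.pool[0] if g.pool else None)
    d_in = size * size * c_in
    for width in config.hidden_dense:
        layers.append(nn.Dense(d_in, width, rng))
        layers.append(nn.ReLU())
        d_in = width
    layers.append(nn.Dense(d_in, config.n_classes, rng))
    net = nn.Sequential(layers)
    class_names = list(CLASSES)[: config.n_classes] \
        if config.n_classes <= len(CLASSES) else \
        [f"class{i}" for i in range(config.n_classes)]
    return TrainedModel(config=config, net=net, class_names=class_names)


def _as_batch(maps, size: int = MAP_SIZE) -> np.ndarray:
    arrs = [np.asarray(getattr(m, "values", m), dtype=np.float32) for m in maps]
    x = np.stack(arrs)
    if x.shape[1:] != (size, size):
        raise ValueError(f"expected {size}x{size} maps, got {x.shape[1:]}")
    return x[..., None]


def predict(model: TrainedModel, tf_map: TimeFrequencyMap | np.ndarray
            ) -> np.ndarray:
    """Class-probability vector for one map (softmax output, sums to 1)."""
    return predict_proba(model, [tf_map])[0]


def predict_proba(model: TrainedModel, maps) -> np.ndarray:
    x = _as_batch(maps, model.config.input_size)
    logits = model.net.forward(x, training=False)
    return nn.softmax(logits.astype(np.float64))


def _run_epochs(model: TrainedModel, x: np.ndarray, y: np.ndarray,
                epochs: int, rng: np.random.Generator) -> list[float]:
    cfg = model.config
    opt = nn.Adam(model.net.params, model.net.grads, lr=cfg.learning_rate)
    losses = []
    n = x.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            logits = model.net.forward(x[sel], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[sel])
            model.net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(sel)
        losses.append(epoch_loss / n + model.net.reg_loss())
    return losses


def evaluate_loss_acc(model: TrainedModel, x: np.ndarray, y: np.ndarray
                      ) -> tuple[float, float]:
    logits = model.net.forward(x, training=False)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    acc = float(np.mean(np.argmax(logits, axis=1) == y))
    return loss, acc


def train(model: TrainedModel, maps, labels, split_seed: int = 0,
          folds: int = 5, epochs: int | None = None) -> TrainedModel:
    """Stratified 80/20 split + k-fold CV; keep the best fold by val loss.

    ``labels`` may be class names or integer indices. The 20 % test portion
    is never touched during training; its indices are stored on the model
    for downstream evaluation.
    """
    if folds < 2:
        raise ValueError(f"k-fold cross-validation needs folds >= 2, got {folds}")
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    x = _as_batch(maps, cfg.input_size)
    y = np.asarray([model.class_names.index(lab) if isinstance(lab, str) else int(lab)
                    for lab in labels], dtype=np.int64)
    counts = np.bincount(y, minlength=cfg.n_classes)
    if np.any(counts == 0):
        missing = [model.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"stratification error: no examples of {missing}")
    if np.any(counts < folds):
        raise ValueError(
            "stratification error: every present class needs at least "
            f"{folds} examples, got counts {counts.tolist()}"
        )
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=0.2, stratify=y, random_state=split_seed % (2 ** 31))
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=split_seed % (2 ** 31))
    init_state = model.net.state()
    best = None
    history = {"folds": []}
    rng = np.random.default_rng(split_seed)
    for fold, (tr, va) in enumerate(skf.split(train_idx, y[train_idx])):
        model.net.load_state(init_state)
        fold_tr, fold_va = train_idx[tr], train_idx[va]
        losses = _run_epochs(model, x[fold_tr], y[fold_tr], epochs,
                             np.random.default_rng(rng.integers(2 ** 31)))
        val_loss, val_acc = evaluate_loss_acc(model, x[fold_va], y[fold_va])
        tr_loss, tr_acc = evaluate_loss_acc(model, x[fold_tr], y[fold_tr])
        history["folds"].append({
            "fold": fold, "train_loss": losses, "val_loss": val_loss,
            "val_accuracy": val_acc, "train_accuracy": tr_acc,
            "final_train_loss": tr_loss,
            "n_train": int(len(fold_tr)), "n_val": int(len(fold_va)),
        })
        if best is None or val_loss < best[0]:
            best = (val_loss, model.net.state())
    model.net.load_state(best[1])
    history["best_fold"] = int(np.argmin([f["val_loss"] for f in history["folds"]]))
    model.history = history
    model.test_indices = test_idx
    return model


def fit_plain(model: TrainedModel, maps, labels, epochs: int,
              seed: int = 0) -> list[float]:
    """Train on everything given, no splitting — for toy/overfit checks."""
    x = _as_batch(maps, model.config.input_size)
    y = np.asarray([model.class_names.index(lab) if isinstance(lab, str) else int(lab)
                    for lab in labels], dtype=np.int64)
    losses = _run_epochs(model, x, y, epochs, np.random.default_rng(seed))
    model.history = {"train_loss": losses}
    return losses
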