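"""Four-stage convolutional classifier: build, train, capture, randomize.

The backbone is a compact analogue of the residual family used for
tissue classification: four named stages (``layer1..layer4``) with
spatial downsampling between them, residual blocks in the two deepest
stages, batch normalization throughout, a global average pool and a
bias-free linear head (the classic CAM head layout). The toolkit's
explanation machinery is agnostic to the classifier; this one exists so
every propagation challenge — convolution, pooling, normalization,
residual additions, dropout — is exercised at desk scale.

Training is weakly supervised in the strict sense: only image-level
labels are ever consumed; masks never enter this module.
"""

from __future__ import annotations

import copy
import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .nn import (AdaMax, BatchNorm2d, Conv2d, Dropout, Flatten,
                 GlobalAvgPool, Linear, MaxPool2d, ModelGraph, ReLU,
                 ResidualBlock, cross_entropy, softmax)

__all__ = ["TrainConfig", "ActivationStack", "build_toy_cnn",
           "train_classifier", "forward_capture", "randomize_stages",
           "save_checkpoint", "load_checkpoint", "CNNClassifier"]

DEFAULT_AUGMENTATIONS = ("vflip", "hflip", "rotation", "contrast")


@dataclass
class TrainConfig:
    """Training hyperparameters (adaptive optimizer, early stopping)."""

    learning_rate: float = 0.001
    max_epochs: int = 30
    patience: int = 10
    batch_size: int = 16
    augmentations: tuple[str, ...] = DEFAULT_AUGMENTATIONS
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        unknown = set(self.augmentations) - set(DEFAULT_AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")


@dataclass
class ActivationStack:
    """Per-stage activations plus the head output of one forward pass."""

    activations: dict[str, np.ndarray]   # stage -> (C, H, W)
    logits: np.ndarray                   # (N,)
    predicted_class: int


def _stage(in_ch, out_ch, *, residual, dropout_rate):
    layers = [Conv2d(in_ch, out_ch), BatchNorm2d(out_ch), ReLU()]
    if residual:
        layers.append(ResidualBlock(
            [Conv2d(out_ch, out_ch), BatchNorm2d(out_ch), ReLU()]))
    layers.append(MaxPool2d(2))
    tail = [Dropout(dropout_rate)] if dropout_rate > 0 else []
    return layers, tail


def build_toy_cnn(n_classes: int = 2, dropout_rate: float = 0.0,
                  in_channels: int = 1, image_size: int = 64,
                  widths=(8, 16, 32, 64), seed: int = 0) -> ModelGraph:
    """Build the 4-stage CNN; stage boundaries sit at each stage's pool."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    layers: list = []
    boundaries: dict[str, int] = {}
    ch = in_channels
    for s, width in enumerate(widths, start=1):
        stage_layers, tail = _stage(ch, width, residual=(s >= 3),
                                    dropout_rate=dropout_rate)
        layers.extend(stage_layers)
        boundaries[f"layer{s}"] = len(layers) - 1
        layers.extend(tail)
        ch = width
    layers += [GlobalAvgPool(), Flatten(),
               Linear(widths[-1], n_classes, bias=False)]
    model = ModelGraph(layers, boundaries, n_classes,
                       (in_channels, image_size, image_size))
    rng = np.random.default_rng(seed)
    for lyr in layers:
        lyr.init_params(rng)
    return model


# -- data plumbing -------------------------------------------------------

def _augment(x, rng, augmentations):
    """Seeded per-image augmentation on a (C, H, W) copy."""
    if "vflip" in augmentations and rng.random() < 0.5:
        x = x[:, ::-1, :]
    if "hflip" in augmentations and rng.random() < 0.5:
        x = x[:, :, ::-1]
    if "rotation" in augmentations:
        k = int(rng.integers(0, 4))
        if k:
            x = np.rot90(x, k=k, axes=(1, 2))
    if "contrast" in augmentations:
        scale = rng.uniform(0.8, 1.2)
        x = np.clip((x - 0.5) * scale + 0.5, 0.0, 1.0)
    return np.ascontiguousarray(x)


def _accuracy(model, x, y, batch=32):
    correct = 0
    for i in range(0, len(x), batch):
        logits = model.forward(x[i:i + batch])
        correct += int((logits.argmax(axis=1) == y[i:i + batch]).sum())
    return correct / len(x)


def train_classifier(model: ModelGraph, x_train, y_train, x_val, y_val,
                     config: TrainConfig | None = None):
    """Train with cross-entropy on image-level labels; early stop on val accuracy.

    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts
    (epoch, train_loss, val_acc). The model with the best validation
    accuracy is restored before returning. Fully deterministic given the
    config seed.
    """
    config = config or TrainConfig()
    config.validate()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split must contain at least two classes")
    rng = np.random.default_rng(config.seed)
    opt = AdaMax(model, lr=config.learning_rate)
    best_acc, best_weights, since_best = -1.0, model.get_weights(), 0
    log = []
    dropout_on = config.dropout_rate > 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = np.stack([_augment(x_train[j], rng, config.augmentations)
                           for j in idx])
            logits = model.forward(xb, bn_train=True, dropout_on=dropout_on,
                                   rng=rng)
            loss, glogits = cross_entropy(logits, y_train[idx])
            model.zero_grads()
            model.backward(glogits)
            opt.step()
            losses.append(loss)
        val_acc = _accuracy(model, x_val, y_val)
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "val_acc": float(val_acc)})
        if val_acc > best_acc:
            best_acc, best_weights, since_best = val_acc, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_weights(best_weights)
    return model, log


def forward_capture(model: ModelGraph, image: np.ndarray, *,
                    dropout_on: bool = False,
                    rng: np.random.Generator | None = None) -> ActivationStack:
    """Run one image through the model recording every stage output.

    ``image`` is ``(C, H, W)`` (or ``(H, W)`` for single-channel models).
    The returned stack holds single-image activations ``(C, H, W)``.
    """
    if image.ndim == 2:
        image = image[None]
    if image.shape != model.input_shape:
        raise ValueError(
            f"input shape {image.shape} != model input {model.input_shape}")
    logits, acts = model.forward(image[None], dropout_on=dropout_on, rng=rng,
                                 capture=True)
    return ActivationStack(
        activations={k: v[0] for k, v in acts.items()},
        logits=logits[0],
        predicted_class=int(logits[0].argmax()),
    )


def randomize_stages(model: ModelGraph, stages_from_top: int,
                     seed: int = 0) -> ModelGraph:
    """Cascading re-initialization: head first, then stages top-down.

    ``stages_from_top`` counts randomized units out of 5 (head + 4
    stages): 0 leaves the model untouched, 1 randomizes the head only,
    5 randomizes everything. The input model is never modified.
    """
    if not 0 <= stages_from_top <= 5:
        raise ValueError("stages_from_top must be in [0, 5]")
    out = copy.deepcopy(model)
    if stages_from_top == 0:
        return out
    rng = np.random.default_rng(seed)
    boundaries = sorted(out.stage_boundaries.items(), key=lambda kv: kv[1])
    # unit 0 = layers above layer4's boundary (the head); unit t = stage 5-t
    cutoffs = [b for _, b in boundaries]  # layer1..layer4 boundary indices
    head_start = cutoffs[-1] + 1
    ranges = [range(head_start, len(out.layers))]
    for s in range(3, -1, -1):  # layer4, layer3, layer2, layer1
        lo = cutoffs[s - 1] + 1 if s > 0 else 0
        ranges.append(range(lo, cutoffs[s] + 1))
    for unit in range(stages_from_top):
        for i in ranges[unit]:
            out.layers[i].init_params(rng)
    return out


# -- checkpoint I/O ------------------------------------------------------

def _topology(model: ModelGraph):
    return {
        "n_classes": model.n_classes,
        "input_shape": list(model.input_shape),
        "stage_boundaries": model.stage_boundaries,
        "dropout_rate": next((l.rate for l in model.layers
                              if isinstance(l, Dropout)), 0.0),
        # top-level convs are exactly the four stage convs
        "widths": [l.out_ch for l in model.layers if isinstance(l, Conv2d)],
    }


def save_checkpoint(model: ModelGraph, path, train_config=None,
                    extra=None) -> None:
    """Single-archive checkpoint: weights (npz) + topology + config (json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = BytesIO()
    # include BN running stats alongside learnable params
    state = dict(model.named_params())
    state.update(_running_stats(model))
    np.savez(buf, **state)
    meta = {"topology": _topology(model)}
    if train_config is not None:
        meta["train_config"] = {k: list(v) if isinstance(v, tuple) else v
                                for k, v in vars(train_config).items()}
    if extra:
        meta["extra"] = extra
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("weights.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta, indent=1))


def _running_stats(model):
    out = {}

    def walk(prefix, layers):
        for i, lyr in enumerate(layers):
            if isinstance(lyr, BatchNorm2d):
                out[f"{prefix}{i}.running_mean"] = lyr.running_mean
                out[f"{prefix}{i}.running_var"] = lyr.running_var
            if isinstance(lyr, ResidualBlock):
                walk(f"{prefix}{i}.branch", lyr.branch)

    walk("layer", model.layers)
    return out


def load_checkpoint(path) -> tuple[ModelGraph, dict]:
    """Rebuild the model from a checkpoint archive; returns (model, meta)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("weights.npz") as fh:
            state = dict(np.load(BytesIO(fh.read())))
    topo = meta["topology"]
    widths = tuple(topo.get("widths", (8, 16, 32, 64)))
    model = build_toy_cnn(
        n_classes=topo["n_classes"],
        dropout_rate=topo.get("dropout_rate", 0.0),
        in_channels=topo["input_shape"][0],
        image_size=topo["input_shape"][1],
        widths=widths,
    )
    params = {k: v for k, v in state.items() if "running_" not in k}
    model.set_weights(params)
    stats = _running_stats(model)
    for k, v in stats.items():
        v[...] = state[k]
    return model, meta


# -- sklearn-style estimator --------------------------------------------

class CNNClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn style wrapper around the 4-stage CNN.

    Parameters mirror :class:`TrainConfig`; ``fit`` carves a stratified
    validation split out of the training data for early stopping (or
    accepts one via ``fit(..., X_val=, y_val=)``).

    Attributes set by ``fit``: ``model_`` (the trained
    :class:`~xrelcam.nn.ModelGraph`), ``classes_``, ``history_``.
    """

    def __init__(self, learning_rate=0.001, max_epochs=30, patience=10,
                 batch_size=16, augmentations=DEFAULT_AUGMENTATIONS,
                 dropout_rate=0.0, validation_fraction=0.1, widths=(8, 16, 32, 64),
                 random_state=0):
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.augmentations = augmentations
        self.dropout_rate = dropout_rate
        self.validation_fraction = validation_fraction
        self.widths = widths
        self.random_state = random_state

    def _as_x(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None]
        if X.ndim != 4:
            raise ValueError("X must be (n, H, W) or (n, C, H, W)")
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._as_x(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        cfg = TrainConfig(
            learning_rate=self.learning_rate, max_epochs=self.max_epochs,
            patience=self.patience, batch_size=self.batch_size,
            augmentations=tuple(self.augmentations),
            dropout_rate=self.dropout_rate, seed=self.random_state)
        if X_val is None:
            rng = np.random.default_rng(self.random_state)
            val_idx = []
            for cls in range(len(self.classes_)):
                members = np.flatnonzero(y_idx == cls)
                n_val = max(1, int(round(self.validation_fraction
                                         * len(members))))
                val_idx.extend(rng.permutation(members)[:n_val])
            val_mask = np.zeros(len(y_idx), dtype=bool)
            val_mask[val_idx] = True
            X_val, y_val = X[val_mask], y_idx[val_mask]
            X_tr, y_tr = X[~val_mask], y_idx[~val_mask]
        else:
            X_val = self._as_x(X_val)
            y_val = np.searchsorted(self.classes_, np.asarray(y_val))
            X_tr, y_tr = X, y_idx
        model = build_toy_cnn(
            n_classes=len(self.classes_), dropout_rate=self.dropout_rate,
            in_channels=X.shape[1], image_size=X.shape[2],
            widths=tuple(self.widths), seed=self.random_state)
        if cfg.max_epochs > 0:
            model, log = train_classifier(model, X_tr, y_tr, X_val, y_val, cfg)
        else:
            log = []
        self.model_ = model
        self.history_ = log
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self.model_.forward(self._as_x(X))

    def predict_proba(self, X):
        return softmax(self.decision_function(X))

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]
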