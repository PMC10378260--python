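"""The mixed-input ANN-CNN sleep/wake classifier.

The convolutional branch processes the Hilbert spectrum image through
three conv layers of 16, 32 and 64 filters (kernel 3, ReLU), each followed
by 2x2 max pooling, then fully connected layers of 16 and 8 nodes. The
dense branch processes the tabular IMF statistics through fully connected
layers of 16 and 8 nodes. Neither branch has a softmax; their outputs are
concatenated to a width-16 vector, passed through a 4-node fully connected
layer, and classified by a single sigmoid unit (binary) or an n-class
softmax (multiclass). A CNN-only baseline reuses the convolutional branch
with the same classification head and compile settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .nn import Adam, Conv2D, Dense, Flatten, MaxPool2D, sigmoid, softmax

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainingHistory",
    "MixedModel",
    "CNNOnlyModel",
    "build_model",
    "build_cnn_only",
    "split_dataset",
    "train",
    "predict",
]

_PREDICT_CHUNK = 256


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the reference design)."""

    conv_filters: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    cnn_fc_nodes: tuple[int, ...] = (16, 8)
    ann_fc_nodes: tuple[int, ...] = (16, 8)
    merge_fc_nodes: int = 4
    image_shape: tuple[int, int, int] = (64, 64, 1)
    feature_dim: int = 64
    n_classes: int = 2

    def __post_init__(self) -> None:
        for a, b in zip(self.conv_filters, self.conv_filters[1:]):
            if b != 2 * a:
                raise ValueError("conv filter counts must double per layer")
        if self.cnn_fc_nodes[-1] + self.ann_fc_nodes[-1] != 16:
            raise ValueError("concatenated branch width must be 16")
        if self.n_classes not in (2, 6) and self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        h, w, _ = self.image_shape
        shrink = self.pool_size ** len(self.conv_filters)
        if h % shrink or w % shrink or h < shrink or w < shrink:
            raise ValueError(
                f"image {h}x{w} too small/odd for {len(self.conv_filters)} pooling stages"
            )
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")

    @property
    def output_activation(self) -> str:
        return "sigmoid" if self.n_classes == 2 else "softmax"

    @property
    def output_units(self) -> int:
        return 1 if self.n_classes == 2 else self.n_classes


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    test_fraction: float = 0.30
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.test_fraction < 1 and 0 < self.validation_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")

    @property
    def loss(self) -> str:
        return "cross-entropy"


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def _make_cnn_branch(config: ModelConfig, rng: np.random.Generator):
    h, w, c = config.image_shape
    layers = []
    c_in = c
    for f in config.conv_filters:
        layers.append(Conv2D(c_in, f, config.kernel_size, rng))
        layers.append(MaxPool2D())
        c_in = f
        h //= config.pool_size
        w //= config.pool_size
    layers.append(Flatten())
    n_in = h * w * c_in
    for nodes in config.cnn_fc_nodes:
        layers.append(Dense(n_in, nodes, "relu", rng))
        n_in = nodes
    return layers


def _make_head(config: ModelConfig, n_in: int, rng: np.random.Generator):
    return [
        Dense(n_in, config.merge_fc_nodes, "relu", rng),
        Dense(config.merge_fc_nodes, config.output_units, "linear", rng),
    ]


def _forward_chain(layers, x):
    for layer in layers:
        x = layer.forward(x)
    return x


def _backward_chain(layers, grad):
    for layer in reversed(layers):
        grad = layer.backward(grad)
    return grad


class MixedModel:
    """Image branch + tabular branch, concatenated into a shared head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.cnn = _make_cnn_branch(config, rng)
        self.ann = []
        n_in = config.feature_dim
        for nodes in config.ann_fc_nodes:
            self.ann.append(Dense(n_in, nodes, "relu", rng))
            n_in = nodes
        self.head = _make_head(
            config, config.cnn_fc_nodes[-1] + config.ann_fc_nodes[-1], rng
        )

    # -- forward / backward ------------------------------------------------
    def forward_logits(self, images: np.ndarray, features: np.ndarray) -> np.ndarray:
        ci = _forward_chain(self.cnn, images)
        ai = _forward_chain(self.ann, features)
        return _forward_chain(self.head, np.concatenate([ci, ai], axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        grad = _backward_chain(self.head, dlogits)
        w = self.config.cnn_fc_nodes[-1]
        _backward_chain(self.cnn, grad[:, :w])
        _backward_chain(self.ann, grad[:, w:])

    def predict_proba(self, images: np.ndarray, features: np.ndarray) -> np.ndarray:
        out = []
        for lo in range(0, len(images), _PREDICT_CHUNK):
            z = self.forward_logits(
                images[lo : lo + _PREDICT_CHUNK], features[lo : lo + _PREDICT_CHUNK]
            )
            out.append(sigmoid(z) if self.config.n_classes == 2 else softmax(z))
        return np.concatenate(out, axis=0)

    # -- introspection -----------------------------------------------------
    @property
    def layers(self):
        return self.cnn + self.ann + self.head

    def parameter_count(self) -> int:
        return sum(p.size for layer in self.layers for p, _ in layer.params())

    def summary(self) -> list[dict]:
        """Layer-by-layer architecture description, for audits."""
        desc = []
        for branch, layers in (("cnn", self.cnn), ("ann", self.ann), ("head", self.head)):
            for layer in layers:
                if isinstance(layer, Conv2D):
                    desc.append({"branch": branch, "type": "conv2d",
                                 "filters": layer.c_out, "kernel": layer.kernel,
                                 "activation": "relu"})
                elif isinstance(layer, MaxPool2D):
                    desc.append({"branch": branch, "type": "maxpool2d", "pool": 2})
                elif isinstance(layer, Flatten):
                    desc.append({"branch": branch, "type": "flatten"})
                else:
                    act = layer.activation
                    if layer is self.layers[-1]:
                        act = self.config.output_activation
                    desc.append({"branch": branch, "type": "dense",
                                 "nodes": layer.n_out, "activation": act})
        return desc


class CNNOnlyModel(MixedModel):
    """The convolutional branch followed directly by the classification head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.cnn = _make_cnn_branch(config, rng)
        self.ann = []
        self.head = _make_head(config, config.cnn_fc_nodes[-1], rng)

    def forward_logits(self, images: np.ndarray, features: np.ndarray = None) -> np.ndarray:
        return _forward_chain(self.head, _forward_chain(self.cnn, images))

    def backward(self, dlogits: np.ndarray) -> None:
        _backward_chain(self.cnn, _backward_chain(self.head, dlogits))

    def predict_proba(self, images: np.ndarray, features: np.ndarray = None) -> np.ndarray:
        out = []
        for lo in range(0, len(images), _PREDICT_CHUNK):
            z = self.forward_logits(images[lo : lo + _PREDICT_CHUNK])
            out.append(sigmoid(z) if self.config.n_classes == 2 else softmax(z))
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig | None = None, seed: int = 0) -> MixedModel:
    return MixedModel(config or ModelConfig(), seed=seed)


def build_cnn_only(config: ModelConfig | None = None, seed: int = 0) -> CNNOnlyModel:
    return CNNOnlyModel(config or ModelConfig(), seed=seed)


def split_dataset(
    labels: np.ndarray, config: TrainConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, disjoint (train, validation, test) index sets.

    ``test_fraction`` of the whole dataset is held out for testing;
    ``validation_fraction`` of the remaining training portion becomes the
    validation set. Deterministic under the config seed.
    """
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    trainval, test = train_test_split(
        idx, test_size=config.test_fraction, stratify=labels,
        random_state=config.seed % (2**32 - 1),
    )
    tr, val = train_test_split(
        trainval, test_size=config.validation_fraction, stratify=labels[trainval],
        random_state=(config.seed + 1) % (2**32 - 1),
    )
    return np.sort(tr), np.sort(val), np.sort(test)


def _loss_and_dlogits(model, logits, y, n_classes):
    eps = 1e-7
    if n_classes == 2:
        p = np.clip(sigmoid(logits[:, 0]), eps, 1 - eps)
        loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        dlogits = ((p - y) / len(y))[:, None].astype(np.float32)
        acc = np.mean((p >= 0.5) == (y == 1))
    else:
        p = np.clip(softmax(logits), eps, 1.0)
        loss = -np.mean(np.log(p[np.arange(len(y)), y]))
        dlog = p.copy()
        dlog[np.arange(len(y)), y] -= 1.0
        dlogits = (dlog / len(y)).astype(np.float32)
        acc = np.mean(p.argmax(axis=1) == y)
    return float(loss), dlogits, float(acc)


def _evaluate_loss(model, images, features, y, n_classes):
    probs = model.predict_proba(images, features)
    eps = 1e-7
    if n_classes == 2:
        p = np.clip(probs[:, 0], eps, 1 - eps)
        loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        acc = np.mean((p >= 0.5) == (y == 1))
    else:
        p = np.clip(probs, eps, 1.0)
        loss = -np.mean(np.log(p[np.arange(len(y)), y]))
        acc = np.mean(p.argmax(axis=1) == y)
    return float(loss), float(acc)


def train(
    model: MixedModel,
    features: np.ndarray,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    validation_data: tuple | None = None,
) -> TrainingHistory:
    """Mini-batch Adam training with binary/categorical cross-entropy.

    ``labels`` are integer class codes (binary: wake = 1 is the positive
    class). ``validation_data`` is an optional (features, images, labels)
    triple evaluated after each training epoch. All shuffling derives from
    the config seed. Returns the per-epoch history.
    """
    cfg = config or TrainConfig()
    features = np.asarray(features, dtype=np.float32)
    images = np.asarray(images, dtype=np.float32)
    y = np.asarray(labels)
    if images.ndim == 3:
        images = images[..., None]
    if not (len(features) == len(images) == len(y)):
        raise ValueError("features, images and labels must be aligned")
    n_classes = model.config.n_classes
    opt = Adam(
        (pg for layer in model.layers for pg in layer.params()),
        lr=cfg.learning_rate,
    )
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    n = len(y)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, accs, weights = [], [], []
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            logits = model.forward_logits(images[sel], features[sel])
            loss, dlogits, acc = _loss_and_dlogits(model, logits, y[sel], n_classes)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            accs.append(acc)
            weights.append(len(sel))
        w = np.asarray(weights, dtype=float)
        history.loss.append(float(np.average(losses, weights=w)))
        history.accuracy.append(float(np.average(accs, weights=w)))
        if validation_data is not None:
            vf, vi, vy = validation_data
            vi = np.asarray(vi, dtype=np.float32)
            if vi.ndim == 3:
                vi = vi[..., None]
            vloss, vacc = _evaluate_loss(model, vi, np.asarray(vf, np.float32),
                                         np.asarray(vy), n_classes)
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)
    return history


def predict(
    model: MixedModel,
    features: np.ndarray,
    images: np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """(predicted class codes, probabilities). Binary probabilities are for
    the positive (wake) class; a probability exactly at the threshold is
    classified positive."""
    features = np.asarray(features, dtype=np.float32)
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[..., None]
    if len(features) != len(images):
        raise ValueError("features and images must be aligned")
    probs = model.predict_proba(images, features)
    if model.config.n_classes == 2:
        return (probs[:, 0] >= threshold).astype(int), probs[:, 0]
    return probs.argmax(axis=1), probs
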