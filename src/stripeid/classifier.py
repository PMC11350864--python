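"""Model assembly and the training / prediction contract.

The identification model is: backbone -> attention gate (optional) ->
global average pooling -> dropout -> dense softmax head.  Training is
minibatch cross-entropy with Adam (default, lr 0.001) or SGD for the
configured number of epochs; the test split's Top-1 accuracy is recorded
every epoch so the maximum and fifth-highest Top-1 statistics can be read
off the log afterwards.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import ops
from .attention import AttentionConfig, append_attention, attention_param_count
from .backbone import ArchConfig, backbone_channels, build_backbone
from .graph import ModelGraph

__all__ = ["TrainConfig", "TrainLog", "Prediction", "Model",
           "build_classifier_graph", "assemble_model",
           "train", "predict", "load_pretrained", "save_weights",
           "summary_table", "DROPOUT_SWEEP_RATES"]

#: Dropout rates swept when selecting the regularization strength.
DROPOUT_SWEEP_RATES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.learning_rate < 0:
            # rate 0 is allowed: it freezes the model, useful as a control
            raise ValueError("learning_rate must not be negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown train config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class TrainLog:
    """Per-epoch test Top-1 accuracies and mean training losses."""

    test_top1: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"epoch": np.arange(1, len(self.loss) + 1),
                             "loss": self.loss, "test_top1": self.test_top1})


@dataclass
class Prediction:
    probabilities: np.ndarray
    class_index: int


class Model:
    """A layer graph bound to its parameters and batch-norm state."""

    def __init__(self, arch: ArchConfig, graph: ModelGraph):
        self.arch = arch
        self.graph = graph
        self.params = graph.init_params(arch.seed)
        self.state = graph.init_state()
        #: parameter keys belonging to the feature extractor (transferable)
        self.backbone_keys = frozenset(
            k for k in self.params if not k.startswith(("att_", "head")))

    def forward(self, x, training: bool = False, rng=None, bn_momentum=0.9):
        """Probabilities for a batch (n, H, W, 3) of normalized images."""
        out = self.graph.forward(x, self.params, self.state, training=training,
                                 rng=rng, bn_momentum=bn_momentum)
        return out["output"]

    def logits(self, x, training: bool = False, rng=None):
        out = self.graph.forward(x, self.params, self.state, training=training,
                                 rng=rng, wanted=("logits",))
        return out["logits"], out["_params"]

    def param_count(self) -> int:
        return self.graph.param_count()


def build_classifier_graph(arch: ArchConfig) -> ModelGraph:
    """The full classifier graph, without instantiating any weights."""
    g = build_backbone(arch)
    src = g.output
    if arch.attention != "none":
        att = AttentionConfig(kind=arch.attention,
                              channels=backbone_channels(arch))
        src = append_attention(g, src, att, prefix="att")
        g.tap("attended", src)
    g.add("pool", "gap", src)
    g.add("drop", "dropout", "pool", rate=arch.dropout_rate)
    g.add("head", "dense", "drop", in_features=backbone_channels(arch),
          out_features=arch.n_classes, use_bias=True)
    g.tap("logits", "head")
    g.add("probs", "softmax", "head")
    g.output = "probs"
    return g


def assemble_model(arch: ArchConfig) -> Model:
    """Backbone, attention gate, pooled dropout head, softmax output."""
    return Model(arch, build_classifier_graph(arch))


def _iter_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-7):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class _SGD:
    def __init__(self, params, lr):
        self.lr = lr

    def step(self, params, grads):
        for k, g in grads.items():
            params[k] -= self.lr * g


def train(model: Model, train_set, test_set, cfg: TrainConfig) -> TrainLog:
    """Minibatch cross-entropy training with per-epoch test evaluation.

    ``train_set``/``test_set`` are ``(X, y)`` pairs: X (n, H, W, 3) float32
    arrays of normalized images, y integer label vectors.  Deterministic
    given ``cfg.seed`` under single-threaded execution.
    """
    Xtr, ytr = _check_set(train_set, model.arch, "train_set")
    Xte, yte = _check_set(test_set, model.arch, "test_set")
    rng = np.random.default_rng(cfg.seed)
    opt_cls = {"adam": _Adam, "sgd": _SGD}[cfg.optimizer]
    opt = opt_cls(model.params, cfg.learning_rate)
    log = TrainLog()
    for _ in range(cfg.epochs):
        losses = []
        for idx in _iter_batches(len(ytr), cfg.batch_size, rng):
            logits, tensors = model.logits(Xtr[idx], training=True, rng=rng)
            loss = ops.softmax_cross_entropy(logits, ytr[idx])
            loss.backward()
            grads = {k: t.grad for k, t in tensors.items() if t.grad is not None}
            opt.step(model.params, grads)
            losses.append(float(loss.data))
        log.loss.append(float(np.mean(losses)))
        log.test_top1.append(evaluate_accuracy(model, Xte, yte, cfg.batch_size))
    return log


def evaluate_accuracy(model: Model, X, y, batch_size: int = 32) -> float:
    correct = 0
    for i in range(0, len(y), batch_size):
        probs = model.forward(X[i:i + batch_size]).data
        correct += int((probs.argmax(axis=-1) == y[i:i + batch_size]).sum())
    return correct / len(y)


def _check_set(dataset, arch, name):
    X, y = dataset
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(y) == 0:
        raise ValueError(f"{name} is empty")
    if X.ndim != 4 or X.shape[1:3] != (arch.input_size, arch.input_size):
        raise ValueError(f"{name} images must be (n, {arch.input_size}, "
                         f"{arch.input_size}, 3); got {X.shape}")
    if y.max() >= arch.n_classes or y.min() < 0:
        raise ValueError(f"{name} labels must lie in [0, {arch.n_classes})")
    return X, y


def predict(model: Model, image) -> Prediction:
    """Probabilities and argmax class for one preprocessed image.

    Dropout is inactive; argmax ties resolve to the lowest class index.
    """
    image = np.asarray(image, dtype=np.float32)
    size = model.arch.input_size
    if image.shape != (size, size, 3):
        raise ValueError(f"expected a ({size}, {size}, 3) image, got {image.shape}")
    probs = model.forward(image[None]).data[0]
    return Prediction(probabilities=probs, class_index=int(probs.argmax()))


def save_weights(model: Model, path):
    arrays = {f"param/{k}": v for k, v in model.params.items()}
    arrays.update({f"state/{k}": v for k, v in model.state.items()})
    np.savez(path, **arrays)


def load_pretrained(model: Model, weights_source) -> Model:
    """Replace backbone parameters from an ``.npz`` file, leaving the
    attention gate and classification head at their initialization."""
    if not os.path.exists(weights_source):
        raise FileNotFoundError(f"weights file not found: {weights_source}")
    with np.load(weights_source) as data:
        staged = {}
        for key in model.backbone_keys:
            name = f"param/{key}"
            if name not in data:
                raise KeyError(f"weights file is missing backbone tensor {key!r}")
            arr = data[name]
            if arr.shape != model.params[key].shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: file has {arr.shape}, "
                    f"model expects {model.params[key].shape}")
            staged[key] = arr.astype(np.float32)
        staged_state = {}
        for key in model.state:
            name = f"state/{key}"
            if name in data:
                staged_state[key] = data[name].astype(np.float32)
    model.params.update(staged)
    model.state.update(staged_state)
    return model


def summary_table(arch: ArchConfig) -> list[tuple[str, str, int]]:
    """Component-level table: backbone, attention block, pooling, dropout,
    dense head — with output shapes and parameter counts."""
    backbone = build_backbone(arch)
    side = backbone.infer_shapes((arch.input_size, arch.input_size, 3))[
        backbone.output][0]
    c = backbone_channels(arch)
    rows = [("inception_resnet_v2 (Functional)",
             f"(None, {side}, {side}, {c})", backbone.param_count())]
    if arch.attention != "none":
        att = AttentionConfig(kind=arch.attention, channels=c)
        rows.append((f"{arch.attention}_block ({arch.attention}_block)",
                     f"(None, {side}, {side}, {c})", attention_param_count(att)))
    rows.append(("global_average_pooling2d_1 (GlobalAveragePooling2D)",
                 f"(None, {c})", 0))
    rows.append(("dropout (Dropout)", f"(None, {c})", 0))
    rows.append(("dense_2 (Dense)", f"(None, {arch.n_classes})",
                 c * arch.n_classes + arch.n_classes))
    return rows


def format_table(rows) -> str:
    widths = [max(len(str(r[i])) for r in rows + [("Layer (Type)",
              "Output Shape", "Param")]) for i in range(3)]
    lines = [f"{'Layer (Type)':<{widths[0]}}  {'Output Shape':<{widths[1]}}  Param",
             "-" * (sum(widths) + 4)]
    total = 0
    for name, shape, count in rows:
        lines.append(f"{name:<{widths[0]}}  {shape:<{widths[1]}}  {count:,}")
        total += count
    lines.append("-" * (sum(widths) + 4))
    lines.append(f"Total params: {total:,}")
    return "\n".join(lines)
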