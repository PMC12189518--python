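"""Transfer-learning classifier: frozen convolutional trunk + small trainable head.

The network is a pretrained (or randomly initialised) convolutional backbone
with its original classification top removed, used purely as a fixed feature
extractor, followed by the task head

    global average pooling -> dense(128, ReLU) -> dropout(0.5)
                           -> dense(2, softmax)

Only the head is trained (Adam on the cross-entropy loss); the backbone's
parameters — including batch-norm statistics, which always run in inference
mode — are bit-identical before and after training. The epoch snapshot with
the minimum validation loss is the model that is kept.

Because the backbone is frozen, its output for a given tensor never changes
during training; features are therefore computed once per input and the head
is optimised on the cached feature matrix. This is mathematically identical to
pushing every batch through the full network each step, at a small fraction of
the cost.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import Layer, count_params, relu, softmax
from .backbones import BACKBONE_FEATURES, BACKBONES, build_backbone
from .config import TrainConfig
from .representation import CDMLTensor

__all__ = ["BackboneSpec", "HeadSpec", "TrainedModel", "build_model", "train",
           "predict", "CLASSES"]

CLASSES = ("left", "right")  # output order; argmax ties resolve to "left"


class DataError(ValueError):
    """Training data violates a precondition (e.g. a single-class set)."""


@dataclass(frozen=True)
class BackboneSpec:
    """Which trunk to use and how to initialise it.

    ``pretrained=True`` loads published natural-image weights from
    ``weights_path`` (an .npz keyed by layer path); no download is attempted.
    ``input_norm`` selects whether the pretraining corpus' channel
    normalisation is applied to the [0, 1] inputs — "canonical" when using
    pretrained weights, "identity" (default) otherwise, where corpus
    statistics would be meaningless.
    """

    name: str = "efficientnet-b0"
    pretrained: bool = False
    frozen: bool = True
    weights_path: str | None = None
    input_norm: str = "identity"  # or "canonical"

    def __post_init__(self) -> None:
        if self.name not in BACKBONES:
            raise ValueError(f"unknown backbone {self.name!r}; supported: {BACKBONES}")
        if self.input_norm not in ("identity", "canonical"):
            raise ValueError("input_norm must be 'identity' or 'canonical'")


@dataclass(frozen=True)
class HeadSpec:
    """The trainable classification head appended to the trunk."""

    hidden_units: int = 128
    dropout_rate: float = 0.5
    output_units: int = 2

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.output_units < 2:
            raise ValueError("head sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class TrainedModel:
    """Backbone + head parameters plus training history."""

    backbone: Layer
    backbone_spec: BackboneSpec
    head_spec: HeadSpec
    head: dict[str, np.ndarray]
    seed: int = 0
    history: list[dict] = field(default_factory=list)
    #: per-feature (mean, std) computed once from the training set and applied
    #: before the first dense layer. A fixed calibration, not trained weights:
    #: a randomly initialised trunk emits features on an arbitrary (and very
    #: small) scale, and this affine map brings them into the head's dynamic
    #: range. Frozen after being set.
    feature_norm: tuple[np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------------ sizes
    @property
    def n_backbone_params(self) -> int:
        return count_params(self.backbone)

    @property
    def n_head_params(self) -> int:
        return int(sum(p.size for p in self.head.values()))

    @property
    def n_params(self) -> int:
        return self.n_backbone_params + self.n_head_params

    @property
    def n_trainable_params(self) -> int:
        return self.n_head_params if self.backbone_spec.frozen else self.n_params

    def backbone_checksum(self) -> str:
        """Digest of every backbone parameter (freezing contract witness)."""
        h = hashlib.sha256()
        for name, p in sorted(self.backbone.params()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # ---------------------------------------------------------------- forward
    def features(self, tensors: list[CDMLTensor] | np.ndarray,
                 batch_size: int = 8) -> np.ndarray:
        """Frozen-trunk features after global average pooling, shape (N, F)."""
        if isinstance(tensors, np.ndarray):
            x = tensors
        else:
            x = np.stack([t.layers for t in tensors])
        feats = []
        for i in range(0, len(x), batch_size):
            fmap = self.backbone(x[i:i + batch_size].astype(np.float32))
            feats.append(fmap.mean(axis=(1, 2)))  # global average pooling
        return np.concatenate(feats).astype(np.float64)

    def head_forward(self, feats: np.ndarray) -> np.ndarray:
        """Inference-mode head: probabilities of (left, right)."""
        if self.feature_norm is not None:
            mu, sd = self.feature_norm
            feats = (feats - mu) / sd
        h = relu(feats @ self.head["w1"] + self.head["b1"])
        return softmax(h @ self.head["w2"] + self.head["b2"], axis=-1)

    def predict_proba(self, tensors: list[CDMLTensor] | np.ndarray) -> np.ndarray:
        return self.head_forward(self.features(tensors))


def _init_head(feature_width: int, head: HeadSpec,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    lim1 = np.sqrt(6.0 / (feature_width + head.hidden_units))
    lim2 = np.sqrt(6.0 / (head.hidden_units + head.output_units))
    return {
        "w1": rng.uniform(-lim1, lim1, (feature_width, head.hidden_units)),
        "b1": np.zeros(head.hidden_units),
        "w2": rng.uniform(-lim2, lim2, (head.hidden_units, head.output_units)),
        "b2": np.zeros(head.output_units),
    }


def build_model(backbone: BackboneSpec | str = BackboneSpec(),
                head: HeadSpec = HeadSpec(), seed: int = 0) -> TrainedModel:
    """Assemble the (untrained) classifier.

    The trunk is randomly initialised from ``seed``; with
    ``backbone.pretrained`` the published weights are loaded over it from
    ``backbone.weights_path``.
    """
    if isinstance(backbone, str):
        backbone = BackboneSpec(name=backbone)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    trunk = build_backbone(backbone.name, rng)
    if backbone.input_norm == "canonical":
        _set_input_norm(trunk, True)
    if backbone.pretrained:
        if not backbone.weights_path:
            raise ValueError(
                "pretrained=True requires weights_path: published weights are "
                "consumed from a local .npz file, never downloaded")
        _load_weights(trunk, backbone.weights_path)
    head_params = _init_head(BACKBONE_FEATURES[backbone.name], head, rng)
    return TrainedModel(backbone=trunk, backbone_spec=backbone,
                        head_spec=head, head=head_params, seed=seed)


def _set_input_norm(trunk: Layer, active: bool) -> None:
    from .backbones import InputNorm

    for child in _walk(trunk):
        if isinstance(child, InputNorm):
            child.active = active


def _walk(layer: Layer):
    yield layer
    for child in layer.children():
        yield from _walk(child)


def _load_weights(trunk: Layer, path: str | Path) -> None:
    weights = np.load(path)
    own = dict(trunk.params())
    missing = [k for k in own if k not in weights.files]
    if missing:
        raise ValueError(f"weight file lacks {len(missing)} arrays, e.g. {missing[:3]}")
    for name, p in trunk.params():
        arr = np.asarray(weights[name], dtype=p.dtype)
        if arr.shape != p.shape:
            raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.shape}")
        p[...] = arr


# -------------------------------------------------------------------- training

def _one_hot(labels: list[str]) -> np.ndarray:
    try:
        idx = np.array([CLASSES.index(lab) for lab in labels])
    except ValueError as exc:
        raise DataError(f"labels must be within {CLASSES}") from exc
    return np.eye(len(CLASSES))[idx]


def train_head_on_features(model: TrainedModel, feats: np.ndarray,
                           labels: list[str], val_feats: np.ndarray,
                           val_labels: list[str], cfg: TrainConfig) -> TrainedModel:
    """Adam/cross-entropy optimisation of the head on precomputed features.

    Keeps the epoch snapshot with minimum validation loss. The trained head is
    written back into ``model`` (which is also returned).
    """
    if len(set(labels)) < 2:
        raise DataError("training set must contain both classes")
    if len(feats) == 0 or len(val_feats) == 0:
        raise DataError("training and validation sets must be non-empty")
    y = _one_hot(list(labels))
    y_val = _one_hot(list(val_labels))
    mu = feats.mean(axis=0)
    sd = np.maximum(feats.std(axis=0), 1e-12)
    model.feature_norm = (mu, sd)
    feats = (feats - mu) / sd  # val_feats stay raw; head_forward normalises
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 29]))
    params = model.head
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    drop = model.head_spec.dropout_rate
    step = 0
    best = (np.inf, {k: p.copy() for k, p in params.items()})
    n = len(feats)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = feats[idx], y[idx]
            # forward
            h_pre = xb @ params["w1"] + params["b1"]
            h = relu(h_pre)
            if drop > 0:
                mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                h_d = h * mask
            else:
                h_d = h
            logits = h_d @ params["w2"] + params["b2"]
            p = softmax(logits, axis=-1)
            epoch_loss += -np.sum(np.log(np.clip(p[yb.astype(bool)], 1e-12, None)))
            # backward
            dlogits = (p - yb) / len(idx)
            grads = {
                "w2": h_d.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            dh = (dlogits @ params["w2"].T)
            if drop > 0:
                dh = dh * mask
            dh *= (h_pre > 0)
            grads["w1"] = xb.T @ dh
            grads["b1"] = dh.sum(axis=0)
            # Adam update
            step += 1
            for k in params:
                m[k] = b1m * m[k] + (1 - b1m) * grads[k]
                v[k] = b2m * v[k] + (1 - b2m) * grads[k] ** 2
                mhat = m[k] / (1 - b1m ** step)
                vhat = v[k] / (1 - b2m ** step)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        p_val = model.head_forward(val_feats)
        val_loss = float(-np.mean(np.log(np.clip(p_val[y_val.astype(bool)],
                                                 1e-12, None))))
        val_acc = float(np.mean(p_val.argmax(1) == y_val.argmax(1)))
        model.history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                              "val_loss": val_loss, "val_acc": val_acc})
        if val_loss < best[0]:
            best = (val_loss, {k: p.copy() for k, p in params.items()})

    model.head = best[1]
    return model


def train(model: TrainedModel, train_set: list[CDMLTensor],
          val_set: list[CDMLTensor], cfg: TrainConfig | None = None) -> TrainedModel:
    """Train the head on CDML tensors; the frozen backbone never changes.

    Model selection keeps the epoch with minimum loss on ``val_set``.
    """
    cfg = cfg or TrainConfig()
    if not model.backbone_spec.frozen:
        raise NotImplementedError(
            "only frozen-backbone training is supported: the trunk is a fixed "
            "feature extractor and no gradients flow through it")
    if not train_set or not val_set:
        raise DataError("training and validation sets must be non-empty")
    checksum = model.backbone_checksum()
    feats = model.features(train_set)
    val_feats = model.features(val_set)
    model = train_head_on_features(model, feats, [t.label for t in train_set],
                                   val_feats, [t.label for t in val_set], cfg)
    assert model.backbone_checksum() == checksum, "frozen backbone was modified"
    return model


def predict(model: TrainedModel, x: CDMLTensor) -> tuple[float, float]:
    """Probability pair (left, right) for one tensor; dropout disabled."""
    if x.layers.ndim != 3:
        raise ValueError("expected a single H x W x 3 tensor")
    p = model.predict_proba(x.layers[None])[0]
    return float(p[0]), float(p[1])


def predict_label(model: TrainedModel, x: CDMLTensor) -> str:
    """Argmax class; exact ties resolve to 'left' (documented convention)."""
    p_left, p_right = predict(model, x)
    return "right" if p_right > p_left else "left"
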