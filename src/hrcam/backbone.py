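"""CNN backbones with named tap points, stage-1 training, feature harvest.

A *tap* is a named intermediate activation of the network.  The default
tap set follows the pre-downsampling rule: the last activation at each
spatial resolution (i.e. the output feeding a pooling or strided
convolution) plus the final convolutional output.  Feature maps
harvested at these taps are what the multi-scale activation-map head
consumes.

Two registry architectures are provided: ``"simple"``, a three-stage
plain CNN sized for 64x64 desk-scale experiments, and ``"resnet_small"``,
a compact residual network demonstrating that tap enumeration handles
skip connections and strided downsampling.  Both end in global average
pooling and a softmax classification head, so the final dense weights
are directly usable for classic GAP-based class activation maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import roc_auc_score

from ._nn import (Adam, Add, Conv2d, Dense, GlobalAvgPool, MaxPool2d,
                  Network, Node, ReLU, softmax, softmax_cross_entropy)
from .augment import augment_batch
from .simulate import LabeledImage


@dataclass
class TapSpec:
    """Ordered tap points: layer ids, channel counts, spatial sizes."""

    layer_ids: list[str]
    channels: list[int]
    spatial_sizes: list[tuple[int, int]]

    def __post_init__(self) -> None:
        k = len(self.layer_ids)
        if k < 1:
            raise ValueError("TapSpec needs at least one tap")
        if len(self.channels) != k or len(self.spatial_sizes) != k:
            raise ValueError("TapSpec field lengths disagree")
        if any(c <= 0 for c in self.channels):
            raise ValueError("channel counts must be positive")

    @property
    def k(self) -> int:
        return len(self.layer_ids)


@dataclass
class TrainConfig:
    """Hyperparameters shared by both training stages.

    Defaults: Adam at learning rate 1e-3, batch 32, categorical
    cross-entropy, 20% validation split, flip/shift/rotate augmentation
    on, early stopping on validation loss with patience 5.
    """

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    validation_fraction: float = 0.2
    weight_decay: float = 0.0
    seed: int = 0
    augment_flip: bool = True
    augment_shift: bool = True
    augment_rotate: bool = True
    early_stop_patience: int = 5

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation fraction must be in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FeatureBundle:
    """Feature maps harvested at each tap for one input image.

    ``taps[i]`` is an array of shape (m_i, h_i, w_i) holding the m_i
    feature maps of tap i, in TapSpec order.
    """

    taps: list[np.ndarray]
    tap_spec: TapSpec
    sample_id: str = ""
    model_fingerprint: str = ""

    @property
    def total_maps(self) -> int:
        return int(sum(t.shape[0] for t in self.taps))


# ---------------------------------------------------------------------------
# Architecture registry
# ---------------------------------------------------------------------------

def _build_simple(input_size: tuple[int, int], class_count: int,
                  widths: tuple[int, ...] = (8, 16, 32)) -> Network:
    """Plain CNN: two 3x3 conv+ReLU per resolution stage, 2x2 max-pool
    between stages.  The tap at each stage is the second ReLU output."""
    nodes: list[Node] = []
    prev, in_ch = "input", 1
    for s, width in enumerate(widths, start=1):
        nodes.append(Node(f"conv{s}a", Conv2d(in_ch, width), [prev]))
        nodes.append(Node(f"relu{s}a", ReLU(), [f"conv{s}a"]))
        nodes.append(Node(f"conv{s}b", Conv2d(width, width), [f"relu{s}a"]))
        nodes.append(Node(f"relu{s}b", ReLU(), [f"conv{s}b"]))
        prev = f"relu{s}b"
        if s < len(widths):
            nodes.append(Node(f"pool{s}", MaxPool2d(2), [prev], downsamples=True))
            prev = f"pool{s}"
        in_ch = width
    nodes.append(Node("gap", GlobalAvgPool(), [prev]))
    nodes.append(Node("fc", Dense(widths[-1], class_count), ["gap"]))
    return Network(nodes)


def _build_resnet_small(input_size: tuple[int, int], class_count: int
                        ) -> Network:
    def block(nodes: list[Node], tag: str, ch: int, src: str) -> str:
        nodes.append(Node(f"{tag}_conv1", Conv2d(ch, ch), [src]))
        nodes.append(Node(f"{tag}_relu1", ReLU(), [f"{tag}_conv1"]))
        nodes.append(Node(f"{tag}_conv2", Conv2d(ch, ch), [f"{tag}_relu1"]))
        nodes.append(Node(f"{tag}_add", Add(), [f"{tag}_conv2", src]))
        nodes.append(Node(f"{tag}_relu2", ReLU(), [f"{tag}_add"]))
        return f"{tag}_relu2"

    nodes: list[Node] = [
        Node("stem_conv", Conv2d(1, 8), ["input"]),
        Node("stem_relu", ReLU(), ["stem_conv"]),
    ]
    prev = "stem_relu"
    for s, ch in enumerate((16, 32), start=1):
        in_ch = 8 if s == 1 else 16
        nodes.append(Node(f"ds{s}_conv", Conv2d(in_ch, ch, stride=2), [prev],
                          downsamples=True))
        nodes.append(Node(f"ds{s}_relu", ReLU(), [f"ds{s}_conv"]))
        prev = block(nodes, f"b{s}", ch, f"ds{s}_relu")
    nodes.append(Node("gap", GlobalAvgPool(), [prev]))
    nodes.append(Node("fc", Dense(32, class_count), ["gap"]))
    return Network(nodes)


ARCHITECTURES = {
    "simple": _build_simple,
    "resnet_small": _build_resnet_small,
}


def default_tap_spec(network: Network, input_size: tuple[int, int]) -> TapSpec:
    """Enumerate pre-downsampling taps plus the final convolutional output.

    Runs a dummy forward pass and records, in depth order, the input
    activation of every downsampling node, then the activation feeding
    global average pooling (the final convolutional output).
    """
    h, w = input_size
    acts = network.forward(np.zeros((1, 1, h, w)))
    tap_names: list[str] = []
    for node in network.nodes:
        if node.downsamples:
            tap_names.append(node.inputs[0])
        if isinstance(node.layer, GlobalAvgPool):
            final = node.inputs[0]
            if final not in tap_names:
                tap_names.append(final)
    channels = [int(acts[n].shape[1]) for n in tap_names]
    sizes = [(int(acts[n].shape[2]), int(acts[n].shape[3])) for n in tap_names]
    return TapSpec(tap_names, channels, sizes)


# ---------------------------------------------------------------------------
# Classifier model / results
# ---------------------------------------------------------------------------

class CNNClassifier:
    """A CNN image classifier with GAP + softmax head and named taps.

    Construct via :func:`build_backbone`, then call :meth:`fit` with a
    list of labeled images; ``fit`` returns a :class:`ClassifierResults`
    wrapping this (now trained) model.
    """

    def __init__(self, arch_name: str, input_size: tuple[int, int],
                 class_count: int):
        if arch_name not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {arch_name!r}; "
                             f"registry has {sorted(ARCHITECTURES)}")
        h, w = input_size
        factor = 4  # both registry nets downsample twice
        if h < 2 * factor or w < 2 * factor:
            raise ValueError(f"input {input_size} smaller than total "
                             f"downsampling factor {factor}")
        self.arch_name = arch_name
        self.input_size = (h, w)
        self.class_count = class_count
        self.network = ARCHITECTURES[arch_name]((h, w), class_count)
        self.network.init_params(np.random.default_rng(0))
        self.tap_spec = default_tap_spec(self.network, (h, w))
        self.trained = False

    # -- inference ---------------------------------------------------------

    def _as_batch(self, images) -> np.ndarray:
        # intensities arrive in [0,1]; center them so early layers see a
        # zero-mean signal (fixed preprocessing, part of the model contract)
        arrs = [im.pixels if isinstance(im, LabeledImage) else np.asarray(im)
                for im in images]
        x = np.stack(arrs)[:, None, :, :]
        if x.shape[2:] != self.input_size:
            raise ValueError(f"input size {x.shape[2:]} does not match "
                             f"model input {self.input_size}")
        return x - 0.5

    def predict_proba(self, images) -> np.ndarray:
        acts = self.network.forward(self._as_batch(images))
        return softmax(acts[self.network.output_name])

    def predict(self, images) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)

    @property
    def head_weights(self) -> np.ndarray:
        """Final dense layer weights, shape (C, m_k)."""
        return self.network.by_name["fc"].layer.params["W"]

    @property
    def final_tap(self) -> str:
        return self.tap_spec.layer_ids[-1]

    def fingerprint(self) -> str:
        return self.network.param_fingerprint()

    # -- training ----------------------------------------------------------

    def fit(self, dataset: list[LabeledImage],
            config: TrainConfig | None = None) -> "ClassifierResults":
        config = config or TrainConfig()
        config.validate()
        labels = np.array([im.label for im in dataset])
        if len(np.unique(labels)) < 2:
            raise ValueError("dataset must contain at least 2 classes")
        if labels.min() < 0 or labels.max() >= self.class_count:
            raise ValueError("labels out of range for class_count")

        rng = np.random.default_rng(config.seed)
        self.network.init_params(np.random.default_rng(config.seed + 1))
        tr_idx, va_idx = stratified_split(labels, config.validation_fraction,
                                          config.seed)
        raw = np.stack([im.pixels for im in dataset])  # [0,1], pre-centering
        if raw.shape[1:] != self.input_size:
            raise ValueError("dataset image size does not match model input")
        x_tr, y_tr = raw[tr_idx], labels[tr_idx]
        x_va = raw[va_idx][:, None] - 0.5
        y_va = labels[va_idx]

        opt = Adam(self.network.layers(), lr=config.learning_rate)
        history = []
        best_val, best_state, patience = np.inf, None, 0
        for epoch in range(config.epochs):
            order = rng.permutation(len(x_tr))
            losses = []
            for start in range(0, len(order), config.batch_size):
                idx = order[start:start + config.batch_size]
                xb = x_tr[idx]
                if config.augment_flip or config.augment_shift or config.augment_rotate:
                    xb = augment_batch(xb, rng, flip=config.augment_flip,
                                       do_shift=config.augment_shift,
                                       do_rotate=config.augment_rotate)
                acts = self.network.forward(xb[:, None] - 0.5)
                loss, g = softmax_cross_entropy(acts[self.network.output_name],
                                                y_tr[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                self.network.zero_grad()
                self.network.backward(g)
                opt.step()
                losses.append(loss)
            val_logits = self.network.forward(x_va)[self.network.output_name]
            val_loss, _ = softmax_cross_entropy(val_logits, y_va)
            val_acc = float((val_logits.argmax(axis=1) == y_va).mean())
            history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                            "val_loss": val_loss, "val_acc": val_acc})
            if val_loss < best_val - 1e-6:
                best_val, best_state, patience = val_loss, self.network.get_state(), 0
            else:
                patience += 1
                if patience >= config.early_stop_patience:
                    break
        if best_state is not None:
            self.network.set_state(best_state)
        self.trained = True

        proba = self.predict_proba([dataset[i] for i in va_idx])
        val_acc = float((proba.argmax(axis=1) == y_va).mean())
        if self.class_count == 2:
            val_auroc = float(roc_auc_score(y_va, proba[:, 1]))
        else:
            val_auroc = float(roc_auc_score(y_va, proba, multi_class="ovr"))
        return ClassifierResults(
            model=self, config=config,
            history=pd.DataFrame(history),
            val_indices=np.asarray(va_idx), train_indices=np.asarray(tr_idx),
            val_accuracy=val_acc, val_auroc=val_auroc)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save parameters (.npz) plus a YAML sidecar describing the model."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.network.get_state())
        sidecar = {
            "arch_name": self.arch_name,
            "input_size": list(self.input_size),
            "class_count": self.class_count,
            "trained": self.trained,
            "tap_spec": {
                "layer_ids": self.tap_spec.layer_ids,
                "channels": self.tap_spec.channels,
                "spatial_sizes": [list(s) for s in self.tap_spec.spatial_sizes],
            },
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        model = cls(meta["arch_name"], tuple(meta["input_size"]),
                    meta["class_count"])
        with np.load(path.with_suffix(".npz")) as data:
            model.network.set_state({k: data[k] for k in data.files})
        model.trained = bool(meta["trained"])
        return model


@dataclass
class ClassifierResults:
    """Stage-1 training results: the trained model plus diagnostics."""

    model: CNNClassifier
    config: TrainConfig
    history: pd.DataFrame
    val_indices: np.ndarray
    train_indices: np.ndarray
    val_accuracy: float
    val_auroc: float

    def summary(self) -> str:
        lines = [
            "CNN classifier (stage 1)",
            "=" * 40,
            f"architecture:      {self.model.arch_name}",
            f"input size:        {self.model.input_size}",
            f"classes:           {self.model.class_count}",
            f"taps (k):          {self.model.tap_spec.k} "
            f"{self.model.tap_spec.layer_ids}",
            f"epochs run:        {len(self.history)}",
            f"final train loss:  {self.history['train_loss'].iloc[-1]:.4f}",
            f"validation acc:    {self.val_accuracy:.4f}",
            f"validation AU-ROC: {self.val_auroc:.4f}",
        ]
        return "\n".join(lines)


def build_backbone(arch_name: str, input_size: tuple[int, int],
                   class_count: int) -> CNNClassifier:
    """Instantiate an untrained registry architecture with its TapSpec."""
    return CNNClassifier(arch_name, input_size, class_count)


def stratified_split(labels: np.ndarray, validation_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic per-class split; returns (train_idx, val_idx)."""
    rng = np.random.default_rng(seed)
    tr, va = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(validation_fraction * len(idx))))
        va.extend(idx[:n_val])
        tr.extend(idx[n_val:])
    return np.sort(np.array(tr)), np.sort(np.array(va))


# ---------------------------------------------------------------------------
# Feature harvesting
# ---------------------------------------------------------------------------

def harvest_features(model: CNNClassifier, image,
                     tap_spec: TapSpec | None = None) -> FeatureBundle:
    """Forward-propagate one image and collect feature maps at the taps.

    Pure read-only operation: model parameters are untouched and two
    calls on the same image return identical bundles.
    """
    spec = tap_spec or model.tap_spec
    sample_id = image.sample_id if isinstance(image, LabeledImage) else ""
    acts = model.network.forward(model._as_batch([image]))
    taps = [acts[name][0].copy() for name in spec.layer_ids]
    for t, m in zip(taps, spec.channels):
        if t.shape[0] != m:
            raise ValueError("harvested channel count disagrees with TapSpec")
    return FeatureBundle(taps=taps, tap_spec=spec, sample_id=sample_id,
                         model_fingerprint=model.fingerprint())


def global_average_pool(feature_map: np.ndarray) -> float:
    """Arithmetic mean of a non-empty 2-D feature map."""
    fm = np.asarray(feature_map, dtype=float)
    if fm.ndim != 2 or fm.size == 0:
        raise ValueError("feature map must be non-empty and 2-D")
    return float(fm.mean())
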