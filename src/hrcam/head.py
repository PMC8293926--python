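"""High-resolution CAM head: concatenated-GAP training and map composition.

Stage 2 of the procedure: feature maps are tapped at k layers of a
trained, *frozen* CNN, globally average pooled, and concatenated into a
vector of length N = sum(m_i).  A single dense softmax layer is trained
on that vector with categorical cross-entropy (Adam), yielding per-class
weights w^c over all N feature maps.  The high-resolution activation
map for class c is then

    A = sum_i  w^c_i * upsample(f_i),

the weighted sum over all N feature maps bilinearly upsampled to input
resolution.  No rectification is applied; signed contributions are
retained and only min-max normalization follows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._nn import Adam, Dense, softmax_cross_entropy
from .backbone import (CNNClassifier, FeatureBundle, TapSpec, TrainConfig,
                       harvest_features, stratified_split)
from .maps import ActivationMap, bilinear_upsample, min_max_normalize
from .simulate import LabeledImage


def concatenated_length(taps: TapSpec) -> int:
    """Length N of the concatenated GAP vector: the sum of per-tap
    channel counts."""
    return int(sum(taps.channels))


@dataclass
class HeadWeights:
    """Per-class dense weights over the concatenated GAP vector.

    ``W`` has shape (C, N) with N = sum(m_i); ``tap_offsets[i]`` is the
    start index of tap i's block, so tap i occupies columns
    ``tap_offsets[i] : tap_offsets[i] + m_i``.
    """

    tap_spec: TapSpec
    class_count: int
    W: np.ndarray
    bias: np.ndarray
    trained: bool = False

    def __post_init__(self) -> None:
        n = concatenated_length(self.tap_spec)
        if self.W.shape != (self.class_count, n):
            raise ValueError(f"W shape {self.W.shape} != "
                             f"({self.class_count}, {n})")
        if self.bias.shape != (self.class_count,):
            raise ValueError("bias length must equal class count")

    @property
    def n(self) -> int:
        return concatenated_length(self.tap_spec)

    @property
    def tap_offsets(self) -> list[int]:
        return [0] + list(np.cumsum(self.tap_spec.channels[:-1]))

    def predict_logits(self, features: np.ndarray) -> np.ndarray:
        return features @ self.W.T + self.bias

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), W=self.W, bias=self.bias)
        sidecar = {
            "n": self.n,
            "class_count": self.class_count,
            "tap_offsets": [int(o) for o in self.tap_offsets],
            "trained": self.trained,
            "tap_spec": {
                "layer_ids": self.tap_spec.layer_ids,
                "channels": self.tap_spec.channels,
                "spatial_sizes": [list(s) for s in self.tap_spec.spatial_sizes],
            },
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "HeadWeights":
        path = Path(path)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        ts = meta["tap_spec"]
        spec = TapSpec(ts["layer_ids"], ts["channels"],
                       [tuple(s) for s in ts["spatial_sizes"]])
        with np.load(path.with_suffix(".npz")) as data:
            return cls(tap_spec=spec, class_count=meta["class_count"],
                       W=data["W"], bias=data["bias"],
                       trained=bool(meta["trained"]))


def build_head(model: CNNClassifier, taps: TapSpec | None = None
               ) -> HeadWeights:
    """Construct an untrained head for ``model`` and freeze its backbone."""
    taps = taps or model.tap_spec
    for name in taps.layer_ids:
        if name not in model.network.by_name:
            raise ValueError(f"tap {name!r} not present in model")
    model.network.set_trainable(False)
    n = concatenated_length(taps)
    return HeadWeights(tap_spec=taps, class_count=model.class_count,
                       W=np.zeros((model.class_count, n)),
                       bias=np.zeros(model.class_count))


def concat_gap_features(model: CNNClassifier, images,
                        taps: TapSpec) -> np.ndarray:
    """Concatenated GAP vectors for a list of images, shape (S, N)."""
    x = model._as_batch(images)
    feats = []
    for start in range(0, len(x), 64):
        acts = model.network.forward(x[start:start + 64])
        feats.append(np.concatenate(
            [acts[name].mean(axis=(2, 3)) for name in taps.layer_ids], axis=1))
    return np.concatenate(feats, axis=0)


def fit_dense_softmax(x_tr: np.ndarray, y_tr: np.ndarray,
                      x_va: np.ndarray, y_va: np.ndarray,
                      config: TrainConfig
                      ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Minibatch-Adam softmax regression with early stopping.

    The optimization core of head training, exposed separately so the
    convex objective can be checked against independent optimizers.
    Returns ``(W, bias, history)`` for the epoch with the best
    validation loss.
    """
    classes = int(max(y_tr.max(), y_va.max())) + 1
    dense = Dense(x_tr.shape[1], classes)
    rng = np.random.default_rng(config.seed + 2)
    dense.params["W"] = rng.normal(0.0, 0.01, size=(classes, x_tr.shape[1]))
    dense.params["b"] = np.zeros(classes)
    opt = Adam([dense], lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 3)

    history = []
    best_val, best_state, patience = np.inf, None, 0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = dense.forward(x_tr[idx])
            loss, g = softmax_cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite head training loss")
            dense.zero_grad()
            dense.backward(g)
            if config.weight_decay > 0:
                dense.grads["W"] += config.weight_decay * dense.params["W"]
            opt.step()
            losses.append(loss)
        val_loss, _ = softmax_cross_entropy(dense.forward(x_va), y_va)
        val_acc = float((dense.forward(x_va).argmax(axis=1) == y_va).mean())
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "val_acc": val_acc})
        if val_loss < best_val - 1e-7:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in dense.params.items()}
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience:
                break
    if best_state is not None:
        dense.params.update(best_state)
    return (dense.params["W"].copy(), dense.params["b"].copy(),
            pd.DataFrame(history))


def train_head(head: HeadWeights, model: CNNClassifier,
               dataset: list[LabeledImage],
               config: TrainConfig | None = None) -> "HRCAMResults":
    """Train the dense head on frozen-backbone GAP features (Adam).

    The backbone is untouched by construction (features are computed
    once up front); its parameter fingerprint is asserted bit-identical
    before and after as the freezing contract.
    """
    config = config or TrainConfig(epochs=50, weight_decay=1e-4)
    config.validate()
    if not model.trained:
        raise ValueError("stage-1 model must be trained before head training")
    if any(layer.trainable for layer in model.network.layers()):
        raise ValueError("unfrozen backbone detected; call build_head first")
    fp_before = model.fingerprint()

    labels = np.array([im.label for im in dataset])
    if len(np.unique(labels)) < 2:
        raise ValueError("dataset must contain at least 2 classes")
    feats = concat_gap_features(model, dataset, head.tap_spec)
    tr_idx, va_idx = stratified_split(labels, config.validation_fraction,
                                      config.seed)
    # GAP scales differ by orders of magnitude between shallow and deep
    # taps; optimize in standardized coordinates (train-split statistics)
    # and fold the affine change of variables back into the stored
    # raw-feature weights afterwards -- same model family, well
    # conditioned.  A small L2 penalty (in standardized space) keeps
    # weights on dead/uninformative features at zero.
    mu = feats[tr_idx].mean(axis=0)
    sd = np.maximum(feats[tr_idx].std(axis=0), 1e-6)
    z = (feats - mu) / sd

    w_z, b_z, history = fit_dense_softmax(z[tr_idx], labels[tr_idx],
                                          z[va_idx], labels[va_idx], config)

    # fold standardization back: w_raw = w_z / sd, b_raw = b - w_z . mu/sd
    head.W = w_z / sd[None, :]
    head.bias = b_z - (w_z * (mu / sd)[None, :]).sum(axis=1)
    head.trained = True

    fp_after = model.fingerprint()
    if fp_after != fp_before:
        raise RuntimeError("backbone parameters changed during head training")

    logits = head.predict_logits(feats[va_idx])
    y_va = labels[va_idx]
    val_acc = float((logits.argmax(axis=1) == y_va).mean())
    final_loss, _ = softmax_cross_entropy(logits, y_va)
    return HRCAMResults(model=model, head=head, config=config,
                        history=pd.DataFrame(history),
                        val_accuracy=val_acc, final_val_loss=float(final_loss))


# ---------------------------------------------------------------------------
# Map composition
# ---------------------------------------------------------------------------

def compose_map(bundle: FeatureBundle, head: HeadWeights, class_id: int,
                out_size: tuple[int, int]) -> ActivationMap:
    """Weighted sum of upsampled feature maps (unnormalized, signed).

    Per tap, the weighted channel sum is formed at native resolution and
    bilinearly upsampled once; by linearity of the interpolation this
    equals upsampling every channel individually before weighting.
    """
    if bundle.tap_spec.layer_ids != head.tap_spec.layer_ids:
        raise ValueError("bundle and head disagree on tap layout")
    if not 0 <= class_id < head.class_count:
        raise ValueError(f"unknown class id {class_id}")
    acc = np.zeros(out_size)
    offsets = head.tap_offsets
    for i, fmap in enumerate(bundle.taps):
        m = fmap.shape[0]
        w = head.W[class_id, offsets[i]:offsets[i] + m]
        weighted = np.tensordot(w, fmap, axes=(0, 0))
        acc += (weighted if weighted.shape == tuple(out_size)
                else bilinear_upsample(weighted, out_size))
    return ActivationMap(values=acc, class_id=class_id, normalized=False,
                         source_method="hrcam")


def hrcam_explain(model: CNNClassifier, head: HeadWeights, image,
                  class_id: int | None = None) -> ActivationMap:
    """Harvest -> compose -> min-max normalize for one image.

    ``class_id`` defaults to the head's own predicted class.
    """
    bundle = harvest_features(model, image, head.tap_spec)
    if class_id is None:
        feats = np.concatenate([t.mean(axis=(1, 2)) for t in bundle.taps])
        class_id = int(head.predict_logits(feats[None])[0].argmax())
    amap = compose_map(bundle, head, class_id, model.input_size)
    return min_max_normalize(amap)


# ---------------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------------

class HRCAM:
    """Stage-2 model: a dense head over multi-tap GAP features.

    Parameters
    ----------
    classifier : trained stage-1 :class:`CNNClassifier`
    taps : optional TapSpec override (default: the classifier's own,
        i.e. every pre-downsampling layer plus the final one)
    """

    def __init__(self, classifier: CNNClassifier,
                 taps: TapSpec | None = None):
        self.classifier = classifier
        self.taps = taps or classifier.tap_spec
        self.head = build_head(classifier, self.taps)

    def fit(self, dataset: list[LabeledImage],
            config: TrainConfig | None = None) -> "HRCAMResults":
        return train_head(self.head, self.classifier, dataset, config)


@dataclass
class HRCAMResults:
    """Trained head plus diagnostics; explanation hangs off this object."""

    model: CNNClassifier
    head: HeadWeights
    config: TrainConfig
    history: pd.DataFrame
    val_accuracy: float
    final_val_loss: float

    def explain(self, image, class_id: int | None = None) -> ActivationMap:
        return hrcam_explain(self.model, self.head, image, class_id)

    def layer_weight_distribution(self, class_id: int):
        from .evaluation import layer_weight_distribution
        return layer_weight_distribution(self.head, class_id)

    def summary(self) -> str:
        spec = self.head.tap_spec
        lines = [
            "HR-CAM head (stage 2, frozen backbone)",
            "=" * 44,
            f"taps (k):            {spec.k} {spec.layer_ids}",
            f"concatenated N:      {self.head.n}",
            f"classes:             {self.head.class_count}",
            f"epochs run:          {len(self.history)}",
            f"final val loss:      {self.final_val_loss:.4f}",
            f"head validation acc: {self.val_accuracy:.4f}",
        ]
        for _, row in self.layer_weight_share_table().iterrows():
            lines.append(f"  |w| share {row['layer_id']:<12s} "
                         f"{row['share']:.3f}")
        return "\n".join(lines)

    def layer_weight_share_table(self) -> pd.DataFrame:
        from .evaluation import layer_weight_distribution
        frames = []
        for c in range(self.head.class_count):
            df = layer_weight_distribution(self.head, c).summary
            df = df.assign(class_id=c)
            frames.append(df)
        df = pd.concat(frames, ignore_index=True)
        return (df.groupby("layer_id", sort=False)["share"]
                .mean().reset_index())
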