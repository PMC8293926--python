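"""Mask-based quantitative evaluation of activation maps.

Protocol: normalized maps are binarized at fixed intensity thresholds
(default 0.3, 0.5, 0.8; ties count as detections) and compared pixel by
pixel with the ground-truth abnormality mask, giving per-image
sensitivity (true-positive rate) and specificity (true-negative rate).
Methods are compared by median/IQR per threshold and by a paired
two-sided t-test on the per-image rates (the same test images underlie
every method); an unpaired Welch variant is available.

Evaluation is restricted to images that carry a non-empty ground-truth
mask (the abnormal test images); a rate whose denominator is empty is
recorded as missing and excluded from summaries.

Also provided: the per-tap head-weight distribution diagnostic (which
tap blocks carry the discriminative weight mass) and standard
classifier metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

from .head import HeadWeights
from .maps import ActivationMap
from .simulate import LabeledImage

DEFAULT_THRESHOLDS = (0.3, 0.5, 0.8)


def binarize(amap: ActivationMap, threshold: float) -> np.ndarray:
    """Binary detection mask: pixel is positive iff value >= threshold."""
    if not amap.normalized:
        raise ValueError("binarize expects a min-max normalized map")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return amap.values >= threshold


def sensitivity_specificity(pred: np.ndarray, truth: np.ndarray
                            ) -> tuple[float | None, float | None]:
    """Pixel-wise TPR and TNR of a binary prediction against a mask.

    Returns ``None`` for a rate whose denominator is zero (no positive
    pixels in truth -> sensitivity undefined; no negatives ->
    specificity undefined).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec


@dataclass
class EvalRecord:
    sample_id: str
    method: str
    threshold: float
    sensitivity: float | None
    specificity: float | None


@dataclass
class MethodComparison:
    """All per-image records plus summaries and pairwise tests."""

    records: pd.DataFrame
    thresholds: tuple[float, ...]
    methods: tuple[str, ...]
    n_undefined: int = 0

    def summary(self) -> pd.DataFrame:
        """Median and quartiles of each metric per method x threshold."""
        rows = []
        for (method, thr), grp in self.records.groupby(["method", "threshold"]):
            row = {"method": method, "threshold": thr, "n": len(grp)}
            for metric in ("sensitivity", "specificity"):
                vals = grp[metric].dropna()
                row[f"{metric}_median"] = vals.median()
                row[f"{metric}_q1"] = vals.quantile(0.25)
                row[f"{metric}_q3"] = vals.quantile(0.75)
            rows.append(row)
        return pd.DataFrame(rows)

    def metric_values(self, method: str, metric: str, threshold: float
                      ) -> pd.Series:
        sub = self.records[(self.records.method == method)
                           & (self.records.threshold == threshold)]
        return sub.set_index("sample_id")[metric]


MapFn = Callable[[LabeledImage], ActivationMap]


def evaluate_methods(dataset: Sequence[LabeledImage],
                     methods: dict[str, MapFn],
                     thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                     ) -> MethodComparison:
    """Evaluate every method on every masked image at every threshold.

    ``methods`` maps a method name to a callable producing a normalized
    :class:`ActivationMap` for one image.  Images without a non-empty
    ground-truth mask are skipped (normative images carry no lesion to
    localize).
    """
    if not methods:
        raise ValueError("empty method list")
    masked = [im for im in dataset if im.mask is not None and im.mask.any()]
    if not masked:
        raise ValueError("no images with non-empty ground-truth masks")
    thresholds = tuple(float(t) for t in thresholds)
    records: list[EvalRecord] = []
    n_undefined = 0
    for im in masked:
        for name, fn in methods.items():
            amap = fn(im)
            for thr in thresholds:
                sens, spec = sensitivity_specificity(binarize(amap, thr),
                                                     im.mask)
                if sens is None or spec is None:
                    n_undefined += 1
                records.append(EvalRecord(im.sample_id, name, thr, sens, spec))
    df = pd.DataFrame([r.__dict__ for r in records])
    return MethodComparison(records=df, thresholds=thresholds,
                            methods=tuple(methods), n_undefined=n_undefined)


def compare_significance(comparison: MethodComparison, method_a: str,
                         method_b: str, metric: str, threshold: float,
                         paired: bool = True) -> tuple[float, float]:
    """Two-sided t-test between two methods on per-image metric values.

    Returns ``(p_value, mean_difference)`` with the difference taken as
    a - b.  Paired by sample by default (the same images underlie every
    method); ``paired=False`` runs Welch's unpaired variant.  Identical
    inputs give mean difference 0 and p = 1.
    """
    a = comparison.metric_values(method_a, metric, threshold).dropna()
    b = comparison.metric_values(method_b, metric, threshold).dropna()
    if paired:
        if not a.index.equals(b.index):
            raise ValueError("methods were not evaluated on the same samples")
        if len(a) < 3:
            raise ValueError("need at least 3 paired samples")
        diff = a.values - b.values
        if np.allclose(diff, 0.0):
            return 1.0, 0.0
        res = stats.ttest_rel(a.values, b.values)
        return float(res.pvalue), float(diff.mean())
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 samples per method")
    res = stats.ttest_ind(a.values, b.values, equal_var=False)
    return float(res.pvalue), float(a.mean() - b.mean())


@dataclass
class LayerWeightDistribution:
    """Per-tap absolute-weight diagnostics for one class."""

    class_id: int
    per_tap_weights: list[np.ndarray]
    summary: pd.DataFrame


def layer_weight_distribution(head: HeadWeights, class_id: int
                              ) -> LayerWeightDistribution:
    """Absolute head weights grouped by tap block, with block shares.

    Shares of total |w| mass sum to 1; a head whose mass sits entirely
    on the final block indicates the multi-scale fusion collapsed to
    the classic final-layer CAM regime.
    """
    if not head.trained:
        raise ValueError("head is untrained")
    if not 0 <= class_id < head.class_count:
        raise ValueError(f"unknown class id {class_id}")
    w = np.abs(head.W[class_id])
    total = w.sum()
    offsets = head.tap_offsets
    per_tap, rows = [], []
    for i, m in enumerate(head.tap_spec.channels):
        block = w[offsets[i]:offsets[i] + m]
        per_tap.append(block.copy())
        rows.append({"layer_id": head.tap_spec.layer_ids[i],
                     "n_maps": m,
                     "sum": float(block.sum()),
                     "mean": float(block.mean()),
                     "share": float(block.sum() / total) if total > 0
                     else 1.0 / head.tap_spec.k})
    return LayerWeightDistribution(class_id=class_id,
                                   per_tap_weights=per_tap,
                                   summary=pd.DataFrame(rows))


def classifier_metrics(model, dataset: Sequence[LabeledImage]
                       ) -> dict[str, float]:
    """Accuracy, AU-ROC (rank statistic) and F1 on a labeled dataset.

    AU-ROC uses the class-1 predicted probability for binary problems
    and one-vs-rest averaging otherwise; F1 is micro-averaged for
    multi-class, standard binary F1 otherwise.
    """
    labels = np.array([im.label for im in dataset])
    if len(np.unique(labels)) < 2:
        raise ValueError("AU-ROC undefined on a single-class dataset")
    proba = model.predict_proba(list(dataset))
    pred = proba.argmax(axis=1)
    acc = float((pred == labels).mean())
    if proba.shape[1] == 2:
        auroc = float(roc_auc_score(labels, proba[:, 1]))
        f1 = float(f1_score(labels, pred))
    else:
        auroc = float(roc_auc_score(labels, proba, multi_class="ovr"))
        f1 = float(f1_score(labels, pred, average="micro"))
    return {"accuracy": acc, "auroc": auroc, "f1": f1}
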