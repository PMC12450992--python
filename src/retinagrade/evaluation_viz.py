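"""Metrics and saliency: top-k accuracy, one-vs-rest sensitivity/specificity,
confusion matrices, gradient-weighted class-activation heatmaps, and Dice
agreement between binarised heatmaps and ground-truth lesion masks.

The classifier has no segmentation head; lesion localisation is read out as
saliency.  A heatmap is the channel-wise gradient-weighted sum of the fused
feature map (ReLU'd, min-max normalised, bilinearly upsampled), thresholded
and cleaned of sub-minimum connected components before Dice scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from skimage import morphology, transform
from sklearn.metrics import confusion_matrix as _sk_confusion

from .nn import Tensor
from .network import DualBranchClassifier
from .training import preprocess

__all__ = [
    "MetricsReport", "topk_accuracy", "sensitivity_specificity",
    "confusion", "dice", "attention_heatmap", "binarize_heatmap",
    "heatmap_dice_eval",
    "evaluate_model", "save_overlay", "save_convergence_plot",
]


@dataclass
class MetricsReport:
    top1: float
    top5: float
    confusion: np.ndarray
    per_class: list[tuple[float, float]] = field(default_factory=list)
    dice_per_sample: list[float] | None = None
    dice_mean: float | None = None

    def to_dict(self) -> dict:
        return {
            "top1": self.top1,
            "top5": self.top5,
            "confusion": self.confusion.tolist(),
            "per_class": [{"sensitivity": s, "specificity": p}
                          for s, p in self.per_class],
            "dice_mean": self.dice_mean,
        }


def topk_accuracy(probs: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Fraction of rows whose true label ranks in the top k probabilities.

    Ties are broken toward the lower class index (stable sort on -p).
    """
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    n, num_classes = probs.shape
    if not 1 <= k <= num_classes:
        raise ValueError(f"k must be in [1, {num_classes}], got {k}")
    ranked = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return float((ranked == labels[:, None]).any(axis=1).mean())


def confusion(y_true: np.ndarray, y_pred: np.ndarray, num_classes: int) -> np.ndarray:
    return _sk_confusion(y_true, y_pred, labels=np.arange(num_classes))


def sensitivity_specificity(conf: np.ndarray, class_id: int
                            ) -> tuple[float, float]:
    """One-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP).

    A class absent from the truth (or from the rest) yields NaN rather than
    a division error.
    """
    conf = np.asarray(conf)
    tp = conf[class_id, class_id]
    fn = conf[class_id].sum() - tp
    fp = conf[:, class_id].sum() - tp
    tn = conf.sum() - tp - fn - fp
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sens), float(spec)


def dice(binary_pred: np.ndarray, binary_truth: np.ndarray) -> float:
    """2|A∩B| / (|A| + |B|); two empty masks agree perfectly (1.0)."""
    a = np.asarray(binary_pred, dtype=bool)
    b = np.asarray(binary_truth, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


def attention_heatmap(model: DualBranchClassifier, image: np.ndarray,
                      class_id: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation map over the fused feature stage.

    The target logit (predicted class unless ``class_id`` given) is
    backpropagated to the fused feature map; channel weights are the
    spatially averaged gradients; the weighted sum is ReLU'd, min-max
    normalised to [0, 1] and bilinearly upsampled to image size.
    Deterministic in eval mode.
    """
    was_training = model.training
    model.eval()
    try:
        x = Tensor(preprocess(image[None]))
        fmap = model.features(x).retain_grad()
        from .nn import global_avg_pool
        logits = model.head(global_avg_pool(fmap))
        cid = int(logits.data[0].argmax()) if class_id is None else int(class_id)
        seed = np.zeros_like(logits.data)
        seed[0, cid] = 1.0
        logits.backward(seed)
        if fmap.grad is None:
            raise RuntimeError("no gradient reached the fused features; "
                               "is the model frozen?")
        weights = fmap.grad[0].mean(axis=(1, 2))            # (C,)
        cam = np.maximum((weights[:, None, None] * fmap.data[0]).sum(axis=0), 0.0)
        lo, hi = cam.min(), cam.max()
        cam = (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
        H, W = image.shape[:2]
        return transform.resize(cam, (H, W), order=1, mode="edge",
                                anti_aliasing=False)
    finally:
        model.train(was_training)


def binarize_heatmap(heat: np.ndarray, threshold: float,
                     min_component: int = 2) -> np.ndarray:
    """Threshold a [0, 1] heatmap (>= threshold) and drop connected
    components smaller than ``min_component`` pixels."""
    pred = np.asarray(heat) >= threshold
    if min_component > 1:
        # drop components strictly smaller than min_component pixels
        pred = morphology.remove_small_objects(pred, max_size=min_component - 1)
    return pred


def heatmap_dice_eval(model: DualBranchClassifier, images: np.ndarray,
                      masks: np.ndarray, threshold: float = 0.7,
                      min_component: int = 2) -> MetricsReport:
    """Binarise heatmaps at ``threshold``, drop components smaller than
    ``min_component`` px, and Dice-score them against lesion masks."""
    if masks is None:
        raise ValueError("heatmap Dice evaluation needs ground-truth masks")
    scores = []
    for img, msk in zip(images, masks):
        heat = attention_heatmap(model, img)
        pred = binarize_heatmap(heat, threshold, min_component)
        scores.append(dice(pred, msk > 0))
    return MetricsReport(top1=float("nan"), top5=float("nan"),
                         confusion=np.zeros((0, 0), dtype=int),
                         dice_per_sample=scores,
                         dice_mean=float(np.mean(scores)) if scores else None)


def evaluate_model(model: DualBranchClassifier, images: np.ndarray,
                   labels: np.ndarray, batch_size: int = 32) -> MetricsReport:
    """Classification metrics on a labelled image array."""
    model.eval()
    probs = []
    for i in range(0, len(images), batch_size):
        probs.append(model.predict(preprocess(images[i:i + batch_size])))
    probs = np.concatenate(probs)
    labels = np.asarray(labels)
    k = probs.shape[1]
    pred = probs.argmax(axis=1)
    conf = confusion(labels, pred, k)
    per_class = [sensitivity_specificity(conf, c) for c in range(k)]
    return MetricsReport(
        top1=topk_accuracy(probs, labels, 1),
        top5=topk_accuracy(probs, labels, min(5, k)),
        confusion=conf,
        per_class=per_class,
    )


def save_overlay(image: np.ndarray, heatmap: np.ndarray, path) -> None:
    """Write an image / heatmap / overlay triptych."""
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].imshow(image)
    axes[0].set_title("image")
    axes[1].imshow(heatmap, cmap="jet", vmin=0, vmax=1)
    axes[1].set_title("lesion confidence")
    axes[2].imshow(image)
    axes[2].imshow(heatmap, cmap="jet", vmin=0, vmax=1, alpha=0.45)
    axes[2].set_title("overlay")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_convergence_plot(history, path) -> None:
    """Training-loss / validation-accuracy convergence curves."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(history["epoch"], history["train_loss"], label="train loss")
    ax1.plot(history["epoch"], history["val_loss"], label="val loss")
    ax1.set_xlabel("epoch")
    ax1.set_ylabel("cross-entropy loss")
    ax2 = ax1.twinx()
    ax2.plot(history["epoch"], history["val_top1"], color="tab:green",
             label="val top-1")
    ax2.set_ylabel("validation top-1")
    lines, labels = ax1.get_legend_handles_labels()
    l2, lab2 = ax2.get_legend_handles_labels()
    ax1.legend(lines + l2, labels + lab2, loc="center right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
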