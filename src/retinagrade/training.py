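"""Training protocol: stratified splits, class-weighted loss, minority
oversampling, photometric/geometric augmentation, Adam with cosine
annealing, and early stopping on validation top-1.

Class imbalance is handled two ways, mirroring screening practice for
heavily skewed grade distributions: inverse-frequency class weights in the
cross-entropy, and replication-with-augmentation of minority-class samples
(feature-space interpolation is ill-defined on raw fundus images, so
minority enrichment is done by resampling and perturbing real pixels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .nn import Adam, Tensor, cross_entropy, no_grad
from .network import DualBranchClassifier

__all__ = [
    "TrainConfig", "SplitManifest", "ArrayDataset",
    "stratified_split", "class_weights", "oversample_minority",
    "augment", "cosine_lr", "train", "preprocess",
]


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 20
    min_lr: float = 1e-6
    # (train pool fraction, test fraction, validation fraction of train pool)
    split: tuple[float, float, float] = (0.8, 0.2, 0.1)
    rotation_deg: float = 15.0
    blur_sigma: tuple[float, float] = (0.5, 1.0)
    brightness_jitter: float = 0.1
    augment_train: bool = True
    oversample: bool = False
    oversample_ratio: float = 1.0
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self):
        tr, te, va = self.split
        if not (0 < tr < 1 and 0 < te < 1 and 0 <= va < 1):
            raise ValueError(f"split fractions out of range: {self.split}")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class SplitManifest:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


@dataclass
class ArrayDataset:
    """In-memory labelled images; the unit the training loop consumes."""
    images: np.ndarray           # (N, H, W, 3) uint8
    labels: np.ndarray           # (N,) int
    masks: np.ndarray | None = None


def _largest_remainder(n: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of n items to len(fractions) buckets."""
    raw = n * fractions
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def stratified_split(labels: np.ndarray, cfg: TrainConfig,
                     num_classes: int | None = None) -> SplitManifest:
    """Disjoint, exhaustive, per-class proportional split (largest remainder).

    The test fraction is taken from each class first; the validation
    fraction is then carved out of each class's train pool, so the default
    (0.8, 0.2, 0.1) yields 72/8/20 per hundred samples of a class.  When a
    ``num_classes`` universe is given, every class in it must be populated.
    """
    labels = np.asarray(labels)
    if num_classes is not None:
        counts = np.bincount(labels, minlength=num_classes)
        if (counts == 0).any():
            missing = int(np.nonzero(counts == 0)[0][0])
            raise ValueError(f"class {missing} has zero samples")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,)))
    tr_frac, te_frac, va_frac = cfg.split
    train_ids, val_ids, test_ids = [], [], []
    for cls in np.unique(labels):
        ids = np.nonzero(labels == cls)[0]
        rng.shuffle(ids)
        n_pool, n_test = _largest_remainder(len(ids), np.array([tr_frac, te_frac]))
        pool, test = ids[:n_pool], ids[n_pool:]
        n_train, n_val = _largest_remainder(len(pool), np.array([1 - va_frac, va_frac]))
        train_ids.append(pool[:n_train])
        val_ids.append(pool[n_train:])
        test_ids.append(test)
    return SplitManifest(train=np.sort(np.concatenate(train_ids)),
                         val=np.sort(np.concatenate(val_ids)),
                         test=np.sort(np.concatenate(test_ids)))


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights, normalised to mean 1."""
    counts = np.asarray(counts, dtype=float)
    if (counts <= 0).any():
        bad = np.nonzero(counts <= 0)[0]
        raise ValueError(f"class {bad[0]} has non-positive count; weights undefined")
    w = 1.0 / counts
    return w / w.mean()


def oversample_minority(train_ids: np.ndarray, labels: np.ndarray, rng,
                        target_ratio: float = 1.0) -> np.ndarray:
    """Replicate minority-class training ids up to ratio * majority count.

    Originals are all retained; replicas are drawn uniformly with the given
    generator (augmentation perturbs them at load time, so replicas are not
    pixel-identical copies in the training stream).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    train_ids = np.asarray(train_ids)
    lab = np.asarray(labels)[train_ids]
    out = [train_ids]
    majority = max(np.bincount(lab, minlength=1).max(), 1)
    target = int(np.ceil(target_ratio * majority))
    for cls in np.unique(lab):
        ids = train_ids[lab == cls]
        deficit = target - len(ids)
        if deficit > 0:
            out.append(rng.choice(ids, size=deficit, replace=True))
    return np.concatenate(out)


def augment(image: np.ndarray, label: int, rng, cfg: TrainConfig
            ) -> tuple[np.ndarray, int]:
    """Random rotation (±rotation_deg), Gaussian blur (sigma in blur_sigma),
    brightness jitter.  Label, dtype and shape are preserved."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = image.astype(float)
    if cfg.rotation_deg > 0:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
    lo, hi = cfg.blur_sigma
    sigma = rng.uniform(lo, hi)
    out = ndimage.gaussian_filter(out, sigma=(sigma, sigma, 0))
    if cfg.brightness_jitter > 0:
        out = out * rng.uniform(1 - cfg.brightness_jitter, 1 + cfg.brightness_jitter)
    return np.clip(out, 0, 255).astype(image.dtype), label


def cosine_lr(epoch: int, cfg: TrainConfig) -> float:
    """Cosine annealing from lr0 at epoch 0 to min_lr at max_epochs."""
    if not 0 <= epoch <= cfg.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.max_epochs}]")
    t, T = epoch, cfg.max_epochs
    return cfg.min_lr + 0.5 * (cfg.lr0 - cfg.min_lr) * (1 + np.cos(np.pi * t / T))


def preprocess(images: np.ndarray) -> np.ndarray:
    """uint8 HWC images -> float32 NCHW in roughly unit range."""
    x = images.astype(np.float32) / 255.0
    x = (x - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _top1(model: DualBranchClassifier, x: np.ndarray, y: np.ndarray,
          batch_size: int) -> tuple[float, float]:
    """(top-1 accuracy, mean unweighted CE loss) over a labelled array."""
    correct, losses = 0, []
    with no_grad():
        for i in range(0, len(x), batch_size):
            xb, yb = x[i:i + batch_size], y[i:i + batch_size]
            logits = model.logits(Tensor(xb))
            pred = logits.data.argmax(axis=1)
            correct += int((pred == yb).sum())
            losses.append(cross_entropy(logits, yb).data * len(yb))
    return correct / len(x), float(np.sum(losses) / len(x))


def train(model: DualBranchClassifier, data: ArrayDataset, cfg: TrainConfig,
          split: SplitManifest | None = None, restore: str = "best",
          ) -> tuple[DualBranchClassifier, pd.DataFrame]:
    """Optimise weighted cross-entropy with Adam + cosine annealing.

    Stops once validation top-1 has not improved for ``cfg.patience``
    epochs.  ``restore="best"`` (default) reloads the best-validation
    checkpoint; ``restore="final"`` keeps the last epoch's weights (useful
    at toy scale where a handful of validation samples make the best-epoch
    choice noisy).  Returns the model plus a per-epoch history (epoch, lr,
    train_loss, train_top1, val_loss, val_top1).
    """
    if restore not in ("best", "final"):
        raise ValueError(f"restore must be 'best' or 'final', got {restore!r}")
    if split is None:
        split = stratified_split(data.labels, cfg)
    if len(split.train) == 0 or len(split.val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
    shuffle_rng, aug_rng, over_rng = [np.random.default_rng(s) for s in ss.spawn(3)]

    train_ids = split.train
    if cfg.oversample:
        train_ids = oversample_minority(train_ids, data.labels, over_rng,
                                        cfg.oversample_ratio)
    counts = np.bincount(data.labels[split.train],
                         minlength=int(data.labels.max()) + 1)
    weights = class_weights(np.maximum(counts, 1)) if cfg.class_weighting else None

    x_val = preprocess(data.images[split.val])
    y_val = data.labels[split.val]
    x_train_clean = preprocess(data.images[split.train])
    y_train_clean = data.labels[split.train]

    opt = Adam(model.parameters(), lr=cfg.lr0, betas=cfg.betas)
    best_top1, best_state, best_epoch = -1.0, model.state_dict(), -1
    since_best = 0
    history = []
    for epoch in range(cfg.max_epochs):
        opt.lr = cosine_lr(epoch, cfg)
        order = shuffle_rng.permutation(len(train_ids))
        ids = train_ids[order]
        model.train()
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(ids), cfg.batch_size):
            bids = ids[i:i + cfg.batch_size]
            imgs = data.images[bids]
            if cfg.augment_train:
                imgs = np.stack([
                    augment(im, 0, aug_rng, cfg)[0] for im in imgs])
            xb = preprocess(imgs)
            yb = data.labels[bids]
            logits = model.logits(Tensor(xb))
            loss = cross_entropy(logits, yb, class_weights=weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(bids)
            seen += len(bids)
        model.eval()
        val_top1, val_loss = _top1(model, x_val, y_val, cfg.batch_size)
        train_top1, _ = _top1(model, x_train_clean, y_train_clean, cfg.batch_size)
        history.append({"epoch": epoch, "lr": opt.lr,
                        "train_loss": epoch_loss / max(seen, 1),
                        "train_top1": train_top1,
                        "val_loss": val_loss, "val_top1": val_top1})
        if val_top1 > best_top1:
            best_top1, best_state, best_epoch = val_top1, model.state_dict(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    if restore == "best":
        model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(history)
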