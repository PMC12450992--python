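"""Training protocol: splits, weights, oversampling, augmentation, schedule
and the optimisation loop."""

import numpy as np
import pytest

from retinagrade.network import ModelConfig, build_variant
from retinagrade.training import (ArrayDataset, TrainConfig, augment,
                                  class_weights, cosine_lr,
                                  oversample_minority, stratified_split,
                                  train)


def _labels(counts):
    return np.concatenate([np.full(n, g) for g, n in enumerate(counts)])


# -- stratified split ----------------------------------------------------------

def test_split_100_samples_gives_72_8_20():
    cfg = TrainConfig(seed=0)
    split = stratified_split(np.zeros(100, dtype=int), cfg)
    assert (len(split.train), len(split.val), len(split.test)) == (72, 8, 20)


def test_split_disjoint_and_exhaustive():
    labels = _labels((50, 20, 10, 8, 12))
    cfg = TrainConfig(seed=1)
    s = stratified_split(labels, cfg)
    all_ids = np.concatenate([s.train, s.val, s.test])
    assert len(all_ids) == len(labels)
    assert len(np.unique(all_ids)) == len(labels)


def test_split_stratification_within_one_sample():
    counts = (53, 21, 11, 9, 6)
    labels = _labels(counts)
    cfg = TrainConfig(seed=2)
    s = stratified_split(labels, cfg)
    for part, frac in ((s.test, 0.2), (s.val, 0.8 * 0.1), (s.train, 0.8 * 0.9)):
        got = np.bincount(labels[part], minlength=5)
        target = np.array(counts) * frac
        assert (np.abs(got - target) <= 1).all()


def test_split_deterministic_under_seed():
    labels = _labels((30, 10, 5, 5, 5))
    cfg = TrainConfig(seed=9)
    a = stratified_split(labels, cfg)
    b = stratified_split(labels, cfg)
    np.testing.assert_array_equal(a.train, b.train)
    np.testing.assert_array_equal(a.test, b.test)


def test_split_names_missing_class():
    with pytest.raises(ValueError, match="class 3"):
        stratified_split(_labels((5, 5, 5, 0, 5)), TrainConfig(), num_classes=5)


# -- class weights -------------------------------------------------------------

def test_equal_counts_give_unit_weights():
    np.testing.assert_allclose(class_weights((10, 10, 10)), 1.0)


def test_inverse_frequency_hand_oracle():
    np.testing.assert_allclose(class_weights((10, 20)), [4 / 3, 2 / 3])


def test_rarest_class_gets_largest_weight():
    # the heavily skewed five-grade distribution: the 708-sample class tops
    w = class_weights((25810, 2443, 5292, 873, 708))
    assert w.argmax() == 4
    assert (np.diff(w[np.argsort((25810, 2443, 5292, 873, 708))[::-1]]) >= 0).all()


def test_zero_count_rejected():
    with pytest.raises(ValueError, match="class"):
        class_weights((10, 0, 5))


# -- oversampling --------------------------------------------------------------

def test_balanced_manifest_unchanged():
    labels = _labels((10, 10))
    ids = np.arange(20)
    out = oversample_minority(ids, labels, np.random.default_rng(0))
    np.testing.assert_array_equal(np.sort(out), ids)


def test_minority_replicated_to_majority_count():
    labels = _labels((100, 10))
    ids = np.arange(110)
    out = oversample_minority(ids, labels, np.random.default_rng(0))
    counts = np.bincount(labels[out])
    assert counts[0] == 100 and counts[1] == 100


def test_replicas_match_seeded_sampler_oracle():
    labels = _labels((8, 3))
    ids = np.arange(11)
    out = oversample_minority(ids, labels, np.random.default_rng(5))
    minority = ids[labels == 1]
    oracle = np.random.default_rng(5).choice(minority, size=5, replace=True)
    np.testing.assert_array_equal(out[11:], oracle)
    np.testing.assert_array_equal(out[:11], ids)   # originals retained


# -- augmentation --------------------------------------------------------------

def test_augment_preserves_label_shape_dtype(rng):
    img = (rng.uniform(0, 255, size=(32, 32, 3))).astype(np.uint8)
    out, label = augment(img, 3, rng, TrainConfig())
    assert label == 3
    assert out.shape == img.shape and out.dtype == img.dtype


def test_augment_deterministic_under_seed():
    img = (np.random.default_rng(0).uniform(0, 255, (32, 32, 3))).astype(np.uint8)
    cfg = TrainConfig()
    a, _ = augment(img, 0, np.random.default_rng(4), cfg)
    b, _ = augment(img, 0, np.random.default_rng(4), cfg)
    np.testing.assert_array_equal(a, b)


def test_augment_approaches_identity_without_rotation_and_blur(rng):
    img = (rng.uniform(60, 200, size=(32, 32, 3))).astype(np.uint8)
    cfg = TrainConfig(rotation_deg=0.0, blur_sigma=(0.01, 0.01),
                      brightness_jitter=0.0)
    out, _ = augment(img, 0, rng, cfg)
    assert np.abs(out.astype(int) - img.astype(int)).max() <= 1


# -- schedule ------------------------------------------------------------------

def test_cosine_schedule_endpoints_and_midpoint():
    cfg = TrainConfig(lr0=1e-4, min_lr=0.0, max_epochs=100)
    assert cosine_lr(0, cfg) == pytest.approx(1e-4)
    assert cosine_lr(100, cfg) == pytest.approx(0.0, abs=1e-20)
    assert cosine_lr(50, cfg) == pytest.approx(5e-5)


def test_cosine_schedule_rejects_out_of_range():
    with pytest.raises(ValueError):
        cosine_lr(101, TrainConfig(max_epochs=100))


# -- training loop -------------------------------------------------------------

@pytest.fixture(scope="module")
def micro_run(tiny_dataset):
    images, masks, labels = tiny_dataset
    cfg = TrainConfig(lr0=1e-3, max_epochs=3, patience=3, batch_size=16,
                      augment_train=False, seed=0)
    model = build_variant("C_msfi", ModelConfig(backbone="conv_stem_toy", seed=0))
    model, history = train(model, ArrayDataset(images, labels), cfg)
    return model, history, cfg


def test_training_loss_decreases(micro_run):
    _, history, _ = micro_run
    assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]


def test_history_bounded_by_max_epochs(micro_run):
    _, history, cfg = micro_run
    assert len(history) <= cfg.max_epochs
    assert set(history.columns) >= {"epoch", "lr", "train_loss", "val_loss",
                                    "val_top1"}


def test_returned_model_matches_best_val_epoch(micro_run, tiny_dataset):
    model, history, cfg = micro_run
    images, _, labels = tiny_dataset
    from retinagrade.training import preprocess, stratified_split, _top1
    split = stratified_split(labels, cfg)
    top1, _ = _top1(model, preprocess(images[split.val]), labels[split.val],
                    cfg.batch_size)
    assert top1 == pytest.approx(history["val_top1"].max())


def test_patience_zero_stops_at_first_plateau(tiny_dataset):
    images, _, labels = tiny_dataset
    cfg = TrainConfig(lr0=1e-9, max_epochs=6, patience=0, batch_size=16,
                      augment_train=False, seed=0)
    model = build_variant("A", ModelConfig(backbone="conv_stem_toy", seed=0))
    _, history = train(model, ArrayDataset(images, labels), cfg)
    # with a frozen learning rate nothing improves after the first epoch
    assert len(history) <= 3


def test_train_requires_nonempty_splits(tiny_dataset):
    images, _, labels = tiny_dataset
    cfg = TrainConfig(seed=0)
    model = build_variant("A", ModelConfig(backbone="conv_stem_toy", seed=0))
    from retinagrade.training import SplitManifest
    empty = SplitManifest(train=np.array([], dtype=int),
                          val=np.array([], dtype=int),
                          test=np.array([], dtype=int))
    with pytest.raises(ValueError, match="non-empty"):
        train(model, ArrayDataset(images, labels), cfg, split=empty)
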