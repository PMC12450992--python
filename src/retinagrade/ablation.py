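"""Ablation harness: train and score every requested architecture variant
on one shared synthetic dataset and tabulate top-1 / parameters / MACs."""

from __future__ import annotations

import logging

import pandas as pd

from .evaluation_viz import evaluate_model
from .interface import RunConfig
from .network import build_variant, complexity
from .synthetic_fundus import generate_array_dataset
from .training import ArrayDataset, stratified_split, train

log = logging.getLogger(__name__)


def run_ablation(cfg: RunConfig, variant_ids: list[str]) -> pd.DataFrame:
    """Run the variant grid end-to-end; one row per variant.

    All variants share the same dataset, split and training protocol, so
    differences in the table reflect architecture alone.
    """
    size = (cfg.data.image_size, cfg.data.image_size)
    images, masks, labels = generate_array_dataset(
        cfg.data.class_counts, image_size=size, seed=cfg.data.seed)
    data = ArrayDataset(images=images, labels=labels, masks=masks)
    tcfg = cfg.train_config_obj()
    split = stratified_split(labels, tcfg)
    rows = []
    for vid in variant_ids:
        model = build_variant(vid, cfg.model_config_obj())
        rep = complexity(model, size)
        model, history = train(model, data, tcfg, split=split)
        metrics = evaluate_model(model, images[split.test], labels[split.test])
        log.info("variant %s: top1 %.3f (%d params)",
                 vid, metrics.top1, rep.parameter_count)
        rows.append({
            "variant": vid,
            "top1": metrics.top1,
            "top5": metrics.top5,
            "parameters": rep.parameter_count,
            "macs_g": rep.mac_count_g,
            "epochs": len(history),
        })
    return pd.DataFrame(rows)
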