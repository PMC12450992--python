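"""Structured configuration and dataset-manifest I/O.

One YAML file drives every subcommand; unknown keys are rejected with the
offending key path, every field has a documented default, and a config
round-trips through serialisation unchanged.  Manifests are plain CSV with
the fixed header ``image,grade,mask``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

__all__ = ["RunConfig", "load_config", "save_config",
           "read_manifest", "write_manifest", "ConfigError"]

MANIFEST_COLUMNS = ["image", "grade", "mask"]


class ConfigError(ValueError):
    pass


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DataSection(_Section):
    class_counts: tuple[int, int, int, int, int] = (40, 10, 20, 5, 5)
    image_size: int = 64
    seed: int = 0
    root: str = "synthetic_fundus"


class DwamSection(_Section):
    allowed_sizes: tuple[int, ...] = (2, 4, 8)
    variance_grid: int | None = 8
    num_heads: int = 4
    quantile_edges: tuple[float, ...] = (1 / 3, 2 / 3)
    focus_top_fraction: float = 0.25
    zero_init_output_projection: bool = False


class MsfiSection(_Section):
    kernel_sizes: tuple[int, ...] = (3, 5, 7)
    branch_channels: int = 32
    fused_channels: int = 64


class ModelSection(_Section):
    backbone: str = "tiny_vit_toy"
    input_size: int = 64
    num_classes: int = 5
    fusion_channels: int = 64
    variant: str = "D"
    seed: int = 0


class TrainSection(_Section):
    lr0: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 20
    min_lr: float = 1e-6
    train_fraction: float = 0.8
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.1
    rotation_deg: float = 15.0
    blur_sigma: tuple[float, float] = (0.5, 1.0)
    brightness_jitter: float = 0.1
    augment: bool = True
    oversample: bool = False
    class_weighting: bool = True
    seed: int = 0


class EvalSection(_Section):
    heatmap_threshold: float = 0.7
    min_component_px: int = 2


class RunConfig(_Section):
    data: DataSection = DataSection()
    model: ModelSection = ModelSection()
    dwam: DwamSection = DwamSection()
    msfi: MsfiSection = MsfiSection()
    train: TrainSection = TrainSection()
    eval: EvalSection = EvalSection()

    # -- bridges to the runtime dataclasses -----------------------------------
    def model_config_obj(self):
        from .dwam_attention import DwamConfig
        from .msfi_fusion import MsfiConfig
        from .network import ModelConfig
        dwam = DwamConfig(allowed_sizes=self.dwam.allowed_sizes,
                          variance_grid=self.dwam.variance_grid,
                          num_heads=self.dwam.num_heads,
                          quantile_edges=self.dwam.quantile_edges,
                          focus_top_fraction=self.dwam.focus_top_fraction,
                          zero_init_output_projection=self.dwam.zero_init_output_projection)
        msfi = MsfiConfig(kernel_sizes=self.msfi.kernel_sizes,
                          branch_channels=self.msfi.branch_channels,
                          fused_channels=self.msfi.fused_channels)
        return ModelConfig(backbone=self.model.backbone,
                           input_size=(self.model.input_size, self.model.input_size),
                           num_classes=self.model.num_classes,
                           dwam=dwam, msfi=msfi,
                           fusion_channels=self.model.fusion_channels,
                           seed=self.model.seed)

    def train_config_obj(self):
        from .training import TrainConfig
        t = self.train
        return TrainConfig(lr0=t.lr0, betas=(t.beta1, t.beta2),
                           batch_size=t.batch_size, max_epochs=t.max_epochs,
                           patience=t.patience, min_lr=t.min_lr,
                           split=(t.train_fraction, t.test_fraction,
                                  t.val_fraction_of_train),
                           rotation_deg=t.rotation_deg, blur_sigma=t.blur_sigma,
                           brightness_jitter=t.brightness_jitter,
                           augment_train=t.augment, oversample=t.oversample,
                           class_weighting=t.class_weighting, seed=t.seed)


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; an empty file yields all defaults."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(f"{path}: invalid config — " + "; ".join(lines)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(cfg.model_dump()), sort_keys=False))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def write_manifest(rows: pd.DataFrame, path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Read a ``image,grade,mask`` CSV; grades must be integers in 0..4."""
    df = pd.read_csv(path, dtype={"image": str, "mask": str},
                     keep_default_na=False)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ValueError(f"{path}: expected header {MANIFEST_COLUMNS}, "
                         f"got {list(df.columns)}")
    grades = pd.to_numeric(df["grade"], errors="coerce")
    bad = df.index[grades.isna() | (grades % 1 != 0) |
                   (grades < 0) | (grades > 4)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(f"{path}: row {row + 2} has invalid grade "
                         f"{df.loc[row, 'grade']!r} (expected integer 0-4)")
    df["grade"] = grades.astype(int)
    return df
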