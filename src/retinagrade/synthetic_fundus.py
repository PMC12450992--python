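"""Seeded synthetic fundus-style images with graded multi-scale lesions.

The generator emulates the structure a retinopathy grader learns from: a
bright circular retinal field on a dark surround, a handful of vessel-like
curvilinear strokes, and three lesion families at well-separated spatial
scales — microaneurysms (MA, tiny dark-red dots, 1–3 px), hemorrhages (HE,
intermediate dark blobs, 4–10 px), exudates (EX, large bright yellowish
patches, 11–24 px) — plus neovascular tufts (NV, branching strokes) that
define proliferative disease.  The pixel ranges keep the clinical ordering
MA < HE < EX with MA near the resolution limit, mirroring how micrometre
scale bands project onto fundus photographs at 64–224 px.

Every sample carries a pixel-accurate label mask (0 background, 1 MA, 2 HE,
3 EX, 4 NV), a lesion inventory, and the grade implied by a deterministic
grading rule, so ground truth is exact by construction.  Same seed, same
bytes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import draw as skdraw

__all__ = [
    "LesionSpec", "GradingRule", "SyntheticSample", "DatasetConfig",
    "DEFAULT_LESION_SPECS", "DEFAULT_GRADING_RULE",
    "render_background", "place_lesions", "generate_sample",
    "generate_dataset", "generate_array_dataset",
    "MASK_LABELS", "PAPER_CLASS_COUNTS",
]

# per-class image counts of the emulated five-grade retinal dataset
PAPER_CLASS_COUNTS = (25810, 2443, 5292, 873, 708)

MASK_LABELS = {"MA": 1, "HE": 2, "EX": 3, "NV": 4}


class ConfigurationError(RuntimeError):
    """Raised when a grading rule cannot be satisfied for a requested grade."""


@dataclass(frozen=True)
class LesionSpec:
    family: str                        # MA | HE | EX | NV
    diameter_px_range: tuple[int, int]
    intensity_delta: tuple[float, float, float]
    shape: str                         # dot | blob | patch | tuft

    def __post_init__(self):
        if self.family not in MASK_LABELS:
            raise ValueError(f"unknown lesion family {self.family!r}")
        lo, hi = self.diameter_px_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad diameter range {self.diameter_px_range}")


DEFAULT_LESION_SPECS: dict[str, LesionSpec] = {
    "MA": LesionSpec("MA", (1, 3), (-60.0, -45.0, -20.0), "dot"),
    "HE": LesionSpec("HE", (4, 10), (-90.0, -65.0, -35.0), "blob"),
    "EX": LesionSpec("EX", (11, 24), (45.0, 40.0, -15.0), "patch"),
    "NV": LesionSpec("NV", (10, 20), (-55.0, -35.0, -20.0), "tuft"),
}


@dataclass(frozen=True)
class GradingRule:
    """Deterministic map from a lesion inventory to a grade 0-4.

    Defaults: no lesions -> 0; 1-5 MA alone -> 1; >=6 MA or any HE/EX (with
    at most 5 HE) -> 2; >=6 HE -> 3; any neovascularisation -> 4 (dominant).
    The rule is total and monotone non-decreasing in every count.
    """

    mild_ma_max: int = 5
    severe_he_min: int = 6

    def __call__(self, inventory: dict[str, int]) -> int:
        n_ma = inventory.get("MA", 0)
        n_he = inventory.get("HE", 0)
        n_ex = inventory.get("EX", 0)
        n_nv = inventory.get("NV", 0)
        if min(n_ma, n_he, n_ex, n_nv) < 0:
            raise ValueError("lesion counts must be non-negative")
        if n_nv >= 1:
            return 4
        if n_he >= self.severe_he_min:
            return 3
        if n_ma > self.mild_ma_max or n_he >= 1 or n_ex >= 1:
            return 2
        if n_ma >= 1:
            return 1
        return 0


DEFAULT_GRADING_RULE = GradingRule()


@dataclass
class SyntheticSample:
    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) uint8, labels per MASK_LABELS
    grade: int
    inventory: dict[str, int]
    seed: int | None = None


@dataclass
class DatasetConfig:
    class_counts: tuple[int, int, int, int, int] = PAPER_CLASS_COUNTS
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0
    output_dir: str | Path = "synthetic_fundus"

    def __post_init__(self):
        if len(self.class_counts) != 5 or any(c < 0 for c in self.class_counts):
            raise ValueError("class_counts must be 5 non-negative integers")


# -- background ----------------------------------------------------------------

def _fundus_geometry(shape: tuple[int, int]):
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    radius = 0.47 * min(H, W)
    yy, xx = np.mgrid[0:H, 0:W]
    rr = np.hypot(yy - cy, xx - cx)
    return cy, cx, radius, rr


def render_background(image_size: tuple[int, int], rng) -> np.ndarray:
    """Circular bright retinal disc, 2-6 vessel strokes, multiplicative noise.

    Deterministic for a fixed generator state; raises for images below
    32 x 32 where the lesion scale bands no longer fit.
    """
    H, W = image_size
    if H < 32 or W < 32:
        raise ValueError(f"image_size must be at least 32x32, got {H}x{W}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cy, cx, radius, rr = _fundus_geometry((H, W))
    inside = rr <= radius
    # warm fundus tint with a gentle radial falloff; surround near-black
    falloff = np.clip(1.0 - 0.35 * (rr / radius) ** 2, 0.0, 1.0)
    base = np.zeros((H, W, 3), dtype=float)
    tint = np.array([195.0, 115.0, 60.0])
    for c in range(3):
        base[..., c] = np.where(inside, tint[c] * falloff, 4.0)
    # vessel strokes: jittered random walks from near the centre outwards
    n_vessels = int(rng.integers(2, 7))
    vessel_delta = np.array([-70.0, -55.0, -25.0])
    for _ in range(n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        y = cy + rng.uniform(-0.15, 0.15) * radius
        x = cx + rng.uniform(-0.15, 0.15) * radius
        step = rng.uniform(1.2, 2.0)
        for _ in range(int(radius / step * 1.2)):
            ang += rng.normal(0.0, 0.25)
            y += step * np.sin(ang)
            x += step * np.cos(ang)
            if np.hypot(y - cy, x - cx) > radius * 0.95:
                break
            ry, rx = skdraw.disk((y, x), rng.uniform(0.6, 1.1), shape=(H, W))
            base[ry, rx] += vessel_delta * 0.6
    # low-amplitude multiplicative noise, spatially smooth
    from scipy.ndimage import gaussian_filter
    noise = gaussian_filter(rng.standard_normal((H, W)), sigma=1.5)
    noise = 1.0 + 0.04 * noise / max(np.abs(noise).max(), 1e-9)
    base *= noise[..., None]
    return np.clip(base, 0, 255).astype(np.uint8)


# -- lesions -------------------------------------------------------------------

def _lesion_footprint(spec: LesionSpec, center: tuple[float, float],
                      diameter: float, rng: np.random.Generator,
                      shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates (rows, cols) of one lesion instance."""
    cy, cx = center
    r = max(diameter / 2.0, 0.5)
    if spec.shape == "dot":
        return skdraw.disk((cy, cx), r, shape=shape)
    if spec.shape == "blob":
        aspect = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        return skdraw.ellipse(cy, cx, r, max(r * aspect, 0.5),
                              rotation=theta, shape=shape)
    if spec.shape == "patch":
        canvas = np.zeros(shape, dtype=bool)
        for _ in range(int(rng.integers(3, 6))):
            oy = cy + rng.uniform(-0.35, 0.35) * r
            ox = cx + rng.uniform(-0.35, 0.35) * r
            rr_, cc_ = skdraw.disk((oy, ox), rng.uniform(0.5, 0.8) * r, shape=shape)
            canvas[rr_, cc_] = True
        return np.nonzero(canvas)
    if spec.shape == "tuft":
        canvas = np.zeros(shape, dtype=bool)
        n_branches = int(rng.integers(3, 7))
        for _ in range(n_branches):
            ang = rng.uniform(0, 2 * np.pi)
            y, x = cy, cx
            for _ in range(int(r * rng.uniform(0.8, 1.2))):
                ang += rng.normal(0.0, 0.5)
                y += np.sin(ang)
                x += np.cos(ang)
                rr_, cc_ = skdraw.disk((y, x), 1.0, shape=shape)
                canvas[rr_, cc_] = True
        return np.nonzero(canvas)
    raise ValueError(f"unknown lesion shape {spec.shape!r}")


def _sample_inventory(grade: int, rule: GradingRule,
                      rng: np.random.Generator, max_attempts: int = 1000
                      ) -> dict[str, int]:
    """Rejection-sample a lesion inventory consistent with the grade."""
    for _ in range(max_attempts):
        if grade == 0:
            inv = {"MA": 0, "HE": 0, "EX": 0, "NV": 0}
        elif grade == 1:
            inv = {"MA": int(rng.integers(1, rule.mild_ma_max + 1)),
                   "HE": 0, "EX": 0, "NV": 0}
        elif grade == 2:
            inv = {"MA": int(rng.integers(0, 11)),
                   "HE": int(rng.integers(0, rule.severe_he_min)),
                   "EX": int(rng.integers(0, 4)), "NV": 0}
        elif grade == 3:
            inv = {"MA": int(rng.integers(0, 11)),
                   "HE": int(rng.integers(rule.severe_he_min, rule.severe_he_min + 7)),
                   "EX": int(rng.integers(0, 4)), "NV": 0}
        elif grade == 4:
            inv = {"MA": int(rng.integers(0, 6)),
                   "HE": int(rng.integers(0, 6)),
                   "EX": int(rng.integers(0, 3)),
                   "NV": int(rng.integers(1, 4))}
        else:
            raise ValueError(f"grade must be 0-4, got {grade}")
        if rule(inv) == grade:
            return inv
    raise ConfigurationError(
        f"could not sample an inventory for grade {grade} in {max_attempts} attempts; "
        "the grading rule is unsatisfiable for this grade")


_PAINT_ORDER = ("EX", "HE", "MA", "NV")  # large first so small lesions stay distinct


def place_lesions(image: np.ndarray, grade: int, rng,
                  lesion_specs: dict[str, LesionSpec] | None = None,
                  grading_rule: GradingRule | None = None) -> SyntheticSample:
    """Paint a grade-consistent lesion inventory onto a background render.

    Lesion centres stay inside the circular field; placement retries avoid
    overlap between instances so mask connected components correspond
    one-to-one with the inventory counts in the typical case.
    """
    if grade not in range(5):
        raise ValueError(f"grade must be in 0..4, got {grade}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    specs = lesion_specs or DEFAULT_LESION_SPECS
    rule = grading_rule or DEFAULT_GRADING_RULE
    inv = _sample_inventory(grade, rule, rng)
    H, W = image.shape[:2]
    cy, cx, radius, _ = _fundus_geometry((H, W))
    img = image.astype(float)
    mask = np.zeros((H, W), dtype=np.uint8)
    for family in _PAINT_ORDER:
        spec = specs[family]
        label = MASK_LABELS[family]
        delta = np.array(spec.intensity_delta)
        for _ in range(inv.get(family, 0)):
            lo, hi = spec.diameter_px_range
            diameter = float(rng.uniform(lo, hi))
            placed = False
            max_rho = max(radius - diameter / 2.0 - 1.5, 1.0)
            for _attempt in range(50):
                rho = max_rho * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                y = cy + rho * np.sin(ang)
                x = cx + rho * np.cos(ang)
                ry, rx = _lesion_footprint(spec, (y, x), diameter, rng, (H, W))
                keep = np.hypot(ry - cy, rx - cx) <= radius - 0.5
                ry, rx = ry[keep], rx[keep]   # clip to the circular field
                if ry.size == 0:
                    continue
                # keep instances separated so components stay countable
                y0, y1 = max(ry.min() - 1, 0), min(ry.max() + 2, H)
                x0, x1 = max(rx.min() - 1, 0), min(rx.max() + 2, W)
                if mask[y0:y1, x0:x1].any():
                    continue
                img[ry, rx] += delta
                mask[ry, rx] = label
                placed = True
                break
            if not placed:   # crowded field: accept the last candidate anyway
                img[ry, rx] += delta
                mask[ry, rx] = label
    out = np.clip(img, 0, 255).astype(np.uint8)
    assert rule(inv) == grade
    return SyntheticSample(image=out, mask=mask, grade=grade, inventory=inv)


def generate_sample(grade: int, image_size: tuple[int, int], seed: int,
                    lesion_specs: dict[str, LesionSpec] | None = None,
                    grading_rule: GradingRule | None = None) -> SyntheticSample:
    """Render one fully-seeded sample (background + lesions + mask)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    bg = render_background(image_size, rng)
    sample = place_lesions(bg, grade, rng, lesion_specs, grading_rule)
    sample.seed = seed
    return sample


def _sample_seed(root_seed: int, index: int) -> int:
    """Stable 31-bit per-sample seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def generate_array_dataset(class_counts, image_size=(64, 64), seed: int = 0,
                           grading_rule: GradingRule | None = None):
    """In-memory dataset: (images, masks, grades) arrays, reproducible by seed."""
    grades = np.concatenate([
        np.full(n, g, dtype=int) for g, n in enumerate(class_counts)])
    images = np.empty((len(grades), *image_size, 3), dtype=np.uint8)
    masks = np.empty((len(grades), *image_size), dtype=np.uint8)
    for i, g in enumerate(grades):
        s = generate_sample(int(g), image_size, _sample_seed(seed, i),
                            grading_rule=grading_rule)
        images[i] = s.image
        masks[i] = s.mask
    return images, masks, grades


def generate_dataset(config: DatasetConfig) -> pd.DataFrame:
    """Write PNG images and masks plus a ``labels.csv`` manifest.

    Layout: ``<root>/images/*.png``, ``<root>/masks/*.png``,
    ``<root>/labels.csv`` with header ``image,grade,mask`` (mask empty for
    grade-0 rows).  Per-class row counts equal ``config.class_counts``
    exactly; regenerating from the same config is byte-identical.
    """
    root = Path(config.output_dir)
    try:
        (root / "images").mkdir(parents=True, exist_ok=True)
        (root / "masks").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directories under {root}: {exc}") from exc
    rows = []
    index = 0
    for grade, count in enumerate(config.class_counts):
        for _ in range(count):
            s = generate_sample(grade, config.image_size,
                                _sample_seed(config.seed, index))
            img_rel = f"images/sample_{index:06d}.png"
            Image.fromarray(s.image).save(root / img_rel)
            if grade == 0:
                mask_rel = ""
            else:
                mask_rel = f"masks/sample_{index:06d}.png"
                Image.fromarray(s.mask).save(root / mask_rel)
            rows.append({"image": img_rel, "grade": grade, "mask": mask_rel})
            index += 1
    manifest = pd.DataFrame(rows, columns=["image", "grade", "mask"])
    manifest.to_csv(root / "labels.csv", index=False)
    return manifest
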