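"""Image records, preprocessing, splits, and the synthetic image generator.

Real data enters as a directory tree ``root/<class_name>/*.{jpg,png}``;
images are bilinearly resized to a square side (224 by default) and scaled
to [0, 1].  The synthetic generator replaces a field dataset for tests and
examples: each class couples a low-frequency cue (leaf blade vs. panicle
silhouette) with a high-frequency cue (spot, streak or speckle lesions),
so no single frequency band separates all classes — mirroring how disease
classes differ both in organ shape and in lesion texture.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image
from scipy import ndimage
from scipy.special import expit

from .errors import DataError, DimensionError

__all__ = [
    "ImageRecord",
    "DatasetSplit",
    "SyntheticClassSpec",
    "add_gaussian_noise",
    "augment",
    "balance_classes",
    "default_class_specs",
    "generate_synthetic_dataset",
    "load_image_folder",
    "save_image_folder",
    "stratified_split",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


@dataclass
class ImageRecord:
    """One labelled image: ``pixels`` is 3 x H x W, values in [0, 1]."""

    pixels: np.ndarray
    label: int
    class_name: str
    source: str = "synthetic"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise DimensionError(
                f"pixels must be 3 x H x W, got shape {self.pixels.shape}"
            )


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions."""

    train: List[ImageRecord]
    validation: List[ImageRecord]
    test: List[ImageRecord]
    ratios: Tuple[int, int, int] = (5, 1, 4)

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    def sizes(self) -> Tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


@dataclass(frozen=True)
class SyntheticClassSpec:
    """Recipe for one synthetic class.

    ``shape_family`` sets the low-frequency silhouette ("leaf" or
    "panicle"); ``lesion_family`` sets the high-frequency texture ("spots",
    "streaks", "speckle" or "none").  ``lesion_density`` is a mean count
    for spots/streaks and a per-pixel probability for speckle;
    ``lesion_radius`` is in pixels at a 64-px rendering side.
    """

    class_name: str
    shape_family: str = "leaf"
    lesion_family: str = "none"
    lesion_density: float = 14.0
    lesion_radius: float = 2.0
    lesion_contrast: float = 0.8
    base_hue: float = 0.30
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.shape_family not in ("leaf", "panicle"):
            raise ValueError(f"unknown shape family {self.shape_family!r}")
        if self.lesion_family not in ("spots", "streaks", "speckle", "none"):
            raise ValueError(f"unknown lesion family {self.lesion_family!r}")
        if self.lesion_density < 0:
            raise ValueError("lesion density must be >= 0")
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ValueError("lesion contrast must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


# ---------------------------------------------------------------------------
# loading and preprocessing
# ---------------------------------------------------------------------------


def load_image_folder(root: Union[str, Path], size: int = 224) -> List[ImageRecord]:
    """Read ``root/<class>/*.{jpg,png}``; resize bilinearly, scale to [0, 1].

    Class indices follow sorted class-folder names.  Unreadable files are
    skipped with a logged count; empty class folders produce a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset directory not found: {root}")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DataError(f"no class subfolders under {root}")
    records: List[ImageRecord] = []
    skipped = 0
    for label, cdir in enumerate(class_dirs):
        files = sorted(
            f for f in cdir.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            logger.warning("class folder %s contains no images", cdir)
            continue
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB").resize((size, size), Image.BILINEAR)
                    arr = np.asarray(im, dtype=np.float32) / 255.0
            except Exception:  # decode errors: skip, keep count
                skipped += 1
                continue
            records.append(
                ImageRecord(arr.transpose(2, 0, 1), label, cdir.name, str(f))
            )
    if skipped:
        logger.warning("skipped %d unreadable image file(s)", skipped)
    if not records:
        raise DataError(f"no readable images under {root}")
    return records


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def augment(
    rec: ImageRecord,
    rng: Union[int, np.random.Generator, None] = None,
    *,
    rotation: Optional[float] = None,
    hflip: Optional[bool] = None,
    vflip: Optional[bool] = None,
    brightness: Optional[float] = None,
    contrast: Optional[float] = None,
) -> ImageRecord:
    """One randomized composition of rotation, flips, brightness, contrast.

    Parameters left as None are drawn from ``rng`` (rotation uniform in
    +-30 degrees, flips with probability 1/2, factors uniform in
    [0.8, 1.2]); passing explicit values makes the transform deterministic.
    Output is clipped to [0, 1]; the label never changes.
    """
    r = _as_rng(rng)
    if rotation is None:
        rotation = float(r.uniform(-30.0, 30.0))
    if hflip is None:
        hflip = bool(r.random() < 0.5)
    if vflip is None:
        vflip = bool(r.random() < 0.5)
    if brightness is None:
        brightness = float(r.uniform(0.8, 1.2))
    if contrast is None:
        contrast = float(r.uniform(0.8, 1.2))

    x = rec.pixels
    if rotation:
        x = ndimage.rotate(
            x, rotation, axes=(-2, -1), reshape=False, order=1, mode="nearest"
        )
    if hflip:
        x = x[:, :, ::-1]
    if vflip:
        x = x[:, ::-1, :]
    x = x * brightness
    mean = x.mean()
    x = mean + (x - mean) * contrast
    x = np.clip(x, 0.0, 1.0).astype(np.float32)
    return replace(rec, pixels=np.ascontiguousarray(x))


def stratified_split(
    records: Sequence[ImageRecord],
    ratios: Tuple[int, int, int] = (5, 1, 4),
    seed: int = 0,
) -> DatasetSplit:
    """Per-class shuffled partition at the given ratios; remainders go to train."""
    if not records:
        raise DataError("cannot split an empty record list")
    rng = _as_rng(seed)
    total = sum(ratios)
    by_class: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        by_class.setdefault(rec.label, []).append(i)
    train, val, test = [], [], []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        rng.shuffle(idx)
        n = len(idx)
        n_val = n * ratios[1] // total
        n_test = n * ratios[2] // total
        n_train = n - n_val - n_test
        train.extend(records[i] for i in idx[:n_train])
        val.extend(records[i] for i in idx[n_train : n_train + n_val])
        test.extend(records[i] for i in idx[n_train + n_val :])
    return DatasetSplit(train, val, test, ratios)


def add_gaussian_noise(
    rec: ImageRecord,
    level: float,
    rng: Union[int, np.random.Generator, None] = None,
) -> ImageRecord:
    """Add i.i.d. N(0, level^2) on the [0, 1] intensity scale, then clip."""
    if level < 0:
        raise ValueError(f"noise level must be >= 0, got {level}")
    if level == 0:
        return replace(rec, pixels=rec.pixels.copy())
    r = _as_rng(rng)
    noisy = rec.pixels + r.normal(0.0, level, size=rec.pixels.shape)
    return replace(rec, pixels=np.clip(noisy, 0.0, 1.0).astype(np.float32))


def balance_classes(
    records: Sequence[ImageRecord], seed: int = 0, min_per_class: int = 0
) -> List[ImageRecord]:
    """Offline augmentation: top every class up to the majority count.

    ``min_per_class`` raises the target further, expanding small datasets by
    augmented copies (the offline-augmentation stage run before training);
    classes already at or above the target are left untouched.
    """
    rng = _as_rng(seed)
    by_class: dict[int, list[ImageRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    target = max(max(len(v) for v in by_class.values()), min_per_class)
    out = list(records)
    for label in sorted(by_class):
        pool = by_class[label]
        need = target - len(pool)
        for j in range(need):
            out.append(augment(pool[j % len(pool)], rng))
    return out


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    h = h % 1.0
    i = int(h * 6.0)
    f = h * 6.0 - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i % 6]
    return np.array(rgb, dtype=np.float32)


def _smooth_field(rng: np.random.Generator, size: int, cells: int = 4) -> np.ndarray:
    """Low-frequency random field in [0, 1] from an upsampled coarse grid."""
    coarse = rng.random((cells, cells))
    out = ndimage.zoom(coarse, size / cells, order=3, mode="nearest", grid_mode=True)
    out = out[:size, :size]
    lo, hi = out.min(), out.max()
    return ((out - lo) / (hi - lo + 1e-9)).astype(np.float32)


def _render_leaf(rng, xx, yy):
    """Tapered blade silhouette; returns (mask, axis angle)."""
    theta = float(rng.uniform(-0.2, 0.2))
    cx, cy = rng.uniform(-0.05, 0.05, size=2)
    a = float(rng.uniform(0.70, 0.78))
    b = float(rng.uniform(0.24, 0.28))
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * (xx - cx) + st * (yy - cy)
    v = -st * (xx - cx) + ct * (yy - cy)
    halfwidth = b * np.clip(1.0 - (u / a) ** 2, 1e-3, None)
    q = (u / a) ** 2 + (v / halfwidth) ** 2
    mask = expit((1.0 - q) / 0.05)
    return mask.astype(np.float32), theta


def _render_panicle(rng, xx, yy):
    """Thin curved stem with a grain cluster at its tip."""
    bx = float(rng.uniform(-0.15, 0.15))
    c1 = float(rng.uniform(-0.2, 0.2))
    c2 = float(rng.uniform(-0.25, 0.25))
    t = np.linspace(0.0, 1.0, 60)
    px = bx + c1 * t + c2 * t * t
    py = 0.9 - 1.45 * t
    pts = np.stack([px, py], axis=1)
    d2 = np.min(
        (xx[..., None] - pts[:, 0]) ** 2 + (yy[..., None] - pts[:, 1]) ** 2, axis=-1
    )
    r_stem = 0.035
    stem = expit((r_stem**2 - d2) / (r_stem**2))
    tipx, tipy = float(px[-1]), float(py[-1])
    grains = np.zeros_like(stem)
    for _ in range(int(rng.integers(13, 17))):
        gx = tipx + float(rng.normal(0.0, 0.13))
        gy = tipy + float(rng.normal(0.10, 0.14))
        gr = float(rng.uniform(0.05, 0.08))
        gd2 = (xx - gx) ** 2 + (yy - gy) ** 2
        grains = np.maximum(grains, expit((gr**2 - gd2) / (0.5 * gr**2)))
    mask = np.maximum(stem, grains)
    angle = float(np.arctan2(px[-1] - px[0], -(py[-1] - py[0])))
    return mask.astype(np.float32), angle, grains.astype(np.float32)


def _apply_lesions(img, fg_mask, spec: SyntheticClassSpec, rng, size, axis_angle):
    inside = fg_mask > 0.5
    ys, xs = np.nonzero(inside)
    if len(ys) == 0 or spec.lesion_family == "none":
        return img
    coords = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(coords, coords)
    scale = size / 64.0

    if spec.lesion_family == "spots":
        # low count variance keeps within-class appearance consistent
        n = max(1, int(round(spec.lesion_density + rng.uniform(-2, 2))))
        core = np.zeros((size, size), dtype=np.float32)
        halo = np.zeros((size, size), dtype=np.float32)
        for _ in range(n):
            j = int(rng.integers(len(ys)))
            cx, cy = coords[xs[j]], coords[ys[j]]
            r_px = max(1.2, float(rng.normal(spec.lesion_radius * scale, 0.4)))
            r = 2.0 * r_px / size
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            core = np.maximum(core, expit((r**2 - d2) / (0.5 * r**2)))
            halo = np.maximum(halo, expit(((1.7 * r) ** 2 - d2) / (0.5 * r**2)))
        core *= inside
        halo = np.clip(halo - core, 0.0, 1.0) * inside  # chlorotic ring
        dark = np.array([0.18, 0.09, 0.04], dtype=np.float32)
        ring = np.array([0.80, 0.74, 0.22], dtype=np.float32)
        wc = spec.lesion_contrast * core
        wh = 0.7 * spec.lesion_contrast * halo
        img = img * (1.0 - wc[None]) + dark[:, None, None] * wc[None]
        img = img * (1.0 - wh[None]) + ring[:, None, None] * wh[None]

    elif spec.lesion_family == "streaks":
        n = max(1, int(round(spec.lesion_density + rng.uniform(-2, 2))))
        lesion = np.zeros((size, size), dtype=np.float32)
        for _ in range(n):
            j = int(rng.integers(len(ys)))
            cx, cy = coords[xs[j]], coords[ys[j]]
            ang = axis_angle + float(rng.normal(0.0, 0.15))
            ct, st = np.cos(ang), np.sin(ang)
            u = st * (xx - cx) - ct * (yy - cy)  # along the organ axis
            v = ct * (xx - cx) + st * (yy - cy)
            half_len = float(rng.uniform(0.22, 0.34))
            half_w = 3.0 / size * 2.0
            bar = expit((half_len - np.abs(u)) / 0.02) * expit(
                (half_w - np.abs(v)) / (half_w * 0.4)
            )
            lesion = np.maximum(lesion, bar.astype(np.float32))
        lesion *= inside
        color = np.array([0.78, 0.68, 0.25], dtype=np.float32)
        w = spec.lesion_contrast * lesion
        img = img * (1.0 - w[None]) + color[:, None, None] * w[None]

    elif spec.lesion_family == "speckle":
        p = min(1.0, spec.lesion_density if spec.lesion_density <= 1.0 else 0.05)
        hits = (rng.random((size, size)) < p) & inside
        signs = rng.choice([-1.0, 1.0], size=(size, size))
        delta = spec.lesion_contrast * 0.6 * signs * hits
        img = img + delta[None].astype(np.float32)

    return img


def _render_image(spec: SyntheticClassSpec, size: int, rng) -> np.ndarray:
    coords = np.linspace(-1.0, 1.0, size)
    xx, yy = np.meshgrid(coords, coords)
    grains = None
    if spec.shape_family == "leaf":
        mask, axis_angle = _render_leaf(rng, xx, yy)
    else:
        mask, axis_angle, grains = _render_panicle(rng, xx, yy)

    bg_base = np.array([0.24, 0.20, 0.12], dtype=np.float32)
    bg = bg_base[:, None, None] * (0.8 + 0.3 * _smooth_field(rng, size))[None]
    hue = spec.base_hue + float(rng.uniform(-0.01, 0.01))
    fg_color = _hsv_to_rgb(hue, 0.55 + float(rng.uniform(-0.03, 0.03)),
                           0.55 + float(rng.uniform(-0.03, 0.03)))
    shading = (0.9 + 0.2 * _smooth_field(rng, size))[None]
    fg = fg_color[:, None, None] * shading
    if grains is not None:
        # ripening grain is tan/golden, unlike the green stem and blades
        tan = _hsv_to_rgb(0.12 + float(rng.uniform(-0.01, 0.01)), 0.55, 0.62)
        fg = fg * (1.0 - grains[None]) + (tan[:, None, None] * shading) * grains[None]
    img = bg * (1.0 - mask[None]) + fg * mask[None]

    img = _apply_lesions(img, mask, spec, rng, size, axis_angle)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def default_class_specs(num_classes: int = 4) -> List[SyntheticClassSpec]:
    """Stock class recipes (4 or 10 classes).

    All classes share one base hue, so color alone cannot separate them:
    the leaf/panicle silhouette resolves one axis and the lesion texture
    the other.
    """
    four = [
        SyntheticClassSpec("leaf_clean", "leaf", "none"),
        SyntheticClassSpec("leaf_spots", "leaf", "spots", 14.0, 3.2, 0.95),
        SyntheticClassSpec("panicle_clean", "panicle", "none"),
        SyntheticClassSpec("panicle_streaks", "panicle", "streaks", 14.0, 2.0, 0.95),
    ]
    if num_classes == 4:
        return four
    if num_classes == 10:
        return [
            SyntheticClassSpec("leaf_clean", "leaf", "none"),
            SyntheticClassSpec("leaf_speckle", "leaf", "speckle", 0.06),
            SyntheticClassSpec("leaf_spots_dense", "leaf", "spots", 18.0, 2.0),
            SyntheticClassSpec("leaf_spots_sparse", "leaf", "spots", 6.0, 3.0),
            SyntheticClassSpec("leaf_streaks", "leaf", "streaks", 8.0),
            SyntheticClassSpec("panicle_clean", "panicle", "none"),
            SyntheticClassSpec("panicle_speckle", "panicle", "speckle", 0.06),
            SyntheticClassSpec("panicle_spots", "panicle", "spots", 10.0, 2.0),
            SyntheticClassSpec("panicle_streaks", "panicle", "streaks", 8.0),
            SyntheticClassSpec("panicle_streaks_dense", "panicle", "streaks", 16.0),
        ]
    raise ValueError("stock recipes exist for 4 or 10 classes")


def generate_synthetic_dataset(
    specs: Sequence[SyntheticClassSpec],
    per_class: int = 50,
    size: int = 64,
    seed: int = 0,
    max_images: int = 100_000,
) -> List[ImageRecord]:
    """Render ``per_class`` images for every class spec, reproducibly.

    Labels follow sorted class names (the same convention as folder
    loading), so a round trip through ``save_image_folder`` +
    ``load_image_folder`` preserves labels.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    if per_class * len(specs) > max_images:
        raise ValueError(
            f"{per_class * len(specs)} images exceed the configured cap {max_images}"
        )
    ordered = sorted(specs, key=lambda s: s.class_name)
    records = []
    for label, spec in enumerate(ordered):
        for j in range(per_class):
            rng = np.random.default_rng([seed, label, j])
            records.append(
                ImageRecord(_render_image(spec, size, rng), label, spec.class_name)
            )
    return records


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_image_folder(records: Sequence[ImageRecord], outdir: Union[str, Path]) -> Path:
    """Write records as ``outdir/<class>/<idx>.png`` plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}
    rows = []
    for rec in records:
        cdir = outdir / rec.class_name
        cdir.mkdir(exist_ok=True)
        i = counters.get(rec.class_name, 0)
        counters[rec.class_name] = i + 1
        path = cdir / f"{i:05d}.png"
        arr = (np.clip(rec.pixels, 0, 1).transpose(1, 2, 0) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(path)
        rows.append((str(path.relative_to(outdir)), rec.class_name, rec.label, ""))
    manifest = outdir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest


def write_manifest(rows: Sequence[tuple], path: Union[str, Path]) -> None:
    """Rows of (path, class_name, label, partition)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class_name", "label", "partition"])
        writer.writerows(rows)
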