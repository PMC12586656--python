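"""Synthetic underwater species corpus, augmentation and splitting.

The generator emulates the statistical structure of a small five-class
shrimp/prawn image corpus shot under aquaculture conditions: each class is
a distinct parametric motif (segmented body chains at class-specific
curvature, segment count and hue; sparse larval blobs; a low-light variant
with strong global attenuation) rendered over a blue-green water background
and degraded with smooth turbidity haze and additive sensor noise. The
motifs are parameterized so class separability for a small convolutional
feature extractor is a controllable property rather than an accident; the
non-dark classes share similar mean gray intensity on purpose, so mean
brightness alone does not solve the task.

All operations are pure functions of (inputs, config, seed): the same seed
reproduces the corpus byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "SyntheticDatasetConfig",
    "AugmentConfig",
    "CLASS_NAMES",
    "generate_dataset",
    "augment",
    "stratified_split",
    "preprocess",
]


class DatasetError(ValueError):
    pass


#: The five species/condition classes of the corpus, in label order.
CLASS_NAMES = (
    "farm_shrimp",
    "prawn",
    "shrimp1",
    "shrimp_larvae",
    "shrimp_low_light",
)


@dataclass
class SyntheticDatasetConfig:
    class_names: tuple[str, ...] = CLASS_NAMES
    per_class: int = 1084  # ~5420 images total across five classes
    image_size: tuple[int, int] = (224, 224)
    haze_strength: float = 0.25
    blur_radius: float = 8.0  # spatial scale of the turbidity field, px
    noise_sd: float = 0.03
    low_light_gain: float = 0.3  # global gain of the low-light class (< 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class < 1:
            raise DatasetError("per_class must be >= 1")
        if min(self.image_size) < 8:
            raise DatasetError("image size must be at least 8x8")
        if not (0.0 < self.low_light_gain < 1.0):
            raise DatasetError("low_light_gain must lie in (0, 1)")


@dataclass
class AugmentConfig:
    """Training-set augmentation ranges (the corpus-expansion transform)."""

    rotation_deg: float = 30.0
    shift_frac: float = 0.20
    shear_frac: float = 0.20
    zoom_frac: float = 0.20
    flip_prob: float = 0.5
    fill_mode: str = "nearest"

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "shift_frac", "shear_frac", "zoom_frac"):
            if getattr(self, name) < 0:
                raise DatasetError(f"{name} must be nonnegative")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise DatasetError("flip_prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# rendering


def _body_chain(
    yy: np.ndarray,
    xx: np.ndarray,
    rng: np.random.Generator,
    n_segments: int,
    curvature: float,
    seg_radius: float,
    length: float,
) -> np.ndarray:
    """Soft mask of a curved chain of elliptical segments (a body silhouette)."""
    h, w = yy.shape
    cy = h * rng.uniform(0.35, 0.65)
    cx = w * rng.uniform(0.35, 0.65)
    heading = rng.uniform(0.0, 2 * np.pi)
    mask = np.zeros_like(yy, dtype=float)
    step = length / max(n_segments - 1, 1)
    y, x = cy, cx
    for _ in range(n_segments):
        r2 = (yy - y) ** 2 + (xx - x) ** 2
        mask += np.exp(-r2 / (2.0 * seg_radius**2))
        heading += curvature
        y += step * np.sin(heading)
        x += step * np.cos(heading)
    return np.clip(mask, 0.0, 1.0)


def _larvae_blobs(
    yy: np.ndarray, xx: np.ndarray, rng: np.random.Generator, n_blobs: int, radius: float
) -> np.ndarray:
    h, w = yy.shape
    mask = np.zeros_like(yy, dtype=float)
    for _ in range(n_blobs):
        y = rng.uniform(0.1, 0.9) * h
        x = rng.uniform(0.1, 0.9) * w
        r2 = (yy - y) ** 2 + (xx - x) ** 2
        mask += np.exp(-r2 / (2.0 * radius**2))
    return np.clip(mask, 0.0, 1.0)


#: Per-class motif parameters: (segments, curvature, radius frac, length frac,
#: body RGB tint). Tuned so a small conv net separates the classes while the
#: non-dark classes overlap in mean gray intensity.
_MOTIFS = {
    "farm_shrimp": dict(segments=6, curvature=0.35, radius=0.065, length=0.45,
                        tint=(1.00, 0.35, 0.25)),
    "prawn": dict(segments=12, curvature=0.08, radius=0.050, length=0.80,
                  tint=(0.25, 0.25, 1.00)),
    "shrimp1": dict(segments=4, curvature=0.85, radius=0.095, length=0.35,
                    tint=(1.00, 0.95, 0.20)),
}


def _render_image(
    class_name: str, size: tuple[int, int], cfg: SyntheticDatasetConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # blue-green water background with a vertical light gradient
    depth = yy / h
    base = np.empty((h, w, 3))
    base[..., 0] = 0.10 + 0.05 * (1 - depth)
    base[..., 1] = 0.35 + 0.10 * (1 - depth)
    base[..., 2] = 0.45 + 0.10 * (1 - depth)
    base += rng.normal(0.0, 0.01, size=3)[None, None, :]

    scale = min(h, w)
    if class_name == "shrimp_larvae":
        mask = _larvae_blobs(yy, xx, rng, n_blobs=rng.integers(12, 18),
                             radius=0.029 * scale)
        tint = np.array([0.95, 0.90, 0.75])
    else:
        motif_key = "farm_shrimp" if class_name == "shrimp_low_light" else class_name
        p = _MOTIFS[motif_key]
        mask = _body_chain(
            yy, xx, rng,
            n_segments=int(p["segments"]),
            curvature=p["curvature"] * rng.uniform(0.8, 1.2) * rng.choice([-1, 1]),
            seg_radius=p["radius"] * scale,
            length=p["length"] * scale,
        )
        tint = np.asarray(p["tint"])

    img = base * (1 - 0.9 * mask[..., None]) + 0.9 * mask[..., None] * tint

    # turbidity haze: a smooth random brightness field (low-pass noise)
    coarse = rng.normal(0.0, 1.0, size=(max(h // int(cfg.blur_radius), 2),) * 2)
    haze = resize(coarse, (h, w), order=1, mode="reflect", anti_aliasing=False)
    haze = (haze - haze.min()) / max(np.ptp(haze), 1e-12)
    img = img * (1 - cfg.haze_strength) + cfg.haze_strength * haze[..., None]

    if class_name == "shrimp_low_light":
        img = img * cfg.low_light_gain

    img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    cfg: SyntheticDatasetConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the labelled corpus.

    Returns ``(images, labels)`` with images ``(N, H, W, 3)`` uint8 and
    integer labels indexing ``cfg.class_names``. Deterministic in
    ``cfg.seed``.
    """
    cfg = cfg or SyntheticDatasetConfig()
    n = cfg.per_class * len(cfg.class_names)
    h, w = cfg.image_size
    images = np.empty((n, h, w, 3), dtype=np.uint8)
    labels = np.empty(n, dtype=int)
    rng = np.random.default_rng(cfg.seed)
    idx = 0
    for label, name in enumerate(cfg.class_names):
        for _ in range(cfg.per_class):
            img = _render_image(name, cfg.image_size, cfg, rng)
            images[idx] = np.round(img * 255).astype(np.uint8)
            labels[idx] = label
            idx += 1
    return images, labels


# ---------------------------------------------------------------------------
# augmentation


def augment(
    image: np.ndarray, cfg: AugmentConfig | None = None, seed: int = 0
) -> np.ndarray:
    """One random draw of the augmentation pipeline.

    Rotation, shear, zoom and shift are sampled uniformly within the
    configured symmetric ranges and composed (about the image centre, in
    the fixed order rotate -> shear -> zoom -> shift) into a single affine
    warp with nearest-edge fill, followed by a horizontal flip with the
    configured probability. Output dtype and shape equal the input's.
    """
    cfg = cfg or AugmentConfig()
    image = np.asarray(image)
    if image.size == 0:
        raise DatasetError("cannot augment an empty image")
    if cfg.fill_mode != "nearest":
        raise DatasetError(f"unsupported fill mode {cfg.fill_mode!r}")
    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]

    angle = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    shear = np.arctan(rng.uniform(-cfg.shear_frac, cfg.shear_frac))
    zoom = 1.0 + rng.uniform(-cfg.zoom_frac, cfg.zoom_frac)
    dy = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * h
    dx = rng.uniform(-cfg.shift_frac, cfg.shift_frac) * w
    flip = rng.random() < cfg.flip_prob

    centre = AffineTransform(translation=(-w / 2, -h / 2))
    core = (
        AffineTransform(rotation=angle)
        + AffineTransform(shear=shear)
        + AffineTransform(scale=(zoom, zoom))
        + AffineTransform(translation=(dx, dy))
    )
    tform = centre + core + AffineTransform(translation=(w / 2, h / 2))

    was_uint8 = image.dtype == np.uint8
    img = image.astype(float) / 255.0 if was_uint8 else image.astype(float)
    identity = (
        angle == 0.0 and shear == 0.0 and zoom == 1.0 and dx == 0.0 and dy == 0.0
    )
    if not identity:
        img = warp(img, tform.inverse, mode="edge", order=1, preserve_range=True)
    if flip:
        img = img[:, ::-1].copy()
    if was_uint8:
        return np.round(np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# splitting and preprocessing


def stratified_split(
    labels,
    ratios: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class shuffled train/val/test partition at the given ratios.

    Within each class the indices are shuffled with the seed and allocated
    by floor counts with largest-remainder rounding, remainder priority
    train > val > test; the three partitions are disjoint and exhaustive.
    A class with fewer samples than the number of splits goes entirely to
    the training partition (with a warning).
    """
    labels = np.asarray(labels)
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise DatasetError("split ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        m = idx.size
        if m < len(ratios):
            warnings.warn(
                f"class {cls} has only {m} samples; assigning all to train",
                stacklevel=2,
            )
            parts[0].extend(idx.tolist())
            continue
        floors = [int(np.floor(r * m)) for r in ratios]
        remainders = [r * m - f for r, f in zip(ratios, floors)]
        short = m - sum(floors)
        # largest remainder first; ties broken by partition priority order
        order = sorted(range(3), key=lambda i: (-remainders[i], i))
        for i in order[:short]:
            floors[i] += 1
        offset = 0
        for part, count in zip(parts, floors):
            part.extend(idx[offset : offset + count].tolist())
            offset += count
    return tuple(np.array(sorted(p), dtype=int) for p in parts)  # type: ignore[return-value]


_PREPROCESS_SCHEMES = ("scale01", "identity")


def preprocess(
    image: np.ndarray,
    target_size: tuple[int, int] = (224, 224),
    scheme: str = "scale01",
) -> np.ndarray:
    """Bilinear resize to the backbone input size plus channel normalization.

    ``scale01`` maps 8-bit intensities to [0, 1] (the toy backbone's
    declared scheme); ``identity`` resizes only.
    """
    if scheme not in _PREPROCESS_SCHEMES:
        raise DatasetError(
            f"unknown preprocessing scheme {scheme!r}; known: {_PREPROCESS_SCHEMES}"
        )
    image = np.asarray(image)
    if image.size == 0:
        raise DatasetError("cannot preprocess an empty image")
    img = image.astype(float)
    if image.dtype == np.uint8:
        img = img / 255.0
    if image.shape[:2] != tuple(target_size):
        img = resize(
            img, tuple(target_size), order=1, mode="edge",
            anti_aliasing=image.shape[0] > target_size[0], preserve_range=True,
        )
    if scheme == "identity" and image.dtype != np.uint8:
        return img
    return np.clip(img, 0.0, 1.0)
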