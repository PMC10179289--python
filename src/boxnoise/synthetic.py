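"""Synthetic bitewing-like scenes with calculus-like objects and tight boxes.

Real bitewing radiographs are highly standardized: a dark background, a few
large smooth tooth crowns, and — in positive images — small bright irregular
mineralized deposits attached to the crown margins, with boundaries blurred
by the imaging process.  The generator emulates exactly this structure:

* a low-intensity noisy background,
* 2-4 large smooth mid-intensity elliptical "teeth",
* per image, ``k >= 1`` (truncated-Poisson) high-intensity irregular objects,
  each a union of 2-4 overlapping small ellipses placed along a tooth crown
  margin (a few background pixels clear of the tooth, so every deposit is a
  distinct bright blob),
* a global Gaussian blur.

Ground-truth boxes are the tight bounding rectangles of each object's
pre-blur support — the reproducible definition of an "accurate" label once
blur has made object boundaries ambiguous.  Generation is a pure function of
``(config.seed, image_id)``.

The three intensity bands (background < teeth < objects) are separated by
construction so that a threshold-based detector is learnable; images without
objects are never produced (mirroring a study design that excludes negative
images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import (
    AnnotatedDataset,
    AnnotatedImage,
    AnnotationError,
    BoundingBox,
    split_dataset,
    stable_id_seed,
)

__all__ = [
    "SceneConfig",
    "generate_scene",
    "generate_dataset",
    "render_scene_components",
    "truncated_poisson_mean",
]

# Intensity bands (pre-blur). Objects sit well above teeth, teeth above
# background, so the midpoint-threshold detector has a clean operating point.
BACKGROUND_LEVEL = 0.12
TOOTH_LEVEL = 0.40
TOOTH_LEVEL_JITTER = 0.03
OBJECT_LEVEL = 0.92
OBJECT_LEVEL_JITTER = 0.04


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic scene distribution.

    ``n_objects_mean`` is the mean of the *untruncated* Poisson law; the
    object count is resampled until >= 1, so the realized mean is
    ``truncated_poisson_mean(n_objects_mean)``.
    """

    image_size: int = 256
    n_objects_mean: float = 3.0
    object_diameter_range: tuple[float, float] = (4.0, 16.0)
    tooth_count_range: tuple[int, int] = (2, 4)
    blur_sigma: float = 1.0
    background_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.object_diameter_range
        if not (0 < lo <= hi):
            raise AnnotationError(f"empty object diameter range ({lo}, {hi})")
        if hi * 1.5 >= self.image_size / 2:
            raise AnnotationError(
                f"object diameter range ({lo}, {hi}) too large for "
                f"{self.image_size}px image"
            )
        tlo, thi = self.tooth_count_range
        if not (1 <= tlo <= thi):
            raise AnnotationError(f"empty tooth count range ({tlo}, {thi})")
        if self.image_size < 32:
            raise AnnotationError("image_size must be at least 32 px")
        if self.n_objects_mean <= 0 or self.blur_sigma < 0 or self.background_noise_sd < 0:
            raise AnnotationError("rates and noise scales must be non-negative")


def truncated_poisson_mean(lam: float) -> float:
    """Mean of a Poisson(lam) conditioned on being >= 1."""
    return lam / (1.0 - np.exp(-lam))


def _ellipse_mask(shape, cx, cy, ax, ay, angle):
    """Boolean mask of a rotated ellipse evaluated at pixel centers."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx + 0.5 - cx
    y = yy + 0.5 - cy
    c, s = np.cos(angle), np.sin(angle)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def _sample_truncated_poisson(rng, lam: float) -> int:
    for _ in range(10_000):
        k = int(rng.poisson(lam))
        if k >= 1:
            return k
    return 1  # pragma: no cover - unreachable for any sane lam


def render_scene_components(config: SceneConfig, image_id: str):
    """Render one scene, returning its internal components for diagnostics.

    Returns ``(image, boxes, object_masks, tooth_mask)`` where ``image`` is
    the final blurred scene, ``object_masks`` the per-object pre-blur boolean
    supports and ``tooth_mask`` the pre-blur tooth support (objects excluded).
    """
    size = config.image_size
    rng = np.random.default_rng(stable_id_seed(config.seed, image_id))

    canvas = np.full((size, size), BACKGROUND_LEVEL)
    canvas += rng.normal(0.0, config.background_noise_sd, size=canvas.shape)

    # Teeth: vertically elongated smooth ellipses spread across the image,
    # like crowns in a bitewing.
    tlo, thi = config.tooth_count_range
    n_teeth = int(rng.integers(tlo, thi + 1))
    tooth_mask = np.zeros((size, size), dtype=bool)
    tooth_params = []
    for t in range(n_teeth):
        cx = size * (t + 0.5 + rng.uniform(-0.08, 0.08)) / n_teeth
        cy = size * rng.uniform(0.40, 0.60)
        ax = size * rng.uniform(0.10, 0.14)
        ay = size * rng.uniform(0.22, 0.32)
        angle = rng.uniform(-0.15, 0.15)
        mask = _ellipse_mask(canvas.shape, cx, cy, ax, ay, angle)
        level = TOOTH_LEVEL + rng.uniform(-TOOTH_LEVEL_JITTER, TOOTH_LEVEL_JITTER)
        canvas[mask] = level
        tooth_mask |= mask
        tooth_params.append((cx, cy, ax, ay, angle))

    # Calculus-like objects: irregular unions of small ellipses placed along
    # the tooth crown margins, a few background pixels clear of the tooth so
    # each deposit remains a distinct bright blob, mutually separated.
    k = _sample_truncated_poisson(rng, config.n_objects_mean)
    dlo, dhi = config.object_diameter_range
    margin = dhi * 1.5
    forbidden = ndimage.binary_dilation(tooth_mask, iterations=3)
    centers: list[tuple[float, float, float]] = []  # (cx, cy, diameter)
    object_masks: list[np.ndarray] = []
    boxes: list[BoundingBox] = []
    placed = 0
    for _ in range(300):
        if placed == k:
            break
        d = rng.uniform(dlo, dhi)
        cx0, cy0, ax, ay, angle = tooth_params[int(rng.integers(n_teeth))]
        theta = rng.uniform(0, 2 * np.pi)
        # Point on the tooth boundary, pushed outward along the radial
        # direction so the deposit sits just off the crown margin.
        u, v = ax * np.cos(theta), ay * np.sin(theta)
        c, s = np.cos(angle), np.sin(angle)
        bx, by = cx0 + c * u - s * v, cy0 + s * u + c * v
        norm = np.hypot(bx - cx0, by - cy0)
        off = d * 0.9 + rng.uniform(4.0, 8.0)
        cx = float(np.clip(bx + (bx - cx0) / norm * off, margin, size - margin))
        cy = float(np.clip(by + (by - cy0) / norm * off, margin, size - margin))
        if any(np.hypot(cx - px, cy - py) < (d + pd) / 2 + 6 for px, py, pd in centers):
            continue
        mask = np.zeros((size, size), dtype=bool)
        n_lobes = int(rng.integers(2, 5))
        for lobe in range(n_lobes):
            if lobe == 0:
                # principal lobe spans the drawn diameter
                lx, ly = cx, cy
                lax = d / 2
                lay = d / 2 * rng.uniform(0.6, 1.0)
            else:
                off = d / 3
                lx = cx + rng.uniform(-off, off)
                ly = cy + rng.uniform(-off, off)
                scale = rng.uniform(0.4, 0.8)
                lax = max(d / 2 * scale * rng.uniform(0.6, 1.0), 1.0)
                lay = max(d / 2 * scale * rng.uniform(0.6, 1.0), 1.0)
            mask |= _ellipse_mask(canvas.shape, lx, ly, lax, lay,
                                  rng.uniform(0, np.pi))
        if not mask.any() or (mask & forbidden).any():
            continue
        rows0 = np.flatnonzero(mask.any(axis=1))
        cols0 = np.flatnonzero(mask.any(axis=0))
        extent = max(rows0[-1] - rows0[0] + 1, cols0[-1] - cols0[0] + 1)
        if extent < dlo:  # pixelization can under-sample a minimal deposit
            continue
        level = OBJECT_LEVEL + rng.uniform(-OBJECT_LEVEL_JITTER, OBJECT_LEVEL_JITTER)
        canvas[mask] = level
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        boxes.append(BoundingBox.from_corners(
            float(cols[0]), float(rows[0]), float(cols[-1] + 1), float(rows[-1] + 1)
        ))
        object_masks.append(mask)
        centers.append((cx, cy, d))
        placed += 1
    if placed == 0:  # pragma: no cover - placement always succeeds in practice
        raise AnnotationError(f"could not place any object in scene {image_id!r}")

    tooth_mask &= ~np.logical_or.reduce(object_masks)
    image = ndimage.gaussian_filter(canvas, config.blur_sigma)
    image = np.clip(image, 0.0, 1.0)
    return image, tuple(boxes), tuple(object_masks), tooth_mask


def generate_scene(config: SceneConfig, image_id: str) -> AnnotatedImage:
    """Generate one annotated scene, deterministic in ``(config.seed, image_id)``."""
    image, boxes, _, _ = render_scene_components(config, image_id)
    return AnnotatedImage(image=image, boxes=boxes, image_id=image_id)


def generate_dataset(config: SceneConfig, n_images: int) -> AnnotatedDataset:
    """Generate ``n_images`` scenes with a default 60/20/20 split.

    Image ids are ``scene_0000`` ... and the split shuffle is seeded from
    ``config.seed``, so the whole dataset is reproducible.
    """
    if n_images < 5:
        raise AnnotationError(f"need at least 5 images, got {n_images}")
    images = tuple(
        generate_scene(config, f"scene_{i:04d}") for i in range(n_images)
    )
    splits = {im.image_id: "train" for im in images}
    ds = AnnotatedDataset(images=images, splits=splits,
                          metadata={"generator": {"seed": int(config.seed),
                                                  "n_images": int(n_images)}})
    return split_dataset(ds, seed=config.seed)
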