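"""Label-corruption models for bounding-box annotations.

Two corruption regimes are provided:

* **Consistent noise** — every box in the dataset has its *area* scaled by the
  same factor ``alpha`` (the center is kept and each side is multiplied by
  ``sqrt(alpha)``), emulating a single annotator who is systematically
  miscalibrated: ``alpha < 1`` means consistently too-small boxes,
  ``alpha > 1`` consistently too-large ones.

* **Inconsistent noise** — the images are partitioned into three near-equal
  thirds standing for three hypothetical annotators: one labels accurately
  (``alpha = 1``), one too large (``alpha = 1 + delta``) and one too small
  (``alpha = 1 - delta``), with ``delta`` in ``(0, 1)``.

Only the labels are corrupted; pixels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotatedDataset, AnnotationError, BoundingBox

__all__ = [
    "ALPHA_GRID",
    "DELTA_GRID",
    "ConsistentNoiseConfig",
    "InconsistentNoiseConfig",
    "scale_box",
    "apply_consistent_noise",
    "apply_inconsistent_noise",
]

#: The consistent-noise area-scale grid used in the sweep experiments:
#: 0.1 ... 0.9 (step 0.1), 1 ... 10 (step 1), 20 ... 100 (step 10) — 28 values.
ALPHA_GRID: tuple[float, ...] = tuple(
    round(a, 10) for a in (
        [0.1 * k for k in range(1, 10)] + list(range(1, 11)) + list(range(20, 101, 10))
    )
)

#: The inconsistent-noise deviation grid: 0.1 ... 0.9 in 0.1 steps.
DELTA_GRID: tuple[float, ...] = tuple(round(0.1 * k, 10) for k in range(1, 10))

#: Minimum side length (px) a shrunken box is allowed to reach.
MIN_SIDE = 1.0


@dataclass(frozen=True)
class ConsistentNoiseConfig:
    """Area scale factor applied to every box; ``alpha = 1`` is the identity."""

    alpha: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise AnnotationError(f"alpha must be a positive real, got {self.alpha}")


@dataclass(frozen=True)
class InconsistentNoiseConfig:
    """Three-annotator corruption: per-third area factors (1, 1+delta, 1-delta)."""

    delta: float
    partition_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            raise AnnotationError(f"delta must lie in (0, 1), got {self.delta}")

    @property
    def third_alphas(self) -> tuple[float, float, float]:
        """Area factors for the (accurate, enlarging, shrinking) annotators."""
        return (1.0, 1.0 + self.delta, 1.0 - self.delta)


def scale_box(box: BoundingBox, alpha: float, image_width: float,
              image_height: float) -> BoundingBox:
    """Scale a box's area by ``alpha`` about its center, then clip to the image.

    Each side is multiplied by ``sqrt(alpha)`` so the area scales by exactly
    ``alpha``.  Sides are floored at 1 px to avoid degenerate boxes under
    strong shrinking, and the scaled box is clipped to the image rectangle
    (which may shift its center when the enlarged box overhangs the border).
    """
    if not (alpha > 0 and np.isfinite(alpha)):
        raise AnnotationError(f"alpha must be a positive real, got {alpha}")
    s = float(np.sqrt(alpha))
    # Floor shrunken sides at 1 px (never *grow* a box that was already
    # sub-pixel, so alpha = 1 stays the exact identity).
    w = max(box.w * s, min(MIN_SIDE, box.w))
    h = max(box.h * s, min(MIN_SIDE, box.h))
    if (box.x - w / 2 >= 0 and box.y - h / 2 >= 0
            and box.x + w / 2 <= image_width and box.y + h / 2 <= image_height):
        # no clipping: keep the center representation bit-exact
        return BoundingBox(box.x, box.y, w, h)
    x1 = max(box.x - w / 2, 0.0)
    y1 = max(box.y - h / 2, 0.0)
    x2 = min(box.x + w / 2, float(image_width))
    y2 = min(box.y + h / 2, float(image_height))
    if x2 <= x1 or y2 <= y1:
        raise AnnotationError(
            f"scaled box has empty intersection with {image_width}x{image_height} image"
        )
    return BoundingBox.from_corners(x1, y1, x2, y2)


def apply_consistent_noise(dataset: AnnotatedDataset,
                           config: ConsistentNoiseConfig) -> AnnotatedDataset:
    """Scale every box in every split by the same area factor ``alpha``."""
    out = dataset.map_boxes(
        lambda im: [scale_box(b, config.alpha, im.width, im.height) for b in im.boxes]
    )
    meta = dict(out.metadata)
    meta["noise"] = {"mode": "consistent", "alpha": float(config.alpha)}
    return AnnotatedDataset(images=out.images, splits=out.splits, metadata=meta)


def apply_inconsistent_noise(dataset: AnnotatedDataset,
                             config: InconsistentNoiseConfig) -> AnnotatedDataset:
    """Corrupt the dataset as three annotators labeling one third each.

    The images are partitioned (seeded by ``partition_seed``) into three
    disjoint thirds whose sizes differ by at most one; boxes in the first
    third are kept, the second third is enlarged with ``alpha = 1 + delta``
    and the last third shrunk with ``alpha = 1 - delta``.  The per-image
    annotator assignment is recorded in the returned dataset's metadata.
    """
    n = len(dataset)
    if n < 3:
        raise AnnotationError(f"inconsistent noise needs >= 3 images, got {n}")
    rng = np.random.default_rng(config.partition_seed)
    order = rng.permutation(n)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    alphas = config.third_alphas
    names = ("accurate", "enlarged", "shrunken")
    assignment: dict[str, str] = {}
    factor: dict[str, float] = {}
    start = 0
    for size, name, a in zip(sizes, names, alphas):
        for idx in order[start:start + size]:
            image_id = dataset.images[idx].image_id
            assignment[image_id] = name
            factor[image_id] = a
        start += size

    out = dataset.map_boxes(
        lambda im: [scale_box(b, factor[im.image_id], im.width, im.height)
                    for b in im.boxes]
    )
    meta = dict(out.metadata)
    meta["noise"] = {
        "mode": "inconsistent",
        "delta": float(config.delta),
        "partition_seed": int(config.partition_seed),
        "partition": assignment,
    }
    return AnnotatedDataset(images=out.images, splits=out.splits, metadata=meta)
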