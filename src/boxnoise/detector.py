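"""A deterministic, desk-scale surrogate detector that learns from its labels.

The detector has exactly two learned components, both estimated from the
training annotations:

* an intensity **threshold** — the midpoint between the mean intensity of
  pixels inside training boxes and the mean intensity of pixels outside all
  boxes, pooled over the training set; and
* a **box-size prior** — per-axis median ratios between annotated box sides
  and the sides of the thresholded blob each annotation covers.

Because both components are functions of the labels, systematic label-size
bias propagates into the predictions: training on boxes enlarged by an area
factor ``alpha`` inflates the size prior by ``sqrt(alpha)`` per side (the
model "learns the annotation error"), and over- or under-sized boxes shift
the threshold by diluting the inside-pixel mean with background or cutting
away dim object peripheries.  This is the one property of a supervised
detector that a label-noise impact study needs, kept in a form that is exact,
fast and deterministic.

Inference thresholds the image, extracts 8-connected blobs, and emits one
detection per blob: the blob's tight bounding rectangle rescaled about the
blob centroid by the learned size prior, with a confidence that increases
with mean blob brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .annotations import AnnotatedImage, AnnotationError, BoundingBox

__all__ = ["DetectorModel", "Detection", "fit", "detect"]

#: 8-connectivity structuring element for blob labeling.
_STRUCTURE = np.ones((3, 3), dtype=bool)


class FitError(RuntimeError):
    """Raised when the detector cannot be estimated from the given data."""


@dataclass(frozen=True)
class DetectorModel:
    """Learned state of the surrogate detector."""

    threshold: float
    size_scale_w: float
    size_scale_h: float
    min_blob_area: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise AnnotationError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.size_scale_w <= 0 or self.size_scale_h <= 0:
            raise AnnotationError("size scales must be positive")


@dataclass(frozen=True)
class Detection:
    """A predicted box with a confidence score in ``(0, 1]``."""

    box: BoundingBox
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence <= 1.0):
            raise AnnotationError(f"confidence must be in (0, 1], got {self.confidence}")


def _box_pixel_mask(shape, boxes) -> np.ndarray:
    """Boolean mask of pixels whose square intersects any of the boxes."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    for b in boxes:
        c0 = int(np.clip(np.floor(b.x1), 0, w))
        c1 = int(np.clip(np.ceil(b.x2), 0, w))
        r0 = int(np.clip(np.floor(b.y1), 0, h))
        r1 = int(np.clip(np.ceil(b.y2), 0, h))
        mask[r0:r1, c0:c1] = True
    return mask


def _blobs(image: np.ndarray, threshold: float, min_area: int):
    """Yield ``(slice_rows, slice_cols, mask, area, centroid_xy, mean_intensity)``
    for each 8-connected blob of ``image >= threshold`` with area >= min_area."""
    binary = image >= threshold
    labels, n = ndimage.label(binary, structure=_STRUCTURE)
    if n == 0:
        return
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        mask = labels[sl] == lab
        area = int(mask.sum())
        if area < min_area:
            continue
        rows, cols = np.nonzero(mask)
        # Continuous centroid: pixel centers are offset by +0.5 from indices.
        cy = rows.mean() + sl[0].start + 0.5
        cx = cols.mean() + sl[1].start + 0.5
        mean_int = float(image[sl][mask].mean())
        yield sl, mask, area, (float(cx), float(cy)), mean_int


def fit(train_images) -> DetectorModel:
    """Estimate the detector from annotated training images.

    The threshold is the midpoint of the pooled inside-box and outside-box
    mean intensities.  The size prior is the per-axis median, over blobs
    whose centroid falls inside a training box, of annotated-side /
    blob-rectangle-side ratios (1.0 if no blob matches any box).
    """
    train_images = list(train_images)
    if not train_images or all(len(im.boxes) == 0 for im in train_images):
        raise FitError("nothing to fit: no training boxes")

    inside_sum = inside_n = outside_sum = outside_n = 0.0
    for im in train_images:
        mask = _box_pixel_mask(im.image.shape, im.boxes)
        inside_sum += float(im.image[mask].sum())
        inside_n += int(mask.sum())
        outside_sum += float(im.image[~mask].sum())
        outside_n += int((~mask).sum())
    if inside_n == 0:
        raise FitError("training boxes cover no pixels")
    inside_mean = inside_sum / inside_n
    outside_mean = outside_sum / outside_n if outside_n else 0.0
    threshold = float(np.clip((inside_mean + outside_mean) / 2, 1e-3, 1 - 1e-3))

    ratios_w: list[float] = []
    ratios_h: list[float] = []
    for im in train_images:
        for sl, _mask, _area, (cx, cy), _mi in _blobs(im.image, threshold, 2):
            containing = [b for b in im.boxes
                          if b.x1 <= cx <= b.x2 and b.y1 <= cy <= b.y2]
            if not containing:
                continue
            # Nearest-center box wins if the centroid sits in several.
            b = min(containing, key=lambda b: (b.x - cx) ** 2 + (b.y - cy) ** 2)
            blob_w = sl[1].stop - sl[1].start
            blob_h = sl[0].stop - sl[0].start
            ratios_w.append(b.w / blob_w)
            ratios_h.append(b.h / blob_h)

    size_scale_w = float(np.median(ratios_w)) if ratios_w else 1.0
    size_scale_h = float(np.median(ratios_h)) if ratios_h else 1.0
    return DetectorModel(threshold=threshold, size_scale_w=size_scale_w,
                         size_scale_h=size_scale_h)


def detect(image: np.ndarray, model: DetectorModel) -> list[Detection]:
    """Run the detector on one image, returning detections sorted by
    descending confidence (ties broken by blob discovery order)."""
    if not isinstance(model, DetectorModel):
        raise FitError("detect requires a fitted DetectorModel")
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    dets: list[Detection] = []
    for sl, _mask, _area, (cx, cy), mean_int in _blobs(
            image, model.threshold, model.min_blob_area):
        x1 = sl[1].start
        x2 = sl[1].stop
        y1 = sl[0].start
        y2 = sl[0].stop
        # Rescale the tight rectangle about the blob centroid, then clip.
        nx1 = max(cx + (x1 - cx) * model.size_scale_w, 0.0)
        nx2 = min(cx + (x2 - cx) * model.size_scale_w, float(w))
        ny1 = max(cy + (y1 - cy) * model.size_scale_h, 0.0)
        ny2 = min(cy + (y2 - cy) * model.size_scale_h, float(h))
        if nx2 <= nx1 or ny2 <= ny1:
            continue
        conf = min(1.0, (mean_int - model.threshold) / (1.0 - model.threshold) + 0.5)
        if conf <= 0:
            continue
        dets.append(Detection(box=BoundingBox.from_corners(nx1, ny1, nx2, ny2),
                              confidence=conf))
    dets.sort(key=lambda d: -d.confidence)
    return dets
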