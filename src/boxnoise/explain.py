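"""Super-pixel Shapley attribution for single detections, with heatmap export.

The image is tiled by a regular grid of super pixels (default 20 x 20 = 400
cells; remainder pixels of non-divisible image sizes are absorbed by the last
row/column of cells).  Each cell is one player in a cooperative game whose
value is a scalar *detection persistence* score: re-run the detector on the
partially masked image and take the best ``confidence x IoU`` agreement of
any resulting detection with the target detection (0 if nothing overlaps).
Masked cells are filled with a background-level constant, by default the mean
intensity of the image's sub-threshold pixels — neutral with respect to the
learned threshold.

Shapley values are estimated by permutation sampling: for each of
``n_evaluations`` random cell permutations, cells are unmasked one at a time
and each cell is credited its marginal change in the score; attributions are
the per-cell averages.  The estimator telescopes along every permutation, so
the efficiency identity ``sum(phi) = full_value - base_value`` holds exactly
on every run.  With ``exhaustive=True`` all permutations are enumerated and
the estimate equals the exact Shapley value (small grids only).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import matplotlib
from PIL import Image

from .annotations import AnnotationError
from .detector import Detection, DetectorModel, detect
from .evaluation import iou

__all__ = [
    "SuperPixelGrid",
    "ShapMap",
    "detection_score_functional",
    "shapley_attribution",
    "permutation_shapley",
    "render_heatmap",
]


@dataclass(frozen=True)
class SuperPixelGrid:
    """Regular partition of an image into ``rows x cols`` rectangular cells."""

    rows: int = 20
    cols: int = 20

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise AnnotationError(f"degenerate grid {self.rows}x{self.cols}")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def cell_slices(self, image_shape) -> list[tuple[slice, slice]]:
        """Pixel extent of each cell, row-major; remainders go to the last
        row/column so exactly ``rows x cols`` cells tile the image."""
        h, w = image_shape
        if h < self.rows or w < self.cols:
            raise AnnotationError(
                f"image {h}x{w} too small for a {self.rows}x{self.cols} grid"
            )
        rh, cw = h // self.rows, w // self.cols
        out = []
        for r in range(self.rows):
            r1 = h if r == self.rows - 1 else (r + 1) * rh
            for c in range(self.cols):
                c1 = w if c == self.cols - 1 else (c + 1) * cw
                out.append((slice(r * rh, r1), slice(c * cw, c1)))
        return out


@dataclass(frozen=True)
class ShapMap:
    """Per-cell attributions with the game's anchoring values."""

    phi: np.ndarray  # shape (rows, cols)
    base_value: float
    full_value: float
    n_evaluations: int
    grid: SuperPixelGrid


def detection_score_functional(image: np.ndarray, model: DetectorModel,
                               target: Detection) -> float:
    """How strongly the target detection persists on a (possibly masked) image.

    Runs the detector and returns the maximum over its detections of
    ``confidence x IoU(detection, target)``; 0 when no detection overlaps the
    target.  On the unmasked image this equals the target's own confidence
    (self-IoU 1); it degrades continuously as masking destroys the object.
    """
    dets = detect(image, model)
    if not dets:
        return 0.0
    return max(d.confidence * iou(d.box, target.box) for d in dets)


def permutation_shapley(value_fn, n_items: int, n_evaluations: int = 25,
                        seed: int = 0, exhaustive: bool = False):
    """Permutation-sampling Shapley estimator for a set function.

    ``value_fn(included)`` maps a boolean inclusion vector of length
    ``n_items`` to a scalar.  Returns ``(phi, base_value, full_value,
    n_passes)``.  With ``exhaustive=True`` every permutation is walked once
    and the result is the exact Shapley value.
    """
    if n_items < 1:
        raise AnnotationError("need at least one item")
    base_value = float(value_fn(np.zeros(n_items, dtype=bool)))
    full_value = float(value_fn(np.ones(n_items, dtype=bool)))
    if exhaustive:
        perms = itertools.permutations(range(n_items))
        n_passes = math.factorial(n_items)
    else:
        if n_evaluations < 1:
            raise AnnotationError("n_evaluations must be >= 1")
        rng = np.random.default_rng(seed)
        perms = (rng.permutation(n_items) for _ in range(n_evaluations))
        n_passes = n_evaluations
    phi = np.zeros(n_items)
    for perm in perms:
        included = np.zeros(n_items, dtype=bool)
        prev = base_value
        for item in perm:
            included[item] = True
            cur = float(value_fn(included))
            phi[item] += cur - prev
            prev = cur
    phi /= n_passes
    return phi, base_value, full_value, n_passes


def shapley_attribution(image: np.ndarray, model: DetectorModel,
                        target: Detection, grid: SuperPixelGrid = SuperPixelGrid(),
                        n_evaluations: int = 25, seed: int = 0,
                        fill_value: float | None = None,
                        exhaustive: bool = False) -> ShapMap:
    """Attribute the persistence of one detection to the image's super pixels.

    ``fill_value`` replaces masked pixels; when None it defaults to the mean
    of the image's sub-threshold (background) pixels, falling back to the
    global mean if the whole image exceeds the threshold.  One "evaluation"
    is one full permutation pass over the grid cells.
    """
    image = np.asarray(image, dtype=float)
    slices = grid.cell_slices(image.shape)
    if fill_value is None:
        below = image[image < model.threshold]
        fill_value = float(below.mean()) if below.size else float(image.mean())

    masked_template = np.full_like(image, fill_value)

    def value_fn(included: np.ndarray) -> float:
        work = masked_template.copy()
        for i in np.flatnonzero(included):
            rs, cs = slices[i]
            work[rs, cs] = image[rs, cs]
        return detection_score_functional(work, model, target)

    phi, base_value, full_value, n_passes = permutation_shapley(
        value_fn, grid.n_cells, n_evaluations=n_evaluations, seed=seed,
        exhaustive=exhaustive)
    return ShapMap(phi=phi.reshape(grid.rows, grid.cols), base_value=base_value,
                   full_value=full_value, n_evaluations=n_passes, grid=grid)


def render_heatmap(shap: ShapMap, image: np.ndarray, out) -> None:
    """Write a PNG overlay: red = positive attribution, blue = negative.

    The color scale is a diverging map symmetric about zero; overlay opacity
    grows with attribution magnitude, so zero attribution leaves the plain
    grayscale image.  The written PNG has exactly the image's dimensions.
    """
    image = np.asarray(image, dtype=float)
    slices = shap.grid.cell_slices(image.shape)
    phi_px = np.zeros_like(image)
    for (rs, cs), v in zip(slices, shap.phi.ravel()):
        phi_px[rs, cs] = v
    vmax = float(np.abs(shap.phi).max())
    scaled = phi_px / vmax if vmax > 0 else phi_px  # in [-1, 1]
    rgba = matplotlib.colormaps["bwr"](0.5 * (scaled + 1.0))  # diverging, white at 0
    alpha = 0.5 * np.abs(scaled)
    gray = np.clip(image, 0.0, 1.0)[..., None].repeat(3, axis=-1)
    blended = gray * (1.0 - alpha[..., None]) + rgba[..., :3] * alpha[..., None]
    arr = np.clip(np.rint(blended * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(out)
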