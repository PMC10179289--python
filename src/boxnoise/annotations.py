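"""Domain types and I/O for annotated grayscale images.

Coordinate convention: continuous pixel coordinates, origin at the top-left
corner, x increasing rightward and y increasing downward.  A pixel with array
index ``(row, col)`` occupies the continuous square ``[col, col+1) x [row,
row+1)`` and its center sits at ``(col + 0.5, row + 0.5)``.  Boxes are closed
axis-aligned rectangles in this continuous space, so geometric quantities
(areas, intersections) are exact and independent of rasterization.

Annotation files use the YOLO txt dialect: one line per box,
``class cx cy w h`` with all four geometry fields normalized to ``[0, 1]`` by
the image width/height.  A single object class (id 0) is used throughout.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "BoundingBox",
    "AnnotatedImage",
    "AnnotatedDataset",
    "AnnotationError",
    "SPLIT_NAMES",
    "DEFAULT_SPLIT_FRACTIONS",
    "read_yolo_annotations",
    "write_yolo_annotations",
    "split_dataset",
    "save_dataset",
    "load_dataset",
    "stable_id_seed",
]

SPLIT_NAMES = ("train", "val", "test")
DEFAULT_SPLIT_FRACTIONS = (0.6, 0.2, 0.2)


class AnnotationError(ValueError):
    """Raised for invalid boxes, malformed annotation files, or bad splits."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box given by center ``(x, y)`` and side lengths ``(w, h)``.

    All fields are continuous pixel quantities; ``w`` and ``h`` must be
    strictly positive.
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise AnnotationError(f"box field {name!r} is not finite: {v}")
        if self.w <= 0 or self.h <= 0:
            raise AnnotationError(
                f"box sides must be positive, got w={self.w}, h={self.h}"
            )

    @property
    def x1(self) -> float:
        return self.x - self.w / 2

    @property
    def y1(self) -> float:
        return self.y - self.h / 2

    @property
    def x2(self) -> float:
        return self.x + self.w / 2

    @property
    def y2(self) -> float:
        return self.y + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """``(x1, y1, x2, y2)`` corner representation."""
        return (self.x1, self.y1, self.x2, self.y2)

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls(x=(x1 + x2) / 2, y=(y1 + y2) / 2, w=x2 - x1, h=y2 - y1)


@dataclass(frozen=True)
class AnnotatedImage:
    """A grayscale image with its ground-truth boxes.

    ``image`` is a 2-D float array with intensities in ``[0, 1]``; every box
    center must lie inside the image bounds.
    """

    image: np.ndarray
    boxes: tuple[BoundingBox, ...]
    image_id: str

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2 or img.shape[0] <= 0 or img.shape[1] <= 0:
            raise AnnotationError(f"image must be 2-D with positive dims, got shape {img.shape}")
        object.__setattr__(self, "image", img)
        object.__setattr__(self, "boxes", tuple(self.boxes))
        h, w = img.shape
        for b in self.boxes:
            if not (0 <= b.x <= w and 0 <= b.y <= h):
                raise AnnotationError(
                    f"box center ({b.x}, {b.y}) outside {w}x{h} image {self.image_id!r}"
                )

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]

    def with_boxes(self, boxes) -> "AnnotatedImage":
        return replace(self, boxes=tuple(boxes))


@dataclass(frozen=True)
class AnnotatedDataset:
    """Images plus a train/val/test split assignment.

    ``splits`` maps every image id to one of ``SPLIT_NAMES``; it must be a
    partition of the image ids (disjoint and exhaustive).  ``metadata``
    records provenance such as applied noise configurations.
    """

    images: tuple[AnnotatedImage, ...]
    splits: dict[str, str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "images", tuple(self.images))
        ids = [im.image_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate image ids in dataset")
        if set(self.splits) != set(ids):
            missing = set(ids) - set(self.splits)
            extra = set(self.splits) - set(ids)
            raise AnnotationError(
                f"splits must cover image ids exactly (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        bad = {i: s for i, s in self.splits.items() if s not in SPLIT_NAMES}
        if bad:
            raise AnnotationError(f"unknown split names: {bad}")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, split: str) -> tuple[AnnotatedImage, ...]:
        """Images assigned to one split, in dataset order."""
        if split not in SPLIT_NAMES:
            raise AnnotationError(f"unknown split {split!r}")
        return tuple(im for im in self.images if self.splits[im.image_id] == split)

    def map_boxes(self, fn) -> "AnnotatedDataset":
        """Apply ``fn(image) -> new box list`` to every image, keeping pixels."""
        new = tuple(im.with_boxes(fn(im)) for im in self.images)
        return replace(self, images=new)


def stable_id_seed(base_seed: int, image_id: str) -> np.random.SeedSequence:
    """Deterministic per-image seed sequence derived from a base seed and id."""
    return np.random.SeedSequence([int(base_seed) % (2**31), zlib.crc32(image_id.encode())])


# ---------------------------------------------------------------------------
# YOLO txt dialect
# ---------------------------------------------------------------------------

def read_yolo_annotations(path, image_width: int, image_height: int) -> list[BoundingBox]:
    """Read a YOLO txt annotation file, denormalizing to pixel coordinates.

    Each non-blank line must be ``class cx cy w h`` with the four geometry
    fields in ``[0, 1]``.  An empty file yields an empty list.
    """
    boxes: list[BoundingBox] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise AnnotationError(
                f"{path}:{lineno}: expected 5 fields, got {len(parts)}"
            )
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
        if cls != 0:
            raise AnnotationError(f"{path}:{lineno}: unexpected class id {cls}")
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0.0 <= v <= 1.0):
                raise AnnotationError(
                    f"{path}:{lineno}: normalized {name}={v} outside [0, 1]"
                )
        boxes.append(
            BoundingBox(x=cx * image_width, y=cy * image_height,
                        w=w * image_width, h=h * image_height)
        )
    return boxes


def write_yolo_annotations(boxes, path, image_width: int, image_height: int) -> None:
    """Write boxes as YOLO txt with 6-decimal fixed precision (class id 0).

    Boxes whose normalized fields fall outside ``[0, 1]`` are refused; callers
    must clip to the image first.
    """
    if image_width <= 0 or image_height <= 0:
        raise AnnotationError("image dimensions must be positive")
    lines = []
    for i, b in enumerate(boxes):
        vals = (b.x / image_width, b.y / image_height,
                b.w / image_width, b.h / image_height)
        for name, v in zip(("cx", "cy", "w", "h"), vals):
            if not (0.0 <= v <= 1.0):
                raise AnnotationError(
                    f"box {i}: normalized {name}={v:.6g} outside [0, 1]; clip before writing"
                )
        lines.append("0 " + " ".join(f"{v:.6f}" for v in vals))
    Path(path).write_text("".join(line + "\n" for line in lines))


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(dataset: AnnotatedDataset, fractions=DEFAULT_SPLIT_FRACTIONS,
                  seed: int = 0) -> AnnotatedDataset:
    """Randomly re-assign train/val/test splits.

    Split sizes follow the fractions by largest-remainder rounding; the
    shuffle is seeded, so a fixed seed reproduces the assignment and distinct
    seeds give the independent re-partitions used for cross-validation.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise AnnotationError(f"need 3 positive fractions, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise AnnotationError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset)
    if n < 5:
        raise AnnotationError(f"need at least 5 images to populate all splits, got {n}")

    # Largest-remainder apportionment of n among the three splits.
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: n - sum(counts)]:
        counts[i] += 1

    rng = np.random.default_rng(seed)
    ids = [im.image_id for im in dataset.images]
    order = [ids[i] for i in rng.permutation(n)]
    splits: dict[str, str] = {}
    start = 0
    for name, c in zip(SPLIT_NAMES, counts):
        for image_id in order[start:start + c]:
            splits[image_id] = name
        start += c
    return replace(dataset, splits=splits)


# ---------------------------------------------------------------------------
# On-disk dataset layout: PNG + YOLO txt + manifest.yaml
# ---------------------------------------------------------------------------

def save_dataset(dataset: AnnotatedDataset, out_dir) -> Path:
    """Export a dataset as 8-bit grayscale PNGs, YOLO txt files and a manifest.

    Returns the manifest path.  Boxes are clipped-validated by the YOLO
    writer; images are scaled from ``[0, 1]`` to 8-bit.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    entries = []
    for im in dataset.images:
        img_rel = f"images/{im.image_id}.png"
        lab_rel = f"labels/{im.image_id}.txt"
        arr = np.clip(np.rint(im.image * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / img_rel)
        write_yolo_annotations(im.boxes, out / lab_rel, im.width, im.height)
        entries.append({
            "id": im.image_id,
            "image": img_rel,
            "annotations": lab_rel,
            "split": dataset.splits[im.image_id],
        })
    manifest = {"images": entries, "metadata": dataset.metadata}
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def load_dataset(manifest_path) -> AnnotatedDataset:
    """Load a dataset previously written by :func:`save_dataset`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = yaml.safe_load(manifest_path.read_text())
    images = []
    splits = {}
    for entry in manifest["images"]:
        arr = np.asarray(Image.open(root / entry["image"]).convert("L"), dtype=float) / 255.0
        boxes = read_yolo_annotations(root / entry["annotations"],
                                      arr.shape[1], arr.shape[0])
        images.append(AnnotatedImage(image=arr, boxes=tuple(boxes), image_id=entry["id"]))
        splits[entry["id"]] = entry["split"]
    return AnnotatedDataset(images=tuple(images), splits=splits,
                            metadata=manifest.get("metadata") or {})
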