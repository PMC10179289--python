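"""From-scratch single-class detection metrics and an exact rank test.

The metric stack follows the standard object-detection recipe: detections are
matched greedily to ground truth in descending confidence order at an IoU
threshold (default 0.5, "mAP50"); precision ``tp/(tp+fp)`` and recall
``tp/(tp+fn)`` are accumulated along the confidence ranking; average
precision is the area under the monotone precision envelope over recall
(all-point interpolation).  With one object class, mAP equals AP.

Two deliberate conventions, both deterministic:

* A detection at IoU *exactly equal* to the threshold counts as a true
  positive (``>=`` rule, as in COCO-style evaluators).  This matters because
  a box and its area-doubled concentric version have IoU exactly 0.5, a case
  that arises by construction when predictions learned from ``alpha = 2``
  labels are scored against accurate labels or vice versa.
* Detections are pooled across all images into a single confidence-ranked
  list (one global precision-recall curve), the common practice when a
  dataset-level AP is reported.

``mann_whitney_u`` implements the exact two-sided Mann-Whitney U test for
small samples (the regime of cross-validation fold scores): the null
distribution of U is computed exactly — by rank-sum counting when there are
no ties, by complete enumeration over group assignments with midranks when
there are — rather than by normal approximation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .annotations import AnnotationError, BoundingBox
from .detector import Detection

__all__ = [
    "MatchResult",
    "EvalResult",
    "iou",
    "match_detections",
    "average_precision",
    "evaluate_dataset",
    "mann_whitney_u",
]


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes in continuous geometry."""
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one image's detections against its ground truth.

    ``flags`` holds one boolean per detection in descending-confidence order
    (True = true positive); ``confidences`` the corresponding scores.
    """

    tp: int
    fp: int
    fn: int
    flags: tuple[bool, ...]
    confidences: tuple[float, ...]

    @property
    def n_truth(self) -> int:
        return self.tp + self.fn


def match_detections(detections, truths, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy confidence-ordered matching at an IoU threshold.

    Each detection, in descending confidence order (stable sort, so input
    order breaks confidence ties), claims the unmatched truth of highest IoU
    provided that IoU is ``>= iou_threshold`` (IoU ties broken by lowest
    truth index).  Claimed truths are consumed; leftover detections are
    false positives and leftover truths false negatives.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise AnnotationError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    dets = sorted(detections, key=lambda d: -d.confidence)
    matched = [False] * len(truths)
    flags: list[bool] = []
    for det in dets:
        best_iou = -1.0
        best_j = -1
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(det.box, t)
            if v > best_iou:  # strict: ties keep the lowest truth index
                best_iou = v
                best_j = j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    tp = sum(flags)
    return MatchResult(tp=tp, fp=len(flags) - tp, fn=len(truths) - tp,
                       flags=tuple(flags),
                       confidences=tuple(d.confidence for d in dets))


def average_precision(flags, n_truth: int) -> float:
    """All-point interpolated AP from per-rank true-positive flags.

    Precision at each rank is ``tp/(tp+fp)`` and recall ``tp/n_truth``; the
    precision envelope (running maximum from the right) is integrated over
    recall.
    """
    if n_truth < 1:
        raise AnnotationError("average precision undefined for n_truth = 0")
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    ranks = np.arange(1, flags.size + 1)
    precision = tp / ranks
    recall = tp / n_truth
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - recall_prev) * envelope))


@dataclass(frozen=True)
class EvalResult:
    """Dataset-level evaluation: pooled PR curve and AP (= mAP50 for 1 class)."""

    precision_curve: tuple[float, ...]
    recall_curve: tuple[float, ...]
    ap: float
    iou_threshold: float
    tp: int
    fp: int
    fn: int
    n_classes: int = 1

    @property
    def map50(self) -> float:
        """Mean AP over classes; identical to AP with a single class."""
        return self.ap


def evaluate_dataset(predictions: dict, truths: dict,
                     iou_threshold: float = 0.5) -> EvalResult:
    """Score per-image detections against per-image ground truth.

    ``predictions`` maps image id -> list of :class:`Detection`, ``truths``
    maps image id -> list of :class:`BoundingBox`; the two id sets must
    coincide.  Matching is per image; the matched flags are then pooled
    across images into one confidence-ranked list from which the global
    precision-recall curve and AP are computed.  Images with truths but no
    detections contribute false negatives.
    """
    pred_ids, truth_ids = set(predictions), set(truths)
    if pred_ids != truth_ids:
        raise AnnotationError(
            "prediction/truth image ids differ: "
            f"only-predictions={sorted(pred_ids - truth_ids)}, "
            f"only-truths={sorted(truth_ids - pred_ids)}"
        )
    pooled: list[tuple[float, int, bool]] = []
    n_truth = 0
    for order, image_id in enumerate(sorted(predictions)):
        m = match_detections(predictions[image_id], truths[image_id], iou_threshold)
        n_truth += m.n_truth
        pooled.extend((c, order, f) for c, f in zip(m.confidences, m.flags))
    if n_truth == 0:
        raise AnnotationError("no ground-truth boxes: AP undefined")
    # Global ranking: descending confidence; ties by image order then rank.
    pooled.sort(key=lambda t: (-t[0], t[1]))
    flags = [f for _, _, f in pooled]
    ap = average_precision(flags, n_truth) if flags else 0.0
    tp_arr = np.cumsum(flags) if flags else np.array([], dtype=int)
    ranks = np.arange(1, len(flags) + 1)
    precision = tuple((tp_arr / ranks).tolist()) if flags else ()
    recall = tuple((tp_arr / n_truth).tolist()) if flags else ()
    tp = int(tp_arr[-1]) if flags else 0
    return EvalResult(precision_curve=precision, recall_curve=recall, ap=float(ap),
                      iou_threshold=iou_threshold, tp=tp, fp=len(flags) - tp,
                      fn=n_truth - tp)


# ---------------------------------------------------------------------------
# Exact Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: pairwise wins plus half-credit for ties."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)

def _exact_u_distribution_no_ties(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U for tie-free data.

    Returns counts over U = 0 .. n1*n2 of the number of rank subsets of size
    n1 achieving each U (classic rank-sum counting recursion).
    """
    # ways[k][s] = number of k-subsets of ranks seen so far with rank-sum s
    max_sum = n1 * (n1 + n2) - n1 * (n1 - 1) // 2
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    ways[0, 0] = 1.0
    for rank in range(1, n1 + n2 + 1):
        for k in range(min(rank, n1), 0, -1):
            ways[k, rank:] += ways[k - 1, :-rank or None]
    sums = np.arange(max_sum + 1)
    counts = np.zeros(n1 * n2 + 1)
    offset = n1 * (n1 + 1) // 2
    valid = (sums >= offset) & (sums <= offset + n1 * n2)
    counts[sums[valid] - offset] = ways[n1, valid]
    return counts


def mann_whitney_u(sample_a, sample_b, max_enumeration: int = 5_000_000):
    """Exact two-sided Mann-Whitney U test for small samples.

    Returns ``(U, p)`` where ``U`` is the statistic of ``sample_a`` (pairwise
    wins plus half-credit for ties) and ``p`` the exact two-sided p-value
    ``min(1, 2 * min(P(U' <= U), P(U' >= U)))`` under the permutation null.
    Tie-free data uses the exact rank-sum counting recursion; data with ties
    is handled by complete enumeration of all group assignments (midranks are
    implicit in the pairwise U), feasible because cross-validation fold
    samples are tiny.  Enumeration beyond ``max_enumeration`` assignments is
    refused rather than silently approximated.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise AnnotationError("both samples must be non-empty")
    u = _u_statistic(a, b)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties:
        counts = _exact_u_distribution_no_ties(n1, n2)
        total = counts.sum()
        us = np.arange(counts.size, dtype=float)
    else:
        n_comb = comb(n1 + n2, n1)
        if n_comb > max_enumeration:
            raise AnnotationError(
                f"tied data with C({n1 + n2},{n1}) = {n_comb} assignments exceeds "
                f"the enumeration limit {max_enumeration}"
            )
        us_list = []
        idx = np.arange(n1 + n2)
        for group_a in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(group_a)] = True
            us_list.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us_list)
        counts = np.ones_like(us)
        total = float(n_comb)
    eps = 1e-9
    p_le = counts[us <= u + eps].sum() / total
    p_ge = counts[us >= u - eps].sum() / total
    return u, float(min(1.0, 2.0 * min(p_le, p_ge)))
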