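"""From heatmaps to boxes, and the localization scoring protocol.

Predicted boxes are the tight axis-aligned boxes of the connected regions
(8-connectivity) of the heatmap thresholded at a constant fraction Q of its
8-bit range.  Overlap is scored as IoBB — intersection area over *predicted*
box area — and a ground-truth-annotated image counts as correctly localized
for class c when at least one predicted box exceeds the IoBB threshold
against at least one ground-truth box (localization accuracy, Lacc).  Boxes
that fail the threshold against every ground-truth box are false positives;
their average count per evaluated image is the FPN.  Evaluation for a class
is restricted to images that carry ground truth for that class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage import measure
from sklearn.metrics import roc_auc_score

from .dataset_io import BoundingBox

__all__ = ["LocalizationResult", "cam_to_boxes", "iobb",
           "localization_accuracy", "false_positive_number", "roc_auc"]

#: box lists keyed by image name, per class: name -> {class_id: [boxes]}
BoxesByImage = Mapping[str, Mapping[int, Sequence[BoundingBox]]]


@dataclass
class LocalizationResult:
    lacc: dict[int, float]
    fpn: dict[int, float]
    q_threshold: float = 0.7
    t_iobb: float = 0.1
    per_image: dict = field(default_factory=dict)


def cam_to_boxes(heatmap_8bit: np.ndarray, q: float = 0.7) -> list[BoundingBox]:
    """Threshold an 8-bit heatmap at ``q * 255`` and box the connected regions.

    Regions are 8-connected; each contributes its tight axis-aligned box.
    An empty mask yields an empty list.  No minimum-area filter is applied.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    hm = np.asarray(heatmap_8bit)
    mask = hm > q * 255.0
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=2)
    boxes = []
    for region in measure.regionprops(labeled):
        y0, x0, y1, x1 = region.bbox          # half-open rows/cols
        boxes.append(BoundingBox(x=x0, y=y0, h=y1 - y0, w=x1 - x0))
    return boxes


def iobb(pred: BoundingBox, gt: BoundingBox) -> float:
    """Intersection area over the predicted box's area, in [0, 1]."""
    if pred.area <= 0:
        raise ValueError("predicted box has zero area")
    ix = max(0.0, min(pred.x2, gt.x2) - max(pred.x, gt.x))
    iy = max(0.0, min(pred.y2, gt.y2) - max(pred.y, gt.y))
    return (ix * iy) / pred.area


def _evaluated_images(ground_truths: BoxesByImage, class_id: int) -> list[str]:
    return [name for name, per_class in ground_truths.items()
            if per_class.get(class_id)]


def localization_accuracy(predictions: BoxesByImage,
                          ground_truths: BoxesByImage,
                          t_iobb: float = 0.1) -> dict[int, float]:
    """Per-class Lacc: fraction of ground-truth-bearing images with at least
    one predicted box whose IoBB against some ground-truth box exceeds
    ``t_iobb`` (strict inequality).  Classes with no annotated images are
    absent from the result."""
    classes = {c for per_class in ground_truths.values() for c in per_class}
    out: dict[int, float] = {}
    for c in sorted(classes):
        names = _evaluated_images(ground_truths, c)
        if not names:
            continue
        hits = 0
        for name in names:
            preds = predictions.get(name, {}).get(c, [])
            gts = ground_truths[name][c]
            if any(iobb(p, g) > t_iobb for p in preds for g in gts):
                hits += 1
        out[c] = hits / len(names)
    return out


def false_positive_number(predictions: BoxesByImage,
                          ground_truths: BoxesByImage,
                          t_iobb: float = 0.1) -> dict[int, float]:
    """Per-class FPN: predicted boxes of class c failing the IoBB threshold
    against every ground-truth box of c, averaged over the evaluated
    (ground-truth-bearing) images of that class."""
    classes = {c for per_class in ground_truths.values() for c in per_class}
    out: dict[int, float] = {}
    for c in sorted(classes):
        names = _evaluated_images(ground_truths, c)
        if not names:
            continue
        n_fp = 0
        for name in names:
            preds = predictions.get(name, {}).get(c, [])
            gts = ground_truths[name][c]
            n_fp += sum(1 for p in preds
                        if all(iobb(p, g) <= t_iobb for g in gts))
        out[c] = n_fp / len(names)
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[dict[int, float], float]:
    """Per-class ROC-AUC (trapezoidal, midrank ties) and the mean over the
    classes for which both label values occur."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    per_class: dict[int, float] = {}
    for c in range(y.shape[1]):
        if len(np.unique(y[:, c])) < 2:
            continue
        per_class[c] = float(roc_auc_score(y[:, c], s[:, c]))
    mean = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return per_class, mean
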