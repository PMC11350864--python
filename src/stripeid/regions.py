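"""Part-region plumbing: COCO box IO, cropping, and detection metrics.

The part detector itself is external; this module consumes its output —
COCO-format boxes over the classes head / left body / right body — crops
the part images, and scores predictions against ground truth with IoU,
precision/recall, all-point-interpolated AP per class, mAP at an IoU
threshold, and a row-normalized confusion matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DetectionBox", "CLASS_NAMES", "read_coco", "write_coco",
           "crop_regions", "iou", "evaluate_detections", "DetectionEval"]

#: canonical class key -> COCO category name
CLASS_NAMES = {"head": "head", "left_body": "left body",
               "right_body": "right body"}
_NAME_TO_KEY = {v: k for k, v in CLASS_NAMES.items()}


@dataclass
class DetectionBox:
    """Axis-aligned box in COCO pixel convention (top-left x/y, w, h)."""

    x: float
    y: float
    w: float
    h: float
    cls: str
    score: float | None = None
    image_id: int = 0

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got "
                             f"w={self.w}, h={self.h}")
        if self.score is not None and not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    @property
    def area(self) -> float:
        return self.w * self.h


def iou(a: DetectionBox, b: DetectionBox) -> float:
    """Intersection area over union area of two boxes."""
    ix = max(0.0, min(a.x + a.w, b.x + b.w) - max(a.x, b.x))
    iy = max(0.0, min(a.y + a.h, b.y + b.h) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# COCO IO


def read_coco(path):
    """Parse a COCO JSON file into (images, boxes, categories).

    ``images``: image id -> metadata dict; ``boxes``: list of
    :class:`DetectionBox` with ``image_id`` set; ``categories``: category
    id -> canonical class key.
    """
    with open(path) as fh:
        doc = json.load(fh)
    images = {img["id"]: img for img in doc.get("images", [])}
    categories = {}
    for cat in doc.get("categories", []):
        name = cat["name"]
        categories[cat["id"]] = _NAME_TO_KEY.get(name, name)
    boxes = []
    for ann in doc.get("annotations", []):
        img_id = ann["image_id"]
        if img_id not in images:
            raise ValueError(f"annotation {ann.get('id')} references unknown "
                             f"image id {img_id}")
        if ann["category_id"] not in categories:
            raise ValueError(f"annotation {ann.get('id')} references unknown "
                             f"category id {ann['category_id']}")
        x, y, w, h = ann["bbox"]
        boxes.append(DetectionBox(x, y, w, h, cls=categories[ann["category_id"]],
                                  score=ann.get("score"), image_id=img_id))
    return images, boxes, categories


def write_coco(images, boxes, path):
    """Write boxes back to COCO JSON (lossless round trip with read_coco)."""
    class_keys = sorted({b.cls for b in boxes} | set(CLASS_NAMES))
    cat_ids = {cls: i + 1 for i, cls in enumerate(class_keys)}
    doc = {
        "images": [dict(img, id=img_id) for img_id, img in sorted(images.items())],
        "categories": [{"id": i, "name": CLASS_NAMES.get(cls, cls)}
                       for cls, i in cat_ids.items()],
        "annotations": [
            {"id": k + 1, "image_id": b.image_id, "category_id": cat_ids[b.cls],
             "bbox": [b.x, b.y, b.w, b.h],
             **({"score": b.score} if b.score is not None else {})}
            for k, b in enumerate(boxes)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def crop_regions(image: np.ndarray, boxes):
    """Pixel-exact crops, one per box, clipped to the image bounds."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    crops = []
    for box in boxes:
        x0, y0 = max(0, int(round(box.x))), max(0, int(round(box.y)))
        x1 = min(w, int(round(box.x + box.w)))
        y1 = min(h, int(round(box.y + box.h)))
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"box {box} has zero area after clipping to "
                             f"{w}x{h} image")
        crops.append((image[y0:y1, x0:x1], box.cls))
    return crops


# ---------------------------------------------------------------------------
# detection metrics


@dataclass
class DetectionEval:
    precision: float
    recall: float
    ap: dict[str, float]
    mean_ap: float
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    confusion: "object"  # pandas DataFrame, rows true / cols predicted
    classes: list[str] = field(default_factory=list)


def _ap_from_flags(tp_flags, n_gt):
    """All-point interpolated area under the precision-recall curve."""
    if n_gt == 0 or len(tp_flags) == 0:
        return 0.0, np.array([0.0]), np.array([0.0])
    tp = np.cumsum(tp_flags)
    fp = np.cumsum(1 - np.asarray(tp_flags))
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # monotone precision envelope from the right, then sum recall steps
    mrec = np.concatenate([[0.0], recall])
    mpre = np.concatenate([[1.0], precision])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    ap = float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))
    return ap, recall, precision


def _sorted_preds(preds):
    # stable sort: descending score, input-order tie break
    return sorted(range(len(preds)), key=lambda i: -_score(preds[i]))


def _score(b):
    if b.score is None:
        raise ValueError("predictions must carry confidence scores")
    return b.score


def _greedy_match(preds, gts, thr, same_class: bool):
    """Greedy score-descending matching; each ground truth used once.

    Returns (matches, tp_flags): matches maps prediction index -> gt index.
    """
    taken = set()
    matches = {}
    for pi in _sorted_preds(preds):
        p = preds[pi]
        best_iou, best_gi = 0.0, None
        for gi, g in enumerate(gts):
            if gi in taken or g.image_id != p.image_id:
                continue
            if same_class and g.cls != p.cls:
                continue
            v = iou(p, g)
            if v >= thr and v > best_iou:
                best_iou, best_gi = v, gi
        if best_gi is not None:
            taken.add(best_gi)
            matches[pi] = best_gi
    return matches


def evaluate_detections(preds, gts, iou_threshold: float = 0.5) -> DetectionEval:
    """Score predicted boxes against ground truth at one IoU threshold.

    AP per class uses greedy per-class matching by descending score with
    each ground truth matched at most once; mAP averages over the classes
    present in the ground truth.  The confusion matrix is matched
    class-agnostically and row-normalized over true classes, with a
    background row/column for false positives / missed boxes.
    """
    import pandas as pd

    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie strictly between 0 and 1")
    preds, gts = list(preds), list(gts)
    classes = sorted({g.cls for g in gts})
    ap, pr_curves = {}, {}
    for cls in classes:
        cp = [p for p in preds if p.cls == cls]
        cg = [g for g in gts if g.cls == cls]
        order = _sorted_preds(cp)
        cp_sorted = [cp[i] for i in order]
        matches = _greedy_match(cp_sorted, cg, iou_threshold, same_class=True)
        flags = [1 if i in matches else 0 for i in range(len(cp_sorted))]
        ap[cls], rec, prec = _ap_from_flags(flags, len(cg))
        pr_curves[cls] = (rec, prec)
    mean_ap = float(np.mean(list(ap.values()))) if ap else 0.0

    matches = _greedy_match(preds, gts, iou_threshold, same_class=True)
    n_tp = len(matches)
    precision = n_tp / len(preds) if preds else 0.0
    recall = n_tp / len(gts) if gts else 0.0

    labels = classes + ["background"]
    conf = pd.DataFrame(0.0, index=labels, columns=labels)
    cam = _greedy_match(preds, gts, iou_threshold, same_class=False)
    matched_gts = set(cam.values())
    for pi, gi in cam.items():
        conf.loc[gts[gi].cls, preds[pi].cls] += 1
    for gi, g in enumerate(gts):
        if gi not in matched_gts:
            conf.loc[g.cls, "background"] += 1
    for pi, p in enumerate(preds):
        if pi not in cam:
            conf.loc["background", p.cls] += 1
    sums = conf.sum(axis=1)
    conf = conf.div(sums.where(sums > 0, 1.0), axis=0)
    return DetectionEval(precision=precision, recall=recall, ap=ap,
                         mean_ap=mean_ap, pr_curves=pr_curves,
                         confusion=conf, classes=classes)
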