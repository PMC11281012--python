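"""Detection evaluation: IoU matching, precision/recall, AP, mAP50(:95).

Matching follows the usual greedy protocol: predictions are visited in
descending confidence and each is assigned to the highest-IoU unmatched
ground truth of its class with IoU strictly greater than the threshold.
AP defaults to the area under the all-point-interpolated precision-recall
curve; a literal accuracy-style variant ``(TP+TN)/(TP+TN+FP+FN)`` with
TN = 0 is kept as ``method="accuracy"`` for completeness (true negatives
are undefined for detection).  mAP is the unweighted mean of per-class AP
over classes that have ground truths; mAP50:95 averages exactly the ten
IoU thresholds 0.50, 0.55, ..., 0.95.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Box",
    "MatchResult",
    "EvalReport",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "f1_score",
    "average_precision",
    "mean_ap",
    "map50_95",
    "confidence_sweep",
    "evaluate",
    "MAP5095_THRESHOLDS",
]

MAP5095_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass
class Box:
    """Axis-aligned box in pixels; ``confidence`` is None for ground truth."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    class_id: int = 0
    confidence: float | None = None

    def __post_init__(self):
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    tn: int = 0
    #: one flag per prediction, in the original order: True = matched a gt
    pred_matched: list[bool] = field(default_factory=list)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def match_detections(preds: list[Box], gts: list[Box], iou_thr: float) -> MatchResult:
    """Greedy confidence-ordered one-to-one matching on a single image.

    Predictions and ground truths must belong to one class partition; the
    IoU comparison is strict (``> iou_thr``).
    """
    order = sorted(range(len(preds)),
                   key=lambda i: -(preds[i].confidence if preds[i].confidence is not None else 1.0))
    gt_used = [False] * len(gts)
    matched = [False] * len(preds)
    for i in order:
        best_j, best_iou = -1, iou_thr
        for j, g in enumerate(gts):
            if gt_used[j]:
                continue
            v = iou(preds[i], g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            gt_used[best_j] = True
            matched[i] = True
    tp = sum(matched)
    return MatchResult(tp=tp, fp=len(preds) - tp, fn=len(gts) - tp, pred_matched=matched)


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); 0 by convention when the denominator is 0."""
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); 0 by convention when the denominator is 0."""
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def f1_score(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def _flat_match(preds: dict, gts: dict, iou_thr: float):
    """Cross-image greedy matching; returns (confidences, tp_flags, n_gt)."""
    records: list[tuple[float, bool]] = []
    n_gt = 0
    for img, gt_list in gts.items():
        n_gt += len(gt_list)
    for img, pred_list in preds.items():
        gt_list = gts.get(img, [])
        res = match_detections(pred_list, gt_list, iou_thr)
        for p, m in zip(pred_list, res.pred_matched):
            records.append((p.confidence if p.confidence is not None else 1.0, m))
    records.sort(key=lambda t: -t[0])
    confs = np.array([c for c, _ in records])
    flags = np.array([m for _, m in records], dtype=bool)
    return confs, flags, n_gt


def average_precision(preds: dict, gts: dict, iou_thr: float = 0.5,
                      method: str = "standard") -> float:
    """Average precision for one class over a set of images.

    ``preds`` and ``gts`` map an image key to its (single-class) box lists.
    ``method="standard"`` integrates the all-point-interpolated PR curve
    built by sweeping the confidence ranking; ``method="accuracy"``
    evaluates the literal accuracy ratio at the fixed operating point of
    all predictions, with TN taken as 0.
    """
    _, flags, n_gt = _flat_match(preds, gts, iou_thr)
    if method == "accuracy":
        tp = int(flags.sum())
        fp = len(flags) - tp
        fn = n_gt - tp
        denom = tp + fp + fn  # + TN, which is 0
        return tp / denom if denom > 0 else 0.0
    if method != "standard":
        raise ValueError(f"unknown AP method: {method!r}")
    if n_gt == 0 or len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_gt
    prec = tp_cum / (tp_cum + fp_cum)
    # all-point interpolation: precision envelope over recall
    mrec = np.concatenate([[0.0], rec, [1.0]])
    mpre = np.concatenate([[0.0], prec, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def _split_by_class(boxes_by_img: dict) -> dict[int, dict]:
    out: dict[int, dict] = {}
    for img, boxes in boxes_by_img.items():
        for b in boxes:
            out.setdefault(b.class_id, {}).setdefault(img, []).append(b)
    return out


def mean_ap(per_class_ap: dict[int, float]) -> float:
    """Unweighted mean of per-class AP; rejects an empty class set."""
    if not per_class_ap:
        raise ValueError("mean AP over an empty class set is undefined")
    return float(np.mean(list(per_class_ap.values())))


def class_aps(preds: dict, gts: dict, iou_thr: float = 0.5) -> dict[int, float]:
    """Per-class AP over classes that appear in the ground truth."""
    pred_c = _split_by_class(preds)
    gt_c = _split_by_class(gts)
    return {
        c: average_precision(pred_c.get(c, {}), gt_c[c], iou_thr)
        for c in sorted(gt_c)
    }


def map50_95(preds: dict, gts: dict) -> float:
    """Mean of mAP over the ten IoU thresholds 0.50 ... 0.95."""
    vals = [mean_ap(class_aps(preds, gts, t)) for t in MAP5095_THRESHOLDS]
    assert len(vals) == 10
    return float(np.mean(vals))


def confidence_sweep(preds: dict, gts: dict, thresholds: list[float],
                     iou_thr: float = 0.5):
    """P/R/F1 curves over confidence thresholds, plus the best-F1 point.

    Counts are pooled over classes and images (micro-averaged): at each
    threshold the predictions are filtered and re-matched per class.
    Returns ``(curves, best)`` where ``curves`` is a list of dicts and
    ``best`` the entry with maximal F1.
    """
    pred_c = _split_by_class(preds)
    gt_c = _split_by_class(gts)
    curves = []
    for thr in thresholds:
        tp = fp = fn = 0
        for c, gt_imgs in gt_c.items():
            p_imgs = pred_c.get(c, {})
            for img, gt_list in gt_imgs.items():
                kept = [p for p in p_imgs.get(img, [])
                        if (p.confidence or 1.0) >= thr]
                res = match_detections(kept, gt_list, iou_thr)
                tp, fp, fn = tp + res.tp, fp + res.fp, fn + res.fn
        # false positives on images with no gt of that class
        for c, p_imgs in pred_c.items():
            gt_imgs = gt_c.get(c, {})
            for img, p_list in p_imgs.items():
                if img not in gt_imgs:
                    fp += sum(1 for p in p_list if (p.confidence or 1.0) >= thr)
        p, r = precision(tp, fp), recall(tp, fn)
        curves.append({"threshold": thr, "precision": p, "recall": r,
                       "f1": f1_score(p, r)})
    best = max(curves, key=lambda c: c["f1"]) if curves else None
    return curves, best


@dataclass
class EvalReport:
    """Structured evaluation summary, JSON-serialisable."""

    per_class_ap50: dict[int, float]
    per_class_ap: dict[int, dict[float, float]]  # class -> iou_thr -> AP
    map50: float
    map50_95: float
    precision: float
    recall: float
    f1: float
    best_operating_point: dict | None

    def to_json(self, path=None) -> str:
        payload = {
            "map50": self.map50,
            "map50_95": self.map50_95,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class_ap50": {str(k): v for k, v in self.per_class_ap50.items()},
            "per_class_ap": {
                str(k): {f"{t:.2f}": v for t, v in d.items()}
                for k, d in self.per_class_ap.items()
            },
            "best_operating_point": self.best_operating_point,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate(preds: dict, gts: dict, conf_thresholds: np.ndarray | None = None) -> EvalReport:
    """Full evaluation of predictions against ground truth.

    Both arguments map an image key to a list of :class:`Box`; prediction
    boxes carry confidences.  Produces per-class AP at every mAP50:95
    threshold, the aggregate mAP50 and mAP50:95, and the P/R/F1 of the
    best confidence operating point at IoU 0.5.
    """
    per_class: dict[int, dict[float, float]] = {}
    pred_c = _split_by_class(preds)
    gt_c = _split_by_class(gts)
    if not gt_c:
        raise ValueError("no ground-truth boxes to evaluate against")
    for c in sorted(gt_c):
        per_class[c] = {
            t: average_precision(pred_c.get(c, {}), gt_c[c], t)
            for t in MAP5095_THRESHOLDS
        }
    ap50 = {c: d[0.5] for c, d in per_class.items()}
    m50 = mean_ap(ap50)
    m5095 = float(np.mean([mean_ap({c: d[t] for c, d in per_class.items()})
                           for t in MAP5095_THRESHOLDS]))
    if conf_thresholds is None:
        conf_thresholds = np.round(np.arange(0.05, 1.0, 0.05), 2)
    curves, best = confidence_sweep(preds, gts, list(conf_thresholds))
    return EvalReport(
        per_class_ap50=ap50,
        per_class_ap=per_class,
        map50=m50,
        map50_95=m5095,
        precision=best["precision"] if best else 0.0,
        recall=best["recall"] if best else 0.0,
        f1=best["f1"] if best else 0.0,
        best_operating_point=best,
    )
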