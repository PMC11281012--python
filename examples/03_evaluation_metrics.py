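"""Score a toy set of detections: P/R, AP, mAP50, mAP50:95.

Predictions are greedily matched to same-class ground truths at an IoU
threshold; AP integrates the all-point-interpolated precision-recall
curve, and mAP50:95 averages mAP over IoU 0.50 ... 0.95 in steps of 0.05.
"""

from rgbdet.metrics import Box, evaluate

gts = {
    "img0": [Box(10, 10, 50, 50, class_id=0), Box(70, 20, 100, 60, class_id=1)],
    "img1": [Box(30, 30, 80, 80, class_id=0)],
}
preds = {
    "img0": [Box(12, 11, 51, 52, class_id=0, confidence=0.92),   # good hit
             Box(72, 22, 98, 58, class_id=1, confidence=0.85)],  # good hit
    "img1": [Box(33, 28, 77, 82, class_id=0, confidence=0.80),   # good hit
             Box(5, 5, 20, 20, class_id=0, confidence=0.40)],    # false alarm
}

report = evaluate(preds, gts)
print(f"mAP50      = {report.map50:.3f}")      # every fruit found at IoU 0.5
print(f"mAP50:95   = {report.map50_95:.3f}")   # drops as the IoU bar rises
print(f"best F1 operating point: conf >= {report.best_operating_point['threshold']:.2f} "
      f"-> P={report.precision:.2f}, R={report.recall:.2f}, F1={report.f1:.2f}")
for cid, ap in report.per_class_ap50.items():
    print(f"  class {cid}: AP50 = {ap:.3f}")
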