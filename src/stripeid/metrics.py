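"""Recognition metrics: Top-1 accuracy, order statistics of a training
run, per-part reporting, and the multi-part fusion rule.

A training run records one test Top-1 value per epoch; besides the
maximum, the fifth-highest value of the series is used as a stabler
summary when maxima nearly tie.  When one image shows several body parts,
the part whose recognizer is empirically most accurate decides:
left flank > right flank > face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import Prediction

__all__ = ["PartPrediction", "top1_accuracy", "kth_best_top1", "max_top1",
           "fifth_top1", "fuse_parts", "per_part_report", "PART_PRIORITY",
           "PART_COLUMN_NAMES"]

#: fixed fusion priority, most reliable part first
PART_PRIORITY = ("left", "right", "face")

#: report column headers per part key
PART_COLUMN_NAMES = {"face": "Head", "left": "Left Body", "right": "Right Body"}


@dataclass
class PartPrediction:
    part: str
    prediction: Prediction

    def __post_init__(self):
        if self.part not in PART_PRIORITY:
            raise ValueError(f"unknown part {self.part!r}")


def top1_accuracy(predictions, labels) -> float:
    """Fraction of predictions whose class equals the label."""
    predictions, labels = list(predictions), list(labels)
    if not predictions:
        raise ValueError("top1_accuracy needs at least one prediction")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    classes = [p.class_index if isinstance(p, Prediction) else int(p)
               for p in predictions]
    correct = sum(c == int(t) for c, t in zip(classes, labels))
    return correct / len(labels)


def kth_best_top1(series, k: int) -> float:
    """k-th largest element of a per-epoch Top-1 series (k=1 is the max)."""
    series = list(series)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > len(series):
        raise ValueError(f"k={k} exceeds series length {len(series)}")
    return float(np.partition(np.asarray(series, dtype=float), -k)[-k])


def max_top1(series) -> float:
    return kth_best_top1(series, 1)


def fifth_top1(series) -> float:
    """Fifth-highest per-epoch Top-1 over a training run."""
    return kth_best_top1(series, 5)


def fuse_parts(parts, by_confidence: bool = False) -> Prediction:
    """Final identification from per-part predictions.

    Default rule: the highest-priority part present wins (left > right >
    face).  ``by_confidence=True`` switches to the alternative rule of
    picking the part with the highest predicted probability.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("fuse_parts needs at least one part prediction")
    seen = [p.part for p in parts]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate part predictions: {sorted(seen)}")
    if by_confidence:
        best = max(parts, key=lambda p: float(np.max(p.prediction.probabilities)))
        return best.prediction
    by_part = {p.part: p.prediction for p in parts}
    for part in PART_PRIORITY:
        if part in by_part:
            return by_part[part]
    raise AssertionError("unreachable: parts validated against PART_PRIORITY")


def per_part_report(eval_results):
    """Accuracy per part per model variant as a DataFrame.

    ``eval_results``: {model name: {part: (predictions, labels)}}; columns
    follow the Head / Left Body / Right Body order for the parts present.
    """
    import pandas as pd

    parts_present = []
    for per_part in eval_results.values():
        for part in per_part:
            if part not in parts_present:
                parts_present.append(part)
    ordered = [p for p in ("face", "left", "right") if p in parts_present]
    rows = {}
    for model_name, per_part in eval_results.items():
        rows[model_name] = {
            PART_COLUMN_NAMES[part]: top1_accuracy(*per_part[part])
            for part in ordered if part in per_part}
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[PART_COLUMN_NAMES[p] for p in ordered])
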