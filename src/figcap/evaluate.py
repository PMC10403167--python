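"""Precision / recall / F-score evaluation against ground truth.

Predictions and truths are matched greedily one-to-one by descending
intersection-over-union; a match with IoU at or above the threshold
(default 0.5) is a true positive, leftover predictions are false positives
and leftover truths false negatives.  Percentages follow

    P = 100·TP/(TP+FP),  R = 100·TP/(TP+FN),  F = 2PR/(P+R),

with zero denominators reported as an explicit ``None`` sentinel rather
than a silent zero.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

from .image import InvalidInputError, InvalidParameterError
from .regions import BBox

TASKS = ("figure", "caption", "pair")


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    task: str = "pair"

    @property
    def precision(self) -> float | None:
        if self.tp + self.fp == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float | None:
        if self.tp + self.fn == 0:
            return None
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def f_score(self) -> float | None:
        return f_score(self.precision, self.recall)

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp, fn=self.fn + other.fn, task=self.task
        )


def f_score(p: float | None, r: float | None) -> float | None:
    """Harmonic mean of precision and recall (percent); None if undefined."""
    if p is None or r is None or p + r == 0:
        return None
    return 2.0 * p * r / (p + r)


def match_boxes(predicted: list[BBox], truth: list[BBox], iou_min: float = 0.5) -> EvalCounts:
    """Greedy one-to-one IoU matching of predicted boxes against truth."""
    if not (0.0 < iou_min <= 1.0):
        raise InvalidParameterError("iou_min must be in (0, 1]")
    scored = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth):
            iou = p.iou(t)
            if iou >= iou_min:
                scored.append((-iou, pi, ti))
    scored.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, pi, ti in scored:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        tp += 1
    return EvalCounts(tp=tp, fp=len(predicted) - tp, fn=len(truth) - tp)


def evaluate_pages(
    predictions: dict[str, dict[str, list[BBox]]],
    truths: dict[str, dict[str, list[BBox]]],
    iou_min: float = 0.5,
) -> dict[str, EvalCounts]:
    """Aggregate per-task counts over pages keyed by page id."""
    missing = sorted(set(truths) ^ set(predictions))
    if missing:
        raise InvalidInputError(f"page id mismatch between runs: {missing}")
    totals = {task: EvalCounts(task=task) for task in TASKS}
    for page in sorted(truths):
        for task in TASKS:
            counts = match_boxes(
                predictions[page].get(task, []), truths[page].get(task, []), iou_min
            )
            totals[task] = totals[task] + counts
    return totals


def _boxes_from_truth(d: dict) -> dict[str, list[BBox]]:
    return {
        "figure": [BBox.from_dict(b) for b in d.get("figures", [])],
        "caption": [BBox.from_dict(b) for b in d.get("captions", [])],
        "pair": [BBox.from_dict(p["merged_bbox"]) for p in d.get("pairs", [])],
    }


def _boxes_from_prediction(d: dict) -> dict[str, list[BBox]]:
    return {
        "figure": [BBox.from_dict(b) for b in d.get("figures", [])],
        "caption": [BBox.from_dict(b) for b in d.get("captions", [])],
        "pair": [BBox.from_dict(p["merged_bbox"]) for p in d.get("pairs", [])],
    }


def evaluate_corpus(
    pred_dir: str | Path, truth_dir: str | Path, iou_min: float = 0.5
) -> dict[str, EvalCounts]:
    """Score a directory of ``*_pairs.json`` runs against ``*_truth.json``."""
    preds: dict[str, dict[str, list[BBox]]] = {}
    truths: dict[str, dict[str, list[BBox]]] = {}
    for path in sorted(Path(truth_dir).glob("*_truth.json")):
        d = json.loads(path.read_text())
        truths[d["page"]] = _boxes_from_truth(d)
    for path in sorted(Path(pred_dir).glob("*_pairs.json")):
        d = json.loads(path.read_text())
        preds[d["page"]] = _boxes_from_prediction(d)
    return evaluate_pages(preds, truths, iou_min)


def write_table(results: dict[str, EvalCounts], path: str | Path) -> None:
    """CSV with one row per task: counts and the three percentages."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["task", "tp", "fp", "fn", "precision", "recall", "f_score"])
        for task in TASKS:
            c = results[task]
            fmt = lambda v: "" if v is None else f"{v:.2f}"
            writer.writerow([task, c.tp, c.fp, c.fn, fmt(c.precision), fmt(c.recall), fmt(c.f_score)])
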