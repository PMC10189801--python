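"""Classification metrics and the cross-condition / sweep experiment grids."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models
from .datasets import DatasetSplit


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)

    def as_dict(self) -> Dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}


def compute_metrics(labels: Sequence[int], calls: Sequence[int]) -> Metrics:
    labels = np.asarray(labels)
    calls = np.asarray(calls)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    if not (np.isin(labels, (0, 1)).all() and np.isin(calls, (0, 1)).all()):
        raise ValueError("labels and calls must be binary")
    tp = int(np.sum((labels == 1) & (calls == 1)))
    fp = int(np.sum((labels == 0) & (calls == 1)))
    fn = int(np.sum((labels == 1) & (calls == 0)))
    tn = int(np.sum((labels == 0) & (calls == 0)))
    return Metrics(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate(trained, dataset) -> Metrics:
    _, calls = models.predict(trained, dataset)
    return compute_metrics(dataset.y, calls)


@dataclass
class CrossMatrix:
    """Accuracy grid: rows = training condition, columns = test condition."""

    row_labels: List[str]
    col_labels: List[str]
    values: np.ndarray  # (rows, cols) accuracies

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)

    def cell(self, row: str, col: str) -> float:
        return float(self.values[self.row_labels.index(row),
                                 self.col_labels.index(col)])


def run_cross_grid(conditions: Dict[str, DatasetSplit],
                   build_model: Callable[[str], models.Model],
                   config: Optional[models.TrainConfig] = None) -> CrossMatrix:
    """Train one model per condition; evaluate each on every condition's test
    set.  ``conditions`` maps a label (context or species name) to its own
    split; all splits must share input shapes (use the shared annotation
    subset when conditions differ in available tracks)."""
    config = config or models.TrainConfig()
    names = list(conditions)
    shapes = set()
    for split in conditions.values():
        if split.train.X is not None:
            shapes.add(split.train.X.shape[1:])
    if len(shapes) > 1:
        raise ValueError(f"incompatible window shapes across conditions: "
                         f"{sorted(shapes)}")
    values = np.zeros((len(names), len(names)))
    for i, row in enumerate(names):
        trained = models.train(build_model(row), conditions[row], config)
        for j, col in enumerate(names):
            values[i, j] = evaluate(trained, conditions[col].test).accuracy
    return CrossMatrix(row_labels=names, col_labels=names, values=values)


def run_sweep(axis: str,
              values: Sequence[int],
              make_split: Callable[[int, str], DatasetSplit],
              build_model: Callable[[int], models.Model],
              contexts: Sequence[str] = ("CG", "CHG", "CHH"),
              config: Optional[models.TrainConfig] = None) -> pd.DataFrame:
    """One trained model per (value, context), all else fixed.

    ``axis`` is ``"window_size"`` or ``"dataset_size"``; ``make_split(value,
    context)`` must build the corresponding split and ``build_model(value)``
    the matching classifier.  Returns a long-format table (value, context,
    accuracy)."""
    if axis not in ("window_size", "dataset_size"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    config = config or models.TrainConfig()
    rows = []
    for value in values:
        if value <= 0 or (axis == "window_size" and value % 2):
            raise ValueError(f"invalid {axis} value {value}")
        for context in contexts:
            split = make_split(value, context)
            trained = models.train(build_model(value), split, config)
            rows.append({axis: value, "context": context,
                         "accuracy": evaluate(trained, split.test).accuracy})
    return pd.DataFrame(rows)
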