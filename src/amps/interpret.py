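"""Grad-CAM importance scoring and motif-candidate extraction.

For the sequence CNN the target layer is its (only) conv layer: channel
weights are the position-averaged gradients of the class score (the
pre-sigmoid logit for the predicted class, negated for the unmethylated
class) with respect to the post-ReLU conv activations; the weighted channel
sum is ReLU-rectified and upsampled to input length by nearest-neighbor
repetition.  Candidate motif subsequences are the length-50 windows with the
highest mean importance (stride 1, leftmost tie-break), exported as FASTA
for downstream motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .datasets import Dataset
from .models import Model, TrainedModel

logger = logging.getLogger(__name__)

CANDIDATE_WINDOW = 50
DEFAULT_N_PER_CLASS = 10_000


@dataclass
class ImportanceProfile:
    scores: np.ndarray  # (W_s,) nonnegative
    example_index: int
    predicted_class: int


@dataclass
class MotifCandidate:
    sequence: str
    window_start: int
    mean_score: float
    example_index: int
    label: int

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.sequence.strip()):
            raise ValueError("candidate sequence has surrounding whitespace")


def _unwrap(trained_or_model) -> Model:
    model = trained_or_model.model if isinstance(trained_or_model, TrainedModel) \
        else trained_or_model
    if model.kind != "amps_cnn":
        raise TypeError(
            f"Grad-CAM requires the convolutional sequence model, got "
            f"{model.kind!r}")
    return model


def gradcam_batch(trained_or_model, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Importance maps for a batch of encoded windows.

    Returns ``(scores, predicted)`` where ``scores`` is (n, W_s) and
    ``predicted`` the model's binary calls.
    """
    model = _unwrap(trained_or_model)
    net: nn.Sequential = model.net
    X = X.astype(np.float32)
    n, W_s, _ = X.shape
    logits = net.forward(X, train=False)[:, 0]
    predicted = (logits >= 0).astype(np.uint8)
    # activations of the ReLU after the conv layer
    activations = net.layers[1].output  # (n, L', C)
    sign = np.where(predicted == 1, 1.0, -1.0)
    dlogits = sign[:, None].astype(np.float32)
    grads = net.backward(dlogits, stop_at=2)  # d score / d activations
    weights = grads.mean(axis=1)  # (n, C) global-average-pooled
    cam = np.einsum("nlc,nc->nl", activations, weights)
    cam = np.maximum(cam, 0.0)
    # nearest-neighbor upsample L' -> W_s
    Lp = cam.shape[1]
    idx = np.minimum((np.arange(W_s) * Lp // W_s), Lp - 1)
    return cam[:, idx], predicted


def gradcam(trained_or_model, example, example_index: int = 0
            ) -> ImportanceProfile:
    """Importance profile of a single encoded window."""
    matrix = example.matrix if hasattr(example, "matrix") else np.asarray(example)
    scores, predicted = gradcam_batch(trained_or_model, matrix[None])
    return ImportanceProfile(scores=scores[0], example_index=example_index,
                             predicted_class=int(predicted[0]))


def best_window(scores: np.ndarray, window: int = CANDIDATE_WINDOW
                ) -> Tuple[int, float]:
    """Leftmost length-``window`` slice with the highest mean importance."""
    W_s = len(scores)
    if window > W_s:
        raise ValueError(f"window {window} longer than profile {W_s}")
    csum = np.concatenate([[0.0], np.cumsum(scores, dtype=np.float64)])
    means = (csum[window:] - csum[:-window]) / window
    start = int(np.argmax(means))  # argmax returns the first maximum
    return start, float(means[start])


def select_candidates(trained_or_model,
                      dataset: Dataset,
                      n_per_class: int = DEFAULT_N_PER_CLASS,
                      window: int = CANDIDATE_WINDOW,
                      batch_size: int = 256) -> Dict[int, List[MotifCandidate]]:
    """Top-importance windows from correctly classified examples.

    Up to ``n_per_class`` correctly classified examples per true class are
    scored; when fewer are available all of them are used (logged).
    Returns ``{1: methylated-class candidates, 0: unmethylated-class}``.
    """
    model = _unwrap(trained_or_model)
    from .models import predict  # local import to avoid cycle at module load
    _, calls = predict(model, dataset)
    correct = calls == dataset.y
    picks: Dict[int, np.ndarray] = {}
    for label in (1, 0):
        idx = np.flatnonzero(correct & (dataset.y == label))
        if len(idx) < n_per_class:
            logger.info("only %d correctly classified examples of class %d "
                        "(requested %d)", len(idx), label, n_per_class)
        picks[label] = idx[:n_per_class]

    out: Dict[int, List[MotifCandidate]] = {1: [], 0: []}
    for label, idx in picks.items():
        for start in range(0, len(idx), batch_size):
            batch = idx[start:start + batch_size]
            scores, _ = gradcam_batch(model, dataset.X[batch])
            for row, i in zip(scores, batch):
                ws, mean_score = best_window(row, window)
                out[label].append(MotifCandidate(
                    sequence=decode_sequence(dataset.X[i, ws:ws + window, :4]),
                    window_start=ws, mean_score=mean_score,
                    example_index=int(i), label=label))
    return out


def decode_sequence(onehot: np.ndarray) -> str:
    """One-hot rows (ACGT columns) back to a string; all-zero rows are N."""
    bases = np.array(list("ACGTN"))
    idx = np.where(onehot.sum(axis=1) == 0, 4, onehot.argmax(axis=1))
    return "".join(bases[idx])


def export_fasta(candidates, path: str | Path) -> None:
    """Write candidates as FASTA; headers carry example id, class,
    window_start and mean_score as ``key=value`` pairs."""
    flat: List[MotifCandidate] = []
    if isinstance(candidates, dict):
        for label in sorted(candidates, reverse=True):
            flat.extend(candidates[label])
    else:
        flat = list(candidates)
    if not flat:
        raise ValueError("no candidates to export")
    with open(path, "w") as handle:
        for k, cand in enumerate(flat):
            handle.write(
                f">candidate_{k} example={cand.example_index} "
                f"class={cand.label} window_start={cand.window_start} "
                f"mean_score={cand.mean_score:.6g}\n{cand.sequence}\n")


def parse_candidate_header(header: str) -> Dict[str, object]:
    """Recover the key=value fields from an exported FASTA header line."""
    fields: Dict[str, object] = {}
    for token in header.lstrip(">").split()[1:]:
        key, value = token.split("=")
        fields[key] = float(value) if key == "mean_score" else int(value)
    return fields
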