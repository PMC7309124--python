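"""Classifier evaluation: confusion-matrix metrics, ROC/AUC, confidence maps.

HCC is the positive class throughout: sensitivity is the true-positive
rate on tumor patches, specificity the true-negative rate on parenchyma.
Confidence maps score a sliding 56x56 window over a full frame and render
the per-pixel mean HCC probability as a red (HCC) to green (PAR) overlay,
the visualization a reading physician would see.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .io_via import HCC, AnnotatedImage

__all__ = ["EvalReport", "ConfidenceMap", "confusion_metrics", "roc_auc", "confidence_map", "render_overlay"]


@dataclass
class EvalReport:
    """Binary-classification report with HCC as the positive class.

    Metrics whose denominator is empty are NaN and listed in ``undefined``.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    undefined: list[str] = field(default_factory=list)
    method: str = ""


def _to_binary(values: Sequence, positive=HCC) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "USO":
        return (arr == positive).astype(int)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError("labels must be binary (0/1 or HCC/PAR)")
    return arr.astype(int)


def confusion_metrics(labels: Sequence, predictions: Sequence, positive=HCC) -> EvalReport:
    """Counts and accuracy/sensitivity/specificity from hard predictions."""
    y = _to_binary(labels, positive)
    p = _to_binary(predictions, positive)
    if len(y) == 0 or len(y) != len(p):
        raise ValueError("labels and predictions must be equal-length and non-empty")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fn = int(np.sum((y == 1) & (p == 0)))
    report = EvalReport(tp=tp, fp=fp, tn=tn, fn=fn)
    report.accuracy = (tp + tn) / len(y)
    if tp + fn > 0:
        report.sensitivity = tp / (tp + fn)
    else:
        report.undefined.append("sensitivity")
    if tn + fp > 0:
        report.specificity = tn / (tn + fp)
    else:
        report.undefined.append("specificity")
    return report


def roc_auc(labels: Sequence, scores: Sequence, positive=HCC) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUC from continuous HCC scores.

    AUC is the probability that a random positive outranks a random
    negative, with ties counted one half -- computed exactly via midranks
    (equivalent to trapezoidal integration of the ROC curve).
    """
    y = _to_binary(labels, positive)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    ranks = rankdata(s)  # midranks handle ties exactly
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # ROC points swept over thresholds, from strictest to laxest
    order = np.argsort(-s, kind="stable")
    sorted_y = y[order]
    sorted_s = s[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(1 - sorted_y)
    # keep the last point of each tied-score run
    keep = np.r_[sorted_s[1:] != sorted_s[:-1], True]
    points = [(0.0, 0.0)] + [
        (fps[i] / n_neg, tps[i] / n_pos) for i in np.nonzero(keep)[0]
    ]
    return points, float(auc)


@dataclass
class ConfidenceMap:
    """Per-pixel HCC probability over a frame, with coverage bookkeeping."""

    probabilities: np.ndarray
    coverage: np.ndarray  # bool: pixels covered by at least one window
    stride: int


def confidence_map(
    scorer: Callable[[np.ndarray], float | np.ndarray],
    image: AnnotatedImage | np.ndarray,
    stride: int = 14,
    window: int = 56,
) -> ConfidenceMap:
    """Slide a window over the frame and average HCC scores per pixel.

    ``scorer`` maps one ``window x window`` patch to an HCC probability (it
    may also accept a stacked ``(n, window, window)`` batch and return n
    probabilities, which is used when available). Overlapping windows are
    aggregated by their mean; pixels no window covers are flagged in the
    coverage mask. The scan includes the last fitting row/column so the
    frame borders are covered.
    """
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    h, w = pixels.shape
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if h < window or w < window:
        raise ValueError("image smaller than the scoring window")

    ys = sorted(set(list(range(0, h - window + 1, stride)) + [h - window]))
    xs = sorted(set(list(range(0, w - window + 1, stride)) + [w - window]))
    origins = [(y, x) for y in ys for x in xs]
    batch = np.stack([pixels[y : y + window, x : x + window] for y, x in origins])
    try:
        probs = np.asarray(scorer(batch), dtype=float).reshape(-1)
        if probs.shape[0] != len(origins):
            raise ValueError
    except Exception:
        probs = np.array([float(scorer(pixels[y : y + window, x : x + window])) for y, x in origins])

    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=np.int64)
    for (y, x), p in zip(origins, probs):
        acc[y : y + window, x : x + window] += p
        cnt[y : y + window, x : x + window] += 1
    covered = cnt > 0
    out = np.zeros((h, w), dtype=float)
    out[covered] = acc[covered] / cnt[covered]
    return ConfidenceMap(probabilities=out, coverage=covered, stride=stride)


def render_overlay(
    cmap: ConfidenceMap, image: AnnotatedImage | np.ndarray, alpha: float = 0.5
) -> np.ndarray:
    """Blend the confidence map onto the frame as an RGB image.

    High HCC probability renders red, high PAR probability green; uncovered
    pixels keep the plain grayscale frame.
    """
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
    gray = pixels.astype(float)
    rgb = np.stack([gray, gray, gray], axis=-1)
    p = cmap.probabilities
    tint = np.zeros_like(rgb)
    tint[..., 0] = 255.0 * p  # red: HCC
    tint[..., 1] = 255.0 * (1.0 - p)  # green: PAR
    mask = cmap.coverage[..., None]
    blended = np.where(mask, (1 - alpha) * rgb + alpha * tint, rgb)
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
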