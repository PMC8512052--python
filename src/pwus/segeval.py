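"""Segmentation-accuracy analysis by pixel counting.

Quantifies, per image, the fraction of the ground-truth bladder surface
the segmenter missed and the fraction it falsely added, both expressed
relative to the ground-truth bladder area, plus the intersection over
union. Cohort results are summarized as medians and histograms.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import skimage.draw

__all__ = ["SegEvalResult", "binarize_gt", "seg_fractions", "summarize"]


@dataclasses.dataclass(frozen=True)
class SegEvalResult:
    """Pixel-counting comparison of predicted and ground-truth masks.

    ``missing_fraction = |GT & ~Pred| / |GT|`` (in [0, 1]),
    ``false_fraction = |Pred & ~GT| / |GT|`` (may exceed 1 when the
    prediction is larger than the ground truth),
    ``iou = |Pred & GT| / |Pred | GT|``.
    """

    missing_fraction: float
    false_fraction: float
    iou: float
    n_gt: int
    n_pred: int
    n_intersection: int
    n_union: int


def binarize_gt(annotation, shape: tuple | None = None) -> np.ndarray:
    """Binarize a ground-truth annotation.

    Accepts either a raster (thresholded at mid-range, already-binary
    rasters unchanged) or a polygon as a point list ``[(x, y), ...]`` /
    ``{"points": [...]}`` (the generic point-list dialect of common
    annotation-tool exports), whose interior is filled. ``shape`` is
    required for -- and identifies -- polygon input.
    """
    if isinstance(annotation, dict):
        annotation = annotation["points"]
    arr = np.asarray(annotation)
    if shape is not None:
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("polygon annotation must be an (N, 2) point list")
        if arr.shape[0] < 3:
            raise ValueError("polygon needs at least 3 points")
        mask = np.zeros(shape, dtype=bool)
        rr, cc = skimage.draw.polygon(arr[:, 1], arr[:, 0], shape=shape)
        mask[rr, cc] = True
        return mask
    if arr.ndim != 2:
        raise ValueError("raster annotation must be 2-D")
    if arr.size == 0:
        raise ValueError("empty annotation")
    lo, hi = float(arr.min()), float(arr.max())
    if lo == hi:
        raise ValueError("annotation carries no foreground/background contrast")
    return arr > (lo + hi) / 2.0


def seg_fractions(pred: np.ndarray, gt: np.ndarray, fan: np.ndarray | None = None) -> SegEvalResult:
    """Missing/false bladder fractions and IoU by exact pixel counting.

    When a fan mask is supplied, evaluation is restricted to the
    fan-valid region. Raises ``ValueError`` when the ground truth is
    empty (the fractions are undefined).
    """
    p = np.asarray(pred).astype(bool)
    g = np.asarray(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError("prediction and ground-truth shapes must match")
    if fan is not None:
        f = np.asarray(fan).astype(bool)
        p, g = p & f, g & f
    n_gt = int(g.sum())
    if n_gt == 0:
        raise ValueError("ground truth is empty; fractions undefined")
    n_pred = int(p.sum())
    inter = int((p & g).sum())
    union = int((p | g).sum())
    return SegEvalResult(
        missing_fraction=(n_gt - inter) / n_gt,
        false_fraction=(n_pred - inter) / n_gt,
        iou=inter / union,
        n_gt=n_gt,
        n_pred=n_pred,
        n_intersection=inter,
        n_union=union,
    )


def summarize(results, n_bins: int = 10) -> dict:
    """Cohort summary: median fractions and fixed-width histograms.

    Histograms span [0, max] of each fraction; the median of an even
    count is the mean of the two central values. Deterministic.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one result")
    missing = np.array([r.missing_fraction for r in results])
    false = np.array([r.false_fraction for r in results])
    iou = np.array([r.iou for r in results])

    def _hist(v):
        top = float(v.max()) if v.max() > 0 else 1.0
        counts, edges = np.histogram(v, bins=n_bins, range=(0.0, top))
        return {"counts": counts.tolist(), "edges": edges.tolist()}

    return {
        "n": len(results),
        "median_missing_fraction": float(np.median(missing)),
        "median_false_fraction": float(np.median(false)),
        "median_iou": float(np.median(iou)),
        "missing_histogram": _hist(missing),
        "false_histogram": _hist(false),
    }
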