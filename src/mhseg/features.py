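"""Hole shape features and pixel-wise evaluation metrics.

Shape features follow the clinical size measures for macular holes:
*base width* (widest per-row extent) and *minimum diameter* (narrowest
per-row extent across the hole interior), plus area, height, aspect
ratio and circularity. Evaluation uses the standard pixel-wise
confusion counts and the derived accuracy, sensitivity, Jaccard index
and Dice similarity coefficient (DSC = 2J/(1+J)).

Sensitivity of an image whose truth mask is empty is undefined
(tp + fn = 0) and is reported as missing rather than 0, so that mean
rows over mixed hole/no-hole sets are not dragged down artificially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import perimeter as skimage_perimeter

from ._validate import as_binary_mask, check_same_shape
from .errors import NoInformativeFeaturesError, ValidationError

_EIGHT = ndimage.generate_binary_structure(2, 2)

FEATURE_NAMES = (
    "area",
    "base_width",
    "min_diameter",
    "height",
    "aspect",
    "circularity",
    "centroid_row",
    "centroid_col",
)


@dataclass(frozen=True)
class HoleFeatures:
    area: int
    base_width: int
    min_diameter: int
    height: int
    aspect: float
    circularity: float
    centroid: tuple[float, float]

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area,
            "base_width": self.base_width,
            "min_diameter": self.min_diameter,
            "height": self.height,
            "aspect": self.aspect,
            "circularity": self.circularity,
            "centroid_row": self.centroid[0],
            "centroid_col": self.centroid[1],
        }


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None = None
    sensitivity: float | None = None
    jaccard: float | None = None
    dsc: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict[str, float | None]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "jaccard": self.jaccard,
            "dsc": self.dsc,
        }


def compute_hole_features(mask: np.ndarray) -> HoleFeatures:
    """Shape features of a single-component hole mask.

    ``base_width`` is the maximum per-row extent (rightmost − leftmost
    + 1); ``min_diameter`` the minimum of that quantity over rows
    strictly between the mask's top and bottom rows (over all rows
    when the mask is fewer than three rows tall). Circularity uses the
    weighted contour-length perimeter estimator (a raw boundary-pixel
    count overestimates curved contours and drags a disk's circularity
    far below 1).
    """
    m = as_binary_mask(mask)
    if not m.any():
        raise ValidationError("empty mask has no features")
    _, n_comp = ndimage.label(m, structure=_EIGHT)
    if n_comp != 1:
        raise ValidationError(f"mask must be a single component, found {n_comp}")
    rows = np.flatnonzero(m.any(axis=1))
    top, bottom = int(rows[0]), int(rows[-1])
    extents = {}
    for r in rows:
        cc = np.flatnonzero(m[r])
        extents[r] = int(cc[-1] - cc[0] + 1)
    base_width = max(extents.values())
    interior_rows = [r for r in rows if top < r < bottom]
    min_diameter = min(
        (extents[r] for r in interior_rows), default=base_width
    )
    height = bottom - top + 1
    area = int(m.sum())
    perim = float(skimage_perimeter(m.astype(bool), neighborhood=4))
    circularity = float(4.0 * np.pi * area / perim**2) if perim > 0 else 1.0
    rr, cc = np.nonzero(m)
    return HoleFeatures(
        area=area,
        base_width=base_width,
        min_diameter=min_diameter,
        height=height,
        aspect=base_width / height,
        circularity=circularity,
        centroid=(float(rr.mean()), float(cc.mean())),
    )


def select_features(
    table: Sequence[Mapping[str, float]] | pd.DataFrame, k: int = 4
) -> list[str]:
    """Unsupervised variance/redundancy feature selection.

    Zero-variance features are dropped; survivors are ranked by the
    variance of their min-max-scaled values (a scale-free spread
    ranking) and greedily kept while their absolute Pearson
    correlation with every feature already kept is ≤ 0.95. The first
    ``k`` survivors are returned (all survivors if fewer).
    """
    df = pd.DataFrame(table) if not isinstance(table, pd.DataFrame) else table.copy()
    df = df.select_dtypes(include=[np.number])
    if len(df) < 2:
        raise ValidationError("need at least two records to rank features")
    if k < 1:
        raise ValidationError("k must be >= 1")
    span = df.max() - df.min()
    informative = span[span > 0].index.tolist()
    if not informative:
        raise NoInformativeFeaturesError("all feature columns are constant")
    scaled = (df[informative] - df[informative].min()) / span[informative]
    ranked = scaled.var().sort_values(ascending=False, kind="stable").index.tolist()
    corr = df[informative].corr().abs()
    kept: list[str] = []
    for name in ranked:
        if all(corr.loc[name, prev] <= 0.95 for prev in kept):
            kept.append(name)
    return kept[:k]


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Pixel-wise confusion counts of a predicted vs. truth mask."""
    p = as_binary_mask(pred, "pred").astype(bool)
    t = as_binary_mask(truth, "truth").astype(bool)
    check_same_shape(p, t, "pred and truth")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = p.size - tp - fp - fn
    return EvalResult(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics_from_counts(counts: EvalResult) -> EvalResult:
    """Accuracy, sensitivity, Jaccard and DSC from confusion counts.

    Sensitivity is None (missing) when the truth has no positive
    pixels; Jaccard/DSC are 1.0 when both masks are empty (perfect
    agreement on the absence of a hole).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = tp + fp + tn + fn
    if n == 0:
        raise ValidationError("empty masks: no pixels to evaluate")
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    denom = tp + fp + fn
    jaccard = tp / denom if denom > 0 else 1.0
    dsc = 2 * tp / (2 * tp + fp + fn) if denom > 0 else 1.0
    return EvalResult(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        jaccard=jaccard,
        dsc=dsc,
    )


def evaluate_masks(pred: np.ndarray, truth: np.ndarray) -> EvalResult:
    """Convenience: confusion counts + metrics in one call."""
    return metrics_from_counts(confusion_counts(pred, truth))
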