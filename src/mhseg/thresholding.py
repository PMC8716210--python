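"""Multilevel gray-level thresholding.

Two criteria are provided for placing K cut points on the intensity
axis of a B-scan:

* ``otsu_multilevel`` — exhaustive maximization of the between-class
  variance over all increasing K-tuples of histogram bin boundaries
  (the canonical multilevel Otsu criterion; deterministic, with ties
  broken by the lexicographically smallest tuple).
* ``valley_thresholds`` — the classical valley rule: smooth the
  histogram, find the K+1 most prominent peaks, and place each
  threshold at the minimum-count bin strictly between consecutive
  peaks. Valley selection is brittle on speckled histograms, so Otsu
  is the pipeline default and the valley mode falls back to it when
  too few modes survive smoothing.

Otsu thresholds are reported as bin-*edge* positions so that applying
them is exact on quantized data; valley thresholds are bin centres
(the valley is a bin, not a boundary). The default K = 3 yields four
classes: vitreous/background, inner retina, outer retina and the
hyper-reflective RPE band — the minimum that isolates a
hypo-reflective hole inside a bright band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from ._validate import as_gray_image
from .errors import DegenerateHistogramError, InsufficientModesError, ValidationError


@dataclass(frozen=True)
class IntensityHistogram:
    """Uniform-bin intensity histogram on [0, 1].

    Bins are right-open except the last (closed at 1); ``counts`` sums
    to the pixel count.
    """

    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered gray-level cut points in (0, 1)."""

    levels: tuple[float, ...]
    method: Literal["valley", "otsu"] = "otsu"

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise ValidationError("at least one threshold level is required")
        lv = np.asarray(self.levels, dtype=np.float64)
        if np.any(np.diff(lv) <= 0):
            raise ValidationError("levels must be strictly increasing")
        if lv[0] <= 0.0 or lv[-1] >= 1.0:
            raise ValidationError("levels must lie in the open interval (0, 1)")

    @property
    def k(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class ClassMap:
    """Per-pixel class labels in {0..k} induced by a ThresholdSet."""

    labels: np.ndarray
    k: int
    levels: tuple[float, ...] = field(default=())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def build_histogram(img: np.ndarray, bins: int = 256) -> IntensityHistogram:
    """Histogram a gray image into uniform bins on [0, 1]."""
    arr = as_gray_image(img)
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return IntensityHistogram(counts=counts.astype(np.int64), bin_edges=edges)


def valley_thresholds(
    hist: IntensityHistogram, k: int = 3, smooth_window: int = 5
) -> ThresholdSet:
    """Histogram-valley thresholds between the k+1 most prominent peaks.

    The counts are smoothed by a centred moving average, local maxima
    are ranked by prominence, and each threshold is the centre of the
    minimum-count bin strictly between consecutive peaks (ties broken
    leftmost).

    Raises
    ------
    InsufficientModesError
        Fewer than k+1 peaks survive smoothing; callers fall back to
        :func:`otsu_multilevel`.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    smoothed = ndimage.uniform_filter1d(
        hist.counts.astype(np.float64), size=smooth_window, mode="nearest"
    )
    peaks, props = find_peaks(smoothed, prominence=0.0)
    if peaks.size < k + 1:
        raise InsufficientModesError(
            f"need {k + 1} histogram modes, found {peaks.size}"
        )
    order = np.argsort(props["prominences"])[::-1]
    chosen = np.sort(peaks[order[: k + 1]])
    centers = hist.bin_centers
    levels = []
    for left, right in zip(chosen[:-1], chosen[1:]):
        if right - left < 2:
            raise InsufficientModesError(
                f"adjacent modes at bins {left} and {right} leave no valley"
            )
        between = smoothed[left + 1 : right]
        valley_bin = left + 1 + int(np.argmin(between))  # argmin -> leftmost tie
        levels.append(float(centers[valley_bin]))
    return ThresholdSet(levels=tuple(levels), method="valley")


def otsu_multilevel(hist: IntensityHistogram, k: int = 3) -> ThresholdSet:
    """Exhaustive multilevel Otsu thresholds of a histogram.

    Maximizes the between-class variance Σ w_c μ_c² (equivalently,
    minimizes within-class variance) over *all* increasing k-tuples of
    interior bin boundaries; ties are broken by the lexicographically
    smallest boundary tuple. Exhaustive search is vectorized for
    k ≤ 3 and falls back to explicit enumeration for larger k.

    Raises
    ------
    DegenerateHistogramError
        Fewer than k+1 occupied bins — no k-cut partition can separate
        anything.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    counts = hist.counts.astype(np.float64)
    if int(np.count_nonzero(counts)) < k + 1:
        raise DegenerateHistogramError(
            f"need at least {k + 1} occupied bins for k={k}, "
            f"got {int(np.count_nonzero(counts))}"
        )
    boundaries = _otsu_boundaries(counts, hist.bin_centers, k)
    levels = tuple(float(hist.bin_edges[b]) for b in boundaries)
    return ThresholdSet(levels=levels, method="otsu")


def _class_score_table(counts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """H[a, b] = (Σ weight·value over bins [a, b))² / Σ weight, or 0 if empty.

    Between-class variance of a partition is Σ H over its classes,
    up to the constant μ_T²·N shared by all partitions.
    """
    nbins = counts.size
    cw = np.concatenate(([0.0], np.cumsum(counts)))
    cm = np.concatenate(([0.0], np.cumsum(counts * centers)))
    w = cw[None, :] - cw[:, None]  # w[a, b] = weight of bins [a, b)
    s = cm[None, :] - cm[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
    return np.triu(h)[: nbins + 1, : nbins + 1]


def _otsu_boundaries(counts: np.ndarray, centers: np.ndarray, k: int) -> tuple[int, ...]:
    nbins = counts.size
    h = _class_score_table(counts, centers)
    cuts = np.arange(1, nbins)  # interior boundaries
    if k == 1:
        scores = h[0, cuts] + h[cuts, nbins]
        return (int(cuts[int(np.argmax(scores))]),)
    if k == 2:
        t1 = cuts[:, None]
        t2 = cuts[None, :]
        scores = np.where(
            t1 < t2, h[0, t1] + h[t1, t2] + h[t2, nbins], -np.inf
        )
        flat = int(np.argmax(scores))  # first occurrence = lexicographic min
        i, j = divmod(flat, cuts.size)
        return (int(cuts[i]), int(cuts[j]))
    if k == 3:
        best_score = -np.inf
        best: tuple[int, ...] = ()
        t2g = cuts[:, None]
        t3g = cuts[None, :]
        ok = (t2g < t3g).astype(np.float64)
        ok[ok == 0] = -np.inf
        ok[ok == 1] = 0.0
        for t1 in cuts:
            # left-to-right summation matches the enumeration oracle
            # bit-for-bit, so exact score ties break identically.
            total = h[0, t1] + h[t1, t2g] + h[t2g, t3g] + h[t3g, nbins] + ok
            total[t2g.ravel() <= t1, :] = -np.inf
            flat = int(np.argmax(total))
            score = float(total.flat[flat])
            if score > best_score:
                i, j = divmod(flat, cuts.size)
                best_score = score
                best = (int(t1), int(cuts[i]), int(cuts[j]))
        return best
    return _otsu_enumerate(h, nbins, k)


def _otsu_enumerate(h: np.ndarray, nbins: int, k: int) -> tuple[int, ...]:
    from itertools import combinations

    best_score = -np.inf
    best: tuple[int, ...] = ()
    for tup in combinations(range(1, nbins), k):
        bounds = (0,) + tup + (nbins,)
        score = sum(h[a, b] for a, b in zip(bounds[:-1], bounds[1:]))
        if score > best_score:  # first maximizer kept -> lexicographic min
            best_score = score
            best = tup
    return best


def apply_thresholds(img: np.ndarray, ts: ThresholdSet) -> ClassMap:
    """Label each pixel by the number of threshold levels ≤ its value.

    Monotone in intensity; a pixel exactly at a level belongs to the
    upper class. Idempotent under re-application of the same set.
    """
    arr = as_gray_image(img)
    levels = np.asarray(ts.levels, dtype=np.float64)
    labels = np.searchsorted(levels, arr, side="right").astype(np.int32)
    return ClassMap(labels=labels, k=ts.k, levels=ts.levels)
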