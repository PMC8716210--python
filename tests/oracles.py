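"""Independent brute-force oracles used to cross-check the library.

These deliberately avoid the library's code paths (and scipy's
convolution machinery): plain nested loops and explicit enumeration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def correlate2d_replicate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop 2-D correlation with replicate (clamp) padding."""
    h, w = img.shape
    kh, kw = kernel.shape
    oh, ow = kh // 2, kw // 2
    out = np.zeros((h, w), dtype=np.float64)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    rr = min(max(r + i - oh, 0), h - 1)
                    cc = min(max(c + j - ow, 0), w - 1)
                    acc += kernel[i, j] * img[rr, cc]
            out[r, c] = acc
    return out


def between_class_variance(
    counts: np.ndarray, centers: np.ndarray, bounds: tuple[int, ...]
) -> float:
    """Sum of (class weighted-sum)^2 / class weight over the partition."""
    score = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        wgt = float(counts[a:b].sum())
        if wgt > 0:
            score = score + float((counts[a:b] * centers[a:b]).sum()) ** 2 / wgt
    return score


def otsu_exhaustive(
    counts: np.ndarray, centers: np.ndarray, k: int
) -> tuple[int, ...]:
    """All increasing k-tuples of interior boundaries; first maximizer
    (lexicographically smallest) wins ties."""
    nbins = counts.size
    best_score = -np.inf
    best: tuple[int, ...] = ()
    for tup in combinations(range(1, nbins), k):
        score = between_class_variance(counts, centers, (0,) + tup + (nbins,))
        if score > best_score:
            best_score = score
            best = tup
    return best


def smoothed_valley_scan(
    counts: np.ndarray, peaks: tuple[int, int], window: int = 5
) -> int:
    """Leftmost minimum bin of the moving-average-smoothed counts
    strictly between two known peak bins."""
    padded = np.pad(counts.astype(np.float64), window, mode="edge")
    kernel = np.ones(window) / window
    sm = np.convolve(padded, kernel, mode="same")[window:-window]
    assert sm.size == counts.size
    left, right = peaks
    between = sm[left + 1 : right]
    return left + 1 + int(np.argmin(between))
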