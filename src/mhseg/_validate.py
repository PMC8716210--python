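"""Array validation helpers shared across modules.

A B-scan ("gray image") is a 2-D float array with finite values in
[0, 1] and at least 3 rows and 3 columns (minimum support of a 3x3
kernel). A binary mask is a 2-D array containing only {0, 1}.
Row 0 is the top of the scan (vitreous side); coordinates are 0-based
and ranges half-open.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

MIN_SIDE = 3


def as_gray_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate and return ``img`` as a float64 gray image in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ValidationError(
            f"{name} must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(
            f"{name} values must lie in [0, 1], got range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def as_binary_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate and return ``mask`` as a uint8 {0, 1} array."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(f"{name} must contain only 0 and 1")
    return arr.astype(np.uint8)


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "arrays") -> None:
    if a.shape != b.shape:
        raise ValidationError(f"{what} must share a shape: {a.shape} vs {b.shape}")
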