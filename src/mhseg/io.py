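"""Image, mask and report I/O.

Images are read from PNG/TIFF/JPEG containers into float arrays in
[0, 1]: 8-bit containers divide by 255, 16-bit by 65535, with no gamma
handling (OCT exports are linear). RGB inputs are collapsed by an
unweighted channel mean — OCT scans are gray and chroma is incidental.
Masks are written as 8-bit single-channel PNGs with values {0, 255};
a write/read round-trip is bit-exact.
"""

from __future__ import annotations

import csv
import json
import math
import os
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np

from ._validate import as_binary_mask, as_gray_image
from .errors import ValidationError

_SUPPORTED_EXT = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}

METRIC_FIELDS = ("accuracy", "sensitivity", "jaccard", "dsc")


def read_grayscale_image(path: str | os.PathLike) -> np.ndarray:
    """Read a single B-scan into a float64 array in [0, 1].

    Parameters
    ----------
    path
        A PNG, TIFF or JPEG file, 8- or 16-bit, single channel or RGB.

    Returns
    -------
    ndarray
        2-D float64 array; intensities linearly mapped from the
        container's integer range to [0, 1].
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise ValidationError(f"unsupported image format {ext!r} (PNG/TIFF/JPEG only)")
    arr = iio.imread(path)
    src_dtype = arr.dtype
    if arr.size == 0:
        raise ValidationError(f"zero-area image: {path}")
    if arr.ndim == 3:
        # RGB(A): unweighted mean of the colour channels, alpha dropped.
        arr = arr[..., :3].mean(axis=2)
    elif arr.ndim != 2:
        raise ValidationError(f"expected 2-D or colour image, got shape {arr.shape}")
    if src_dtype == np.uint8:
        scale = 255.0
    elif src_dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(src_dtype, np.integer):
        scale = 255.0 if arr.max(initial=0) <= 255 else 65535.0
    else:  # float container; assume already normalized unless out of range
        scale = 1.0 if arr.max(initial=0.0) <= 1.0 else 255.0
    img = np.asarray(arr, dtype=np.float64) / scale
    return as_gray_image(np.clip(img, 0.0, 1.0), name=path)


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}."""
    m = as_binary_mask(mask)
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    iio.imwrite(path, (m * 255).astype(np.uint8), extension=".png")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask PNG back to {0, 1} by thresholding at half range."""
    img = read_grayscale_image(path)
    return (img >= 0.5).astype(np.uint8)


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a gray image as an 8-bit PNG (quantized to 256 levels)."""
    arr = as_gray_image(img)
    iio.imwrite(
        os.fspath(path), np.round(arr * 255.0).astype(np.uint8), extension=".png"
    )


def _mean_row(records: Sequence[Mapping[str, Any]]) -> dict[str, Any]:
    """Mean of each metric over records; missing values are excluded."""
    out: dict[str, Any] = {}
    for field in METRIC_FIELDS:
        vals = [
            r[field]
            for r in records
            if r.get(field) is not None and not _is_nan(r.get(field))
        ]
        out[field] = float(np.mean(vals)) if vals else None
    return out


def _is_nan(x: Any) -> bool:
    return isinstance(x, float) and math.isnan(x)


def write_report(
    results: Sequence[Mapping[str, Any]],
    path: str | os.PathLike,
    features: Sequence[Mapping[str, Any]] | None = None,
    features_path: str | os.PathLike | None = None,
) -> None:
    """Write a JSON metric report and an optional companion feature CSV.

    ``results`` holds one record per image with the pixel-wise metrics
    (accuracy, sensitivity, jaccard, dsc; a missing sensitivity — no
    positive truth pixels — is carried as None and excluded from the
    mean row). The report notes that accuracy is pixel-wise.
    """
    if not results:
        raise ValidationError("empty result list: nothing to report")
    for i, rec in enumerate(results):
        for field in METRIC_FIELDS:
            if field not in rec:
                raise ValidationError(f"record {i} is missing metric field {field!r}")
    report = {
        "metric_definition": "pixel-wise; sensitivity excluded from mean when truth is empty",
        "per_image": [dict(r) for r in results],
        "mean": _mean_row(results),
        "n_images": len(results),
    }
    with open(os.fspath(path), "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=False, default=_jsonable)
    if features is not None and features_path is not None:
        write_feature_csv(features, features_path)


def _jsonable(x: Any) -> Any:
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_feature_csv(
    features: Sequence[Mapping[str, Any]], path: str | os.PathLike
) -> None:
    """Write per-image hole features as CSV (one row per image)."""
    if not features:
        raise ValidationError("empty feature list: nothing to write")
    fieldnames = list(features[0].keys())
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for rec in features:
            writer.writerow(dict(rec))
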