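"""Geometry/intensity standardization and speckle suppression.

OCT B-scans carry multiplicative speckle from coherent detection.
The denoiser is a local-statistics adaptive (Lee/Wiener-type) filter:

    out = m + max(0, v - v_n) / max(v, eps) * (in - m)

with ``m``, ``v`` the mean and variance over a sliding window and
``v_n`` the noise variance. Where the local variance falls below the
noise floor the output collapses to the local mean (flat regions are
mean-filtered); where local variance dominates (edges, layer
boundaries) the gain approaches 1 and detail is preserved. An optional
log-domain mode applies log -> filter -> exp for multiplicative
fidelity; the additive default keeps the pipeline monotone in
intensity.

Standardization resizes to the working geometry (default 224 x 224,
bilinear) and min-max rescales intensities to span [0, 1]; resizing
comes first so the default filter window is scale-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from ._validate import as_gray_image
from .errors import ValidationError

_EPS = 1e-12

#: Log-domain offset keeping log() finite on zero-intensity pixels.
_LOG_FLOOR = 1e-3


@dataclass(frozen=True)
class DenoiseParams:
    """Adaptive-filter parameters.

    Parameters
    ----------
    window
        Odd side length of the square sliding window, in pixels.
    noise_variance
        Speckle/noise variance in normalized-intensity² units; if None
        it is estimated from the image (background tiles).
    log_domain
        Apply the filter to log-intensities (multiplicative model).
    """

    window: int = 5
    noise_variance: float | None = None
    log_domain: bool = False

    def validate(self, shape: tuple[int, int] | None = None) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError(f"window must be odd and >= 3, got {self.window}")
        if shape is not None and self.window > min(shape):
            raise ValidationError(
                f"window {self.window} exceeds image extent {min(shape)}"
            )
        if self.noise_variance is not None and self.noise_variance < 0:
            raise ValidationError("noise_variance must be >= 0")


def standardize(
    img: np.ndarray, target_height: int = 224, target_width: int = 224
) -> np.ndarray:
    """Resize to the working geometry and min-max rescale to [0, 1].

    Bilinear interpolation; constant images map to all-zeros (the
    min-max stretch of a constant is degenerate).
    """
    arr = as_gray_image(img)
    if target_height < 3 or target_width < 3:
        raise ValidationError("target dimensions must be >= 3")
    if arr.shape != (target_height, target_width):
        arr = resize(
            arr,
            (target_height, target_width),
            order=1,
            mode="edge",
            anti_aliasing=arr.shape[0] > target_height or arr.shape[1] > target_width,
            preserve_range=True,
        )
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < _EPS:
        return np.zeros_like(arr)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def estimate_noise_variance(img: np.ndarray, tile: int = 16) -> float:
    """Background-dominated noise-variance estimate.

    The image is tiled into non-overlapping ``tile`` x ``tile`` windows;
    the estimate is the mean of the per-tile variances over the
    lowest-variance decile of tiles. In a B-scan the darkest, flattest
    tiles are vitreous/background, so their variance is dominated by
    noise rather than anatomy.
    """
    arr = as_gray_image(img)
    h, w = arr.shape
    tile = max(2, min(tile, h, w))
    th, tw = h // tile, w // tile
    if th == 0 or tw == 0:
        return float(arr.var())
    tiles = arr[: th * tile, : tw * tile].reshape(th, tile, tw, tile)
    variances = tiles.transpose(0, 2, 1, 3).reshape(-1, tile * tile).var(axis=1)
    variances.sort()
    n_keep = max(1, int(np.ceil(variances.size / 10)))
    est = float(variances[:n_keep].mean())
    return est if est > 1e-18 else 0.0  # drop float residue on flat tiles


def adaptive_denoise(img: np.ndarray, params: DenoiseParams | None = None) -> np.ndarray:
    """Local-statistics adaptive (Lee/Wiener-type) speckle filter.

    Deterministic; output clipped to [0, 1]; where local variance is at
    or below the noise variance the output equals the local mean.
    Boundary statistics use replicate padding (zero padding would draw
    dark halos along the scan borders).
    """
    arr = as_gray_image(img)
    params = params or DenoiseParams()
    params.validate(arr.shape)
    v_n = (
        params.noise_variance
        if params.noise_variance is not None
        else estimate_noise_variance(arr)
    )
    work = np.log(np.maximum(arr, _LOG_FLOOR)) if params.log_domain else arr
    out = _lee_filter(work, params.window, v_n)
    if params.log_domain:
        out = np.exp(out)
    return np.clip(out, 0.0, 1.0)


def _lee_filter(arr: np.ndarray, window: int, noise_variance: float) -> np.ndarray:
    mean = ndimage.uniform_filter(arr, size=window, mode="nearest")
    sq_mean = ndimage.uniform_filter(arr * arr, size=window, mode="nearest")
    var = np.maximum(sq_mean - mean * mean, 0.0)
    gain = np.maximum(var - noise_variance, 0.0) / np.maximum(var, _EPS)
    return mean + gain * (arr - mean)
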