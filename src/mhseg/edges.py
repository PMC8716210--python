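"""Derivative-based edge information.

Two edge primitives drive the hole segmentation:

* Sobel gradient fields — the 3x3 kernel pair applied by correlation
  (no kernel flip) under replicate padding, giving the horizontal and
  vertical responses Lx, Ly, the gradient magnitude
  ``|∇L| = sqrt(Lx² + Ly²)`` and direction ``θ = atan2(Ly, Lx)``.

* The blurred-step (erf) edge-profile model for sub-pixel edge
  localization on a 1-D scanline:

      f(x) = (Ir − Il)/2 · erf((x − x0) / (σ√2)) + (Ir + Il)/2

  with asymptotic intensities Il (left) and Ir (right), edge centre x0
  and blur scale σ in pixels. The edge *outset* and *end* are reported
  at x0 − 2σ and x0 + 2σ, bracketing ~95% of the intensity transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.special import erf

from ._validate import as_binary_mask, as_gray_image
from .errors import FitFailureError, NoEdgeError, ValidationError

#: Horizontal-derivative Sobel kernel (columns -1, 0, +1; responds to
#: intensity increasing with column index).
SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])

#: Vertical-derivative Sobel kernel (rows +1, 0, -1; responds to
#: intensity decreasing with row index, i.e. brighter toward the top).
SOBEL_Y = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0], [-1.0, -2.0, -1.0]])


@dataclass(frozen=True)
class GradientField:
    """Per-pixel Sobel responses, magnitude and direction."""

    lx: np.ndarray
    ly: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.lx.shape


@dataclass(frozen=True)
class EdgeProfileModel:
    """Blurred-step model of one intensity edge on a scanline.

    ``i_left``/``i_right`` are the asymptotic intensities on either
    side, ``center`` the sub-pixel edge position and ``sigma`` the blur
    scale, both in pixels.
    """

    i_left: float
    i_right: float
    sigma: float
    center: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        for name in ("i_left", "i_right"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")

    @property
    def outset(self) -> float:
        """Start of the edge transition (center − 2σ)."""
        return self.center - 2.0 * self.sigma

    @property
    def end(self) -> float:
        """End of the edge transition (center + 2σ)."""
        return self.center + 2.0 * self.sigma


def sobel_gradients(img: np.ndarray) -> GradientField:
    """Sobel gradient field of a gray image.

    Kernels are applied by correlation with replicate padding; the
    magnitude and direction are flip-invariant, so downstream stages do
    not depend on the correlation-vs-convolution convention.
    """
    arr = as_gray_image(img)
    lx = ndimage.correlate(arr, SOBEL_X, mode="nearest")
    ly = ndimage.correlate(arr, SOBEL_Y, mode="nearest")
    magnitude = np.hypot(lx, ly)
    direction = np.arctan2(ly, lx)
    return GradientField(lx=lx, ly=ly, magnitude=magnitude, direction=direction)


def edge_profile_value(model: EdgeProfileModel, x: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the erf blurred-step model at position(s) ``x``."""
    return _erf_step(
        np.asarray(x, dtype=np.float64),
        model.i_left,
        model.i_right,
        model.sigma,
        model.center,
    )


def _erf_step(
    x: np.ndarray, i_left: float, i_right: float, sigma: float, center: float
) -> np.ndarray:
    return (i_right - i_left) / 2.0 * erf((x - center) / (sigma * np.sqrt(2.0))) + (
        i_right + i_left
    ) / 2.0


def fit_edge_profile(scanline: np.ndarray) -> EdgeProfileModel:
    """Least-squares fit of the erf step model to a 1-D profile.

    Initialization: asymptotic intensities from the first/last-quartile
    means, centre at the maximum-|gradient| sample, σ = 1; σ is bounded
    in [0.3, len/2]. The fitted model's ``residual`` holds the 2-norm
    of the final residuals.

    Raises
    ------
    NoEdgeError
        The scanline is constant (no transition to localize).
    FitFailureError
        The optimizer reported non-convergence.
    """
    y = np.asarray(scanline, dtype=np.float64).ravel()
    if y.size < 7:
        raise ValidationError(f"scanline must have length >= 7, got {y.size}")
    if np.ptp(y) < 1e-12:
        raise NoEdgeError("constant scanline: no edge to fit")
    n = y.size
    x = np.arange(n, dtype=np.float64)
    q = max(1, n // 4)
    i_left0 = float(np.clip(y[:q].mean(), 0.0, 1.0))
    i_right0 = float(np.clip(y[-q:].mean(), 0.0, 1.0))
    center0 = float(np.argmax(np.abs(np.gradient(y))))
    sigma_lo, sigma_hi = 0.3, n / 2.0
    p0 = np.array([i_left0, i_right0, 1.0, center0])
    lower = np.array([0.0, 0.0, sigma_lo, 0.0])
    upper = np.array([1.0, 1.0, sigma_hi, float(n - 1)])
    p0 = np.clip(p0, lower, upper)

    def residuals(p: np.ndarray) -> np.ndarray:
        return _erf_step(x, p[0], p[1], p[2], p[3]) - y

    result = least_squares(
        residuals,
        p0,
        bounds=(lower, upper),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    if not result.success:
        raise FitFailureError(
            f"edge-profile fit did not converge: {result.message} "
            f"(nfev={result.nfev}, cost={result.cost:.3g})"
        )
    i_left, i_right, sigma, center = result.x
    return EdgeProfileModel(
        i_left=float(i_left),
        i_right=float(i_right),
        sigma=float(sigma),
        center=float(center),
        residual=float(np.linalg.norm(result.fun)),
    )


def edge_map(field: GradientField, rel_threshold: float = 0.2) -> np.ndarray:
    """Binarize a gradient field at a fraction of its peak magnitude.

    ``mask = magnitude >= rel_threshold * max(magnitude)``; an all-zero
    field yields an empty mask for any positive threshold.
    """
    if not (0.0 <= rel_threshold <= 1.0):
        raise ValidationError("rel_threshold must lie in [0, 1]")
    mag = field.magnitude
    peak = float(mag.max())
    # a vanishing peak (constant image up to float residue) has no edges
    if peak <= 1e-12 and rel_threshold > 0.0:
        return np.zeros(mag.shape, dtype=np.uint8)
    return as_binary_mask(mag >= rel_threshold * peak)
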