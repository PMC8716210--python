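"""Synthetic fovea-centred OCT B-scan phantoms with ground truth.

The phantom emulates the geometry of a standardized macular B-scan:
a dark vitreous background, a bright multilayer retinal band
(sublayers of distinct reflectivity, the bottom one the
hyper-reflective RPE), a Gaussian foveal pit carved into the inner
surface, optionally a full-thickness hypo-reflective hole centred on
the pit, vertical shadow artifacts mimicking vessel shadowing,
fully-developed multiplicative speckle (gamma with mean 1 and
variance 1/looks, the standard coherent-imaging model) and a Gaussian
blur standing in for the detector PSF.

Ground truth is defined *pre-noise* — the generative hole region — so
evaluation measures recovery of the latent object, not of a noisy
appearance. What the phantom does not emulate: physical OCT forward
modelling (coherence, A-scan PSF, depth attenuation), cysts,
epiretinal membranes, curvature of the retina.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError

#: Vitreous/background reflectivity.
BACKGROUND_LEVEL = 0.05

#: Default sublayer reflectivities, inner to outer; the last is the
#: hyper-reflective RPE band.
DEFAULT_LAYERS = (0.65, 0.45, 0.55, 0.40, 0.90)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic B-scan.

    Geometry defaults to the standardized working size (224 x 224,
    band rows ~60-150, pit at the centre column). ``speckle_looks``
    may be None to disable speckle entirely (a noise-free phantom).
    """

    height: int = 224
    width: int = 224
    band_top: int = 60
    band_bottom: int = 150
    layer_levels: tuple[float, ...] = DEFAULT_LAYERS
    pit_depth: int = 25
    pit_sigma: float = 12.0
    has_hole: bool = True
    hole_width: int = 30
    hole_col: int | None = None  # None -> centre column
    speckle_looks: int | None = 8
    shadow_cols: tuple[tuple[int, int, float], ...] = field(default=())
    blur_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.band_top < self.band_bottom < self.height):
            raise ValidationError(
                f"need 0 <= band_top < band_bottom < height, got "
                f"{self.band_top}, {self.band_bottom}, {self.height}"
            )
        if self.hole_width >= self.width:
            raise ValidationError("hole_width must be smaller than the image width")
        if self.has_hole and self.hole_width < 1:
            raise ValidationError("hole_width must be >= 1 when has_hole")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ValidationError("speckle_looks must be >= 1 (or None to disable)")
        if not self.layer_levels or any(
            not (0.0 < lv <= 1.0) for lv in self.layer_levels
        ):
            raise ValidationError("layer_levels must be reflectivities in (0, 1]")
        if self.pit_depth < 0 or self.pit_depth >= self.band_bottom - self.band_top:
            raise ValidationError("pit_depth must be in [0, band thickness)")
        if self.pit_sigma <= 0 or self.blur_sigma < 0:
            raise ValidationError("pit_sigma must be > 0 and blur_sigma >= 0")
        for col, width, att in self.shadow_cols:
            if not (0 <= col < self.width) or width < 1 or not (0.0 < att <= 1.0):
                raise ValidationError(f"invalid shadow ({col}, {width}, {att})")

    @property
    def center_col(self) -> int:
        return self.width // 2 if self.hole_col is None else self.hole_col


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, PhantomSpec]:
    """Render one phantom B-scan and its ground-truth hole mask.

    Construction order: background, sublayers, foveal pit (the inner
    surface lowered by ``pit_depth * exp(-(c-c0)^2 / (2 pit_sigma^2))``),
    full-thickness hole, shadows, multiplicative speckle, blur, clip.
    Deterministic under a fixed spec (including its seed).
    """
    spec = spec or PhantomSpec()
    spec.validate()
    h, w = spec.height, spec.width
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)

    # horizontal sublayers between band_top and band_bottom
    n_layers = len(spec.layer_levels)
    bounds = np.linspace(spec.band_top, spec.band_bottom, n_layers + 1).round().astype(int)
    for lv, r0, r1 in zip(spec.layer_levels, bounds[:-1], bounds[1:]):
        img[r0:r1, :] = lv

    # foveal pit: carve the inner surface down by a Gaussian profile
    cols = np.arange(w)
    c0 = spec.center_col
    pit = spec.pit_depth * np.exp(-((cols - c0) ** 2) / (2.0 * spec.pit_sigma**2))
    top = np.round(spec.band_top + pit).astype(int)
    rows = np.arange(h)[:, None]
    img[(rows < top[None, :]) & (rows >= spec.band_top)] = BACKGROUND_LEVEL

    # full-thickness hole centred on the pit
    truth = np.zeros((h, w), dtype=np.uint8)
    if spec.has_hole:
        half = spec.hole_width // 2
        c_lo = c0 - half
        c_hi = c_lo + spec.hole_width
        c_lo, c_hi = max(c_lo, 0), min(c_hi, w)
        hole_region = (
            (rows >= top[None, :])
            & (rows < spec.band_bottom)
            & (cols[None, :] >= c_lo)
            & (cols[None, :] < c_hi)
        )
        img[hole_region] = BACKGROUND_LEVEL
        truth[hole_region] = 1

    for col, width, att in spec.shadow_cols:
        img[:, col : col + width] *= att

    rng = np.random.default_rng(spec.seed)
    if spec.speckle_looks is not None:
        looks = spec.speckle_looks
        img *= rng.gamma(shape=looks, scale=1.0 / looks, size=(h, w))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma, mode="nearest")
    return np.clip(img, 0.0, 1.0), truth, spec


def generate_dataset(
    n: int,
    ranges: dict | None = None,
    seed: int = 0,
) -> tuple[list[tuple[np.ndarray, np.ndarray, PhantomSpec]], pd.DataFrame]:
    """Draw ``n`` phantoms with per-image specs sampled from ``ranges``.

    ``ranges`` maps spec field names to (low, high) tuples (sampled
    uniformly; integer fields get integer draws), to a list of choices,
    or to a fixed value; ``hole_prob`` (default 0.5) sets the fraction
    of phantoms carrying a hole. Per-image seeds are derived
    deterministically from the master seed. Returns the triples and a
    manifest DataFrame of the per-image specs.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    ranges = dict(ranges or {})
    hole_prob = float(ranges.pop("hole_prob", 0.5))
    base = PhantomSpec()
    int_fields = {
        "height", "width", "band_top", "band_bottom", "pit_depth",
        "hole_width", "hole_col", "speckle_looks",
    }
    for key in ranges:
        if not hasattr(base, key):
            raise ValidationError(f"unknown PhantomSpec field {key!r}")
    rng = np.random.default_rng(seed)
    triples = []
    rows = []
    for i in range(n):
        overrides: dict = {"has_hole": bool(rng.random() < hole_prob)}
        for key, rv in ranges.items():
            if isinstance(rv, (list, tuple)) and len(rv) == 2 and all(
                isinstance(v, (int, float)) for v in rv
            ):
                lo, hi = rv
                if key in int_fields:
                    overrides[key] = int(rng.integers(int(lo), int(hi) + 1))
                else:
                    overrides[key] = float(rng.uniform(lo, hi))
            elif isinstance(rv, (list, tuple)):
                overrides[key] = rv[int(rng.integers(len(rv)))]
            else:
                overrides[key] = rv
        overrides["seed"] = int(rng.integers(0, 2**31 - 1))
        spec = replace(base, **overrides)
        img, truth, spec = generate_phantom(spec)
        triples.append((img, truth, spec))
        row = {"index": i, **{k: _scalar(v) for k, v in vars(spec).items()}}
        rows.append(row)
    return triples, pd.DataFrame(rows)


def _scalar(v):
    if isinstance(v, tuple):
        return ";".join(str(x) for x in v)
    return v
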