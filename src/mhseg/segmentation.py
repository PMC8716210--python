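"""Fusing class map and edge map into a macular-hole segmentation.

The hybrid rule: multilevel thresholding proposes candidate regions
(darkest-class pixels inside the retinal band) and the derivative edge
map acts as evidence — a candidate must have a minimum fraction of its
boundary supported by edges, and its score combines area, edge support
and proximity to the foveal depression:

    score = area · edge_support · exp(−|centroid_col − fovea_col| / (width/8))

The spatial decay encodes the clinical prior that macular holes arise
at or near the fovea as a soft preference rather than a hard crop.

The retinal band (inner surface to outer boundary) restricts the
search space: a hole is a hypo-reflective gap *within* the band,
which distinguishes it from the vitreous above. Columns fully emptied
by a full-thickness hole carry no band evidence; their band rows are
linearly interpolated from the neighbouring valid columns so the hole
interior remains inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._validate import as_binary_mask, check_same_shape
from .errors import FoveaNotFoundError, NoRetinaError, ValidationError
from .thresholding import ClassMap

#: 4-connected (cross) structuring element for morphological refinement.
_CROSS = ndimage.generate_binary_structure(2, 1)
#: 8-connectivity for component extraction (4-connectivity splits
#: speckle-pitted components).
_EIGHT = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class RetinaBand:
    """Per-column inner (top) and outer (bottom) retinal boundary rows.

    ``valid[c]`` is False where no non-background pixel was found; for
    those columns ``top``/``bottom`` are interpolated.
    """

    top: np.ndarray
    bottom: np.ndarray
    valid: np.ndarray

    @property
    def width(self) -> int:
        return self.top.size

    def thickness(self) -> np.ndarray:
        return self.bottom - self.top

    def inside(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels strictly between top and bottom."""
        rows = np.arange(shape[0])[:, None]
        return (rows > self.top[None, :]) & (rows < self.bottom[None, :])


@dataclass(frozen=True)
class HoleCandidate:
    """One 8-connected hypo-reflective component inside the band."""

    mask: np.ndarray
    area: int
    centroid: tuple[float, float]
    edge_support: float
    score: float


@dataclass(frozen=True)
class HoleSegmentation:
    """Final hole mask plus provenance of how it was chosen."""

    mask: np.ndarray
    fovea_column: int
    band: RetinaBand
    chosen: HoleCandidate | None
    all_candidates: tuple[HoleCandidate, ...] = field(default=())
    fovea_off_center: bool = False

    @property
    def has_hole(self) -> bool:
        return self.chosen is not None


def detect_retina_band(classmap: ClassMap, median_window: int = 7) -> RetinaBand:
    """Trace the retinal band from a thresholded class map.

    Per column, top/bottom are the first/last rows labelled non-
    background (label ≥ 1); both traces are median-filtered over
    ``median_window`` columns to suppress single-column spikes, and
    invalid columns (no non-background pixel) are interpolated.

    Raises
    ------
    NoRetinaError
        More than half the columns contain no non-background pixel.
    """
    labels = classmap.labels
    h, w = labels.shape
    fg = labels >= 1
    valid = fg.any(axis=0)
    if valid.sum() <= w / 2:
        raise NoRetinaError(
            f"only {int(valid.sum())}/{w} columns contain retinal tissue"
        )
    # Columns holding only a sliver of tissue (well under the typical
    # column's worth) are hole or shadow columns, not band evidence:
    # blur bleed at a full-thickness hole's rim would otherwise anchor
    # the interpolated band far below the true inner surface.
    counts = fg.sum(axis=0).astype(np.float64)
    typical = np.median(counts[valid])
    valid = valid & (counts >= 0.25 * typical)
    if not valid.any():
        raise NoRetinaError("no column holds a typical retinal thickness")
    rows = np.arange(h)[:, None]
    top = np.where(fg, rows, h).min(axis=0).astype(np.float64)
    bottom = np.where(fg, rows, -1).max(axis=0).astype(np.float64)
    # fill invalid columns before filtering so the median window never
    # mixes in sentinel values
    cols = np.arange(w)
    top[~valid] = np.interp(cols[~valid], cols[valid], top[valid])
    bottom[~valid] = np.interp(cols[~valid], cols[valid], bottom[valid])
    top = ndimage.median_filter(top, size=median_window, mode="nearest")
    bottom = ndimage.median_filter(bottom, size=median_window, mode="nearest")
    bottom = np.maximum(bottom, top + 1)  # keep top < bottom everywhere
    return RetinaBand(top=top, bottom=bottom, valid=valid)


def locate_fovea_center(
    band: RetinaBand, smooth_window: int = 7
) -> tuple[int, bool]:
    """Column of the foveal depression (retinal thickness minimum).

    The per-column thickness (bottom − top) is smoothed by a moving
    average and minimized over valid columns restricted to the central
    half of the width; ties go to the column closest to width/2.

    Returns
    -------
    (column, off_center)
        ``off_center`` is True when the *global* thickness minimum lies
        outside the central half (the reported column is still the
        central-half minimum); recorded in provenance downstream.
    """
    w = band.width
    thickness = ndimage.uniform_filter1d(
        band.thickness().astype(np.float64), size=smooth_window, mode="nearest"
    )
    lo, hi = w // 4, w - w // 4  # central half, half-open
    central = np.zeros(w, dtype=bool)
    central[lo:hi] = True
    eligible = central & band.valid
    if not eligible.any():
        raise FoveaNotFoundError("no valid band columns in the central half")
    cols = np.flatnonzero(eligible)
    t = thickness[cols]
    min_t = t.min()
    ties = cols[t == min_t]
    center = (w - 1) / 2.0
    col = int(ties[np.argmin(np.abs(ties - center))])
    # flag when the overall minimum (any valid column) is off-centre
    all_valid = np.flatnonzero(band.valid)
    global_min_col = int(all_valid[np.argmin(thickness[all_valid])])
    off_center = not central[global_min_col]
    return col, off_center


def extract_hole_candidates(
    classmap: ClassMap,
    edges: np.ndarray,
    band: RetinaBand,
    fovea_col: int,
    min_area: int = 25,
    min_edge_support: float = 0.1,
    decay_frac: float = 8.0,
    connectivity: int = 8,
) -> list[HoleCandidate]:
    """Darkest-class components inside the band, filtered and scored.

    Candidate pixels are label-0 (hypo-reflective) pixels strictly
    inside the band. Components smaller than ``min_area`` or with less
    than ``min_edge_support`` of their boundary pixels within 2 px of
    an edge-map pixel are discarded. The score rewards area, edge
    support and foveal proximity (decay constant width/``decay_frac``).
    """
    edges = as_binary_mask(edges, "edge map")
    labels = classmap.labels
    check_same_shape(labels, edges, "class map and edge map")
    if labels.shape[1] != band.width:
        raise ValidationError("band width does not match image width")
    h, w = labels.shape
    candidate_px = (labels == 0) & band.inside((h, w))
    structure = _EIGHT if connectivity == 8 else _CROSS
    comp_labels, n_comp = ndimage.label(candidate_px, structure=structure)
    if n_comp == 0:
        return []
    # distance (in px) from every pixel to the nearest edge pixel
    edge_dist = (
        ndimage.distance_transform_edt(edges == 0)
        if edges.any()
        else np.full((h, w), np.inf)
    )
    out: list[HoleCandidate] = []
    slices = ndimage.find_objects(comp_labels)
    for idx, sl in enumerate(slices, start=1):
        comp = comp_labels[sl] == idx
        area = int(comp.sum())
        if area < min_area:
            continue
        interior = ndimage.binary_erosion(comp, structure=_EIGHT, border_value=0)
        boundary = comp & ~interior
        support = float(np.mean(edge_dist[sl][boundary] <= 2.0))
        if support < min_edge_support:
            continue
        rr, cc = np.nonzero(comp)
        centroid = (
            float(rr.mean() + sl[0].start),
            float(cc.mean() + sl[1].start),
        )
        score = (
            area
            * support
            * float(np.exp(-abs(centroid[1] - fovea_col) / (w / decay_frac)))
        )
        full = np.zeros((h, w), dtype=np.uint8)
        full[sl][comp] = 1
        out.append(
            HoleCandidate(
                mask=full,
                area=area,
                centroid=centroid,
                edge_support=support,
                score=score,
            )
        )
    return out


def select_hole(
    candidates: list[HoleCandidate], fovea_col: int | None = None
) -> HoleCandidate | None:
    """Maximum-score candidate; ties → larger area, then leftmost centroid."""
    if not candidates:
        return None
    return max(
        candidates,
        key=lambda c: (c.score, c.area, -c.centroid[1]),
    )


def refine_mask(mask: np.ndarray, band: RetinaBand | None = None) -> np.ndarray:
    """Morphological cleanup: close, fill holes, open by reconstruction.

    Closing (3x3 cross) bridges speckle pits, hole-filling removes
    enclosed background, and opening-by-reconstruction (erosion by the
    cross followed by geodesic reconstruction) deletes components too
    thin to survive erosion while leaving the shape of the survivors
    intact — a plain structural opening would clip convex corners.
    Idempotent on its own output; when ``band`` is given the result is
    clipped to strictly-inside-band so refinement can never leak the
    mask past the retinal boundaries.
    """
    m = as_binary_mask(mask).astype(bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.uint8)
    m = ndimage.binary_closing(m, structure=_CROSS)
    m = ndimage.binary_fill_holes(m, structure=_CROSS)
    seed = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    m = ndimage.binary_propagation(seed, structure=_EIGHT, mask=m)
    if band is not None:
        m &= band.inside(m.shape)
    return m.astype(np.uint8)
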