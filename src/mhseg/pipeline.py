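"""End-to-end pipeline: preprocess → derive → threshold → extract hole.

Stage order: standardize geometry/intensity, adaptively denoise,
compute Sobel gradients and the edge map, multilevel-threshold the
denoised image, trace the retinal band, locate the foveal depression,
extract/score hole candidates (thresholded regions vetted by edge
support), select the best, and morphologically refine it. The whole
chain is deterministic: identical image + config give a bit-identical
mask and report.

Each stage logs one line (name, wall time, key parameters) through the
``mhseg.pipeline`` logger.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from .edges import edge_map, sobel_gradients
from .errors import InsufficientModesError
from .preprocess import DenoiseParams, adaptive_denoise, standardize
from .segmentation import (
    HoleSegmentation,
    detect_retina_band,
    extract_hole_candidates,
    locate_fovea_center,
    refine_mask,
    select_hole,
)
from .thresholding import apply_thresholds, build_histogram, otsu_multilevel, valley_thresholds

logger = logging.getLogger("mhseg.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the segmentation pipeline (config-file keys)."""

    # preprocess.*
    target_size: tuple[int, int] = (224, 224)
    window: int = 5
    noise_variance: float | None = None
    log_domain: bool = False
    # edges.*
    rel_threshold: float = 0.2
    # threshold.*
    k: int = 3
    method: str = "otsu"  # {"otsu", "valley"}; valley falls back to otsu
    bins: int = 256
    smooth_window: int = 5
    # segment.*
    min_area: int = 25
    min_edge_support: float = 0.1
    decay_frac: float = 8.0
    connectivity: int = 8

    @classmethod
    def from_mapping(cls, cfg: dict[str, Any]) -> "PipelineConfig":
        """Build from a nested mapping with sections preprocess/edges/
        threshold/segment (flat keys also accepted)."""
        flat: dict[str, Any] = {}
        sections = {"preprocess", "edges", "threshold", "segment"}
        for key, value in cfg.items():
            if key in sections and isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "target_size" in flat and flat["target_size"] is not None:
            flat["target_size"] = tuple(flat["target_size"])
        return cls(**flat)


@contextmanager
def _stage(name: str, **params: Any):
    t0 = time.perf_counter()
    yield
    logger.info(
        "stage=%s elapsed=%.3fs %s",
        name,
        time.perf_counter() - t0,
        " ".join(f"{k}={v}" for k, v in params.items()),
    )


def segment_image(
    img: np.ndarray, config: PipelineConfig | None = None
) -> HoleSegmentation:
    """Run the full hole-segmentation pipeline on one B-scan."""
    cfg = config or PipelineConfig()

    with _stage("standardize", target=cfg.target_size):
        work = standardize(img, *cfg.target_size)
    with _stage("denoise", window=cfg.window, log_domain=cfg.log_domain):
        work = adaptive_denoise(
            work,
            DenoiseParams(
                window=cfg.window,
                noise_variance=cfg.noise_variance,
                log_domain=cfg.log_domain,
            ),
        )
    with _stage("edges", rel_threshold=cfg.rel_threshold):
        field_ = sobel_gradients(work)
        edges = edge_map(field_, cfg.rel_threshold)
    with _stage("threshold", k=cfg.k, method=cfg.method, bins=cfg.bins):
        hist = build_histogram(work, bins=cfg.bins)
        if cfg.method == "valley":
            try:
                ts = valley_thresholds(hist, k=cfg.k, smooth_window=cfg.smooth_window)
            except InsufficientModesError:
                logger.info("valley thresholding found too few modes; using otsu")
                ts = otsu_multilevel(hist, k=cfg.k)
        else:
            ts = otsu_multilevel(hist, k=cfg.k)
        classmap = apply_thresholds(work, ts)
    with _stage("band"):
        band = detect_retina_band(classmap)
    with _stage("fovea"):
        fovea_col, off_center = locate_fovea_center(band)
    with _stage(
        "candidates", min_area=cfg.min_area, min_edge_support=cfg.min_edge_support
    ):
        candidates = extract_hole_candidates(
            classmap,
            edges,
            band,
            fovea_col,
            min_area=cfg.min_area,
            min_edge_support=cfg.min_edge_support,
            decay_frac=cfg.decay_frac,
            connectivity=cfg.connectivity,
        )
        chosen = select_hole(candidates, fovea_col)
    with _stage("refine"):
        if chosen is not None:
            mask = refine_mask(chosen.mask, band=band)
        else:
            mask = np.zeros(work.shape, dtype=np.uint8)
    return HoleSegmentation(
        mask=mask,
        fovea_column=fovea_col,
        band=band,
        chosen=chosen,
        all_candidates=tuple(candidates),
        fovea_off_center=off_center,
    )


def provenance_record(seg: HoleSegmentation) -> dict[str, Any]:
    """JSON-ready record of how the segmentation was obtained."""
    return {
        "has_hole": seg.has_hole,
        "fovea_column": int(seg.fovea_column),
        "fovea_off_center": bool(seg.fovea_off_center),
        "n_candidates": len(seg.all_candidates),
        "candidates": [
            {
                "area": int(c.area),
                "centroid_row": float(c.centroid[0]),
                "centroid_col": float(c.centroid[1]),
                "edge_support": float(c.edge_support),
                "score": float(c.score),
                "chosen": seg.chosen is c,
            }
            for c in sorted(
                seg.all_candidates, key=lambda c: c.score, reverse=True
            )
        ],
    }


def config_as_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = asdict(cfg)
    d["target_size"] = list(d["target_size"])
    return d
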