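"""Band tracing, fovea localization, candidate extraction, refinement."""

import numpy as np
import pytest

from mhseg.errors import NoRetinaError
from mhseg.phantom import PhantomSpec, generate_phantom
from mhseg.pipeline import PipelineConfig, segment_image
from mhseg.segmentation import (
    HoleCandidate,
    RetinaBand,
    detect_retina_band,
    extract_hole_candidates,
    locate_fovea_center,
    refine_mask,
    select_hole,
)
from mhseg.thresholding import ClassMap


def _classmap(labels, k=1):
    return ClassMap(labels=np.asarray(labels, dtype=np.int32), k=k)


def _flat_band_labels(h=100, w=60, top=30, bottom=70):
    labels = np.zeros((h, w), dtype=np.int32)
    labels[top:bottom, :] = 1
    return labels


class TestDetectRetinaBand:
    def test_flat_band_recovered(self):
        band = detect_retina_band(_classmap(_flat_band_labels(top=30, bottom=70)))
        assert np.all(np.abs(band.top - 30) <= 2)
        assert np.all(np.abs(band.bottom - 69) <= 2)
        assert band.valid.all()

    def test_known_phantom_band_rows(self, clean_phantom):
        img, _, spec = clean_phantom
        from mhseg.thresholding import apply_thresholds, build_histogram, otsu_multilevel

        hist = build_histogram(img)
        cm = apply_thresholds(img, otsu_multilevel(hist, 3))
        band = detect_retina_band(cm)
        far = np.r_[0:40, 185:224]  # away from pit and hole
        assert np.all(np.abs(band.top[far] - spec.band_top) <= 2)
        assert np.all(np.abs(band.bottom[far] - (spec.band_bottom - 1)) <= 2)

    def test_all_background_raises(self):
        with pytest.raises(NoRetinaError):
            detect_retina_band(_classmap(np.zeros((50, 50))))

    def test_single_column_spike_removed_by_median(self):
        labels = _flat_band_labels()
        labels[5:30, 17] = 1  # spike reaching far above the band in one column
        band = detect_retina_band(_classmap(labels))
        assert abs(band.top[17] - 30) <= 2

    def test_interpolates_over_emptied_columns(self):
        labels = _flat_band_labels(top=30, bottom=70)
        labels[:, 25:35] = 0  # full-thickness gap
        band = detect_retina_band(_classmap(labels))
        assert not band.valid[25:35].any()
        assert np.all(np.abs(band.top[25:35] - 30) <= 2)
        assert np.all(np.abs(band.bottom[25:35] - 69) <= 2)

    def test_top_strictly_above_bottom(self, noisy_phantom):
        img, _, _ = noisy_phantom
        from mhseg.thresholding import apply_thresholds, build_histogram, otsu_multilevel

        cm = apply_thresholds(img, otsu_multilevel(build_histogram(img), 3))
        band = detect_retina_band(cm)
        assert np.all(band.top < band.bottom)


class TestLocateFovea:
    def _band(self, thickness, w=224):
        top = np.full(w, 60.0)
        bottom = top + np.asarray(thickness, dtype=np.float64)
        return RetinaBand(top=top, bottom=bottom, valid=np.ones(w, dtype=bool))

    def test_central_pit_found(self):
        cols = np.arange(224)
        thickness = 90 - 25 * np.exp(-((cols - 112) ** 2) / (2 * 12.0**2))
        col, off = locate_fovea_center(self._band(thickness))
        assert abs(col - 112) <= 3
        assert not off

    def test_phantom_pit_recovered_without_hole(self):
        img, _, spec = generate_phantom(
            PhantomSpec(has_hole=False, speckle_looks=None, seed=0)
        )
        from mhseg.thresholding import apply_thresholds, build_histogram, otsu_multilevel

        cm = apply_thresholds(img, otsu_multilevel(build_histogram(img), 3))
        col, _ = locate_fovea_center(detect_retina_band(cm))
        assert abs(col - spec.center_col) <= 3

    def test_flat_band_tie_breaks_to_center(self):
        col, _ = locate_fovea_center(self._band(np.full(224, 80.0)))
        assert col in (111, 112)

    def test_off_center_pit_flagged_and_clamped_to_central_half(self):
        cols = np.arange(224)
        thickness = 90 - 30 * np.exp(-((cols - 40) ** 2) / (2 * 10.0**2))
        col, off = locate_fovea_center(self._band(thickness))
        assert off
        assert 56 <= col < 168  # stays inside the central half


class TestCandidatesAndSelection:
    def _setup(self, has_hole=True, seed=3):
        img, truth, spec = generate_phantom(PhantomSpec(has_hole=has_hole, seed=seed))
        from mhseg.edges import edge_map, sobel_gradients
        from mhseg.preprocess import DenoiseParams, adaptive_denoise
        from mhseg.thresholding import apply_thresholds, build_histogram, otsu_multilevel

        work = adaptive_denoise(img, DenoiseParams())
        cm = apply_thresholds(work, otsu_multilevel(build_histogram(work), 3))
        band = detect_retina_band(cm)
        fovea, _ = locate_fovea_center(band)
        edges = edge_map(sobel_gradients(work), 0.2)
        cands = extract_hole_candidates(cm, edges, band, fovea)
        return cands, truth, band

    def test_hole_phantom_yields_overlapping_candidate(self):
        cands, truth, _ = self._setup(has_hole=True)
        assert cands
        from mhseg.features import confusion_counts, metrics_from_counts

        best = max(
            metrics_from_counts(confusion_counts(c.mask, truth)).jaccard
            for c in cands
        )
        assert best > 0.5

    def test_no_hole_phantom_yields_no_candidates(self):
        cands, _, _ = self._setup(has_hole=False)
        assert cands == []

    def test_candidates_lie_inside_band(self):
        cands, _, band = self._setup(has_hole=True)
        inside = band.inside(cands[0].mask.shape)
        for c in cands:
            assert np.all(inside[c.mask.astype(bool)])

    def _cand(self, score, area=100, col=50.0):
        mask = np.zeros((10, 10), dtype=np.uint8)
        mask[0, 0] = 1
        return HoleCandidate(
            mask=mask, area=area, centroid=(5.0, col), edge_support=1.0, score=score
        )

    def test_select_single_candidate(self):
        c = self._cand(1.0)
        assert select_hole([c]) is c

    def test_select_prefers_foveal_candidate(self):
        w, fovea = 224, 112
        near = 200 * 1.0 * np.exp(-abs(112 - fovea) / (w / 8))
        far = 200 * 1.0 * np.exp(-abs(32 - fovea) / (w / 8))
        a = self._cand(near, col=112.0)
        b = self._cand(far, col=32.0)
        assert far < near  # the decay term dominates equal areas
        assert select_hole([a, b]) is a

    def test_select_tie_breaks_on_area_then_leftmost(self):
        big = self._cand(1.0, area=300, col=60.0)
        small = self._cand(1.0, area=100, col=10.0)
        assert select_hole([small, big]) is big
        left = self._cand(1.0, area=300, col=20.0)
        assert select_hole([big, left]) is left

    def test_select_empty_returns_none(self):
        assert select_hole([]) is None


class TestRefineMask:
    def test_empty_mask_stays_empty(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        assert refine_mask(m).sum() == 0

    def test_solid_rectangle_is_fixed_point(self):
        m = np.zeros((20, 30), dtype=np.uint8)
        m[4:15, 5:25] = 1
        assert np.array_equal(refine_mask(m), m)

    def test_interior_pinhole_filled(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[5:15, 5:15] = 1
        m[9, 9] = 0
        out = refine_mask(m)
        assert out[9, 9] == 1

    def test_isolated_speck_removed(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[3:14, 3:14] = 1
        m[17, 17] = 1  # single pixel cannot survive erosion
        out = refine_mask(m)
        assert out[17, 17] == 0
        assert out[5, 5] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_on_pipeline_like_masks(self, seed, rng):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[10:30, 12:28] = 1
        holes = rng.random((40, 40)) < 0.08
        m[holes] = 0
        once = refine_mask(m)
        assert np.array_equal(refine_mask(once), once)

    def test_band_clipping(self):
        m = np.zeros((30, 10), dtype=np.uint8)
        m[5:25, 2:8] = 1
        band = RetinaBand(
            top=np.full(10, 8.0), bottom=np.full(10, 20.0), valid=np.ones(10, bool)
        )
        out = refine_mask(m, band=band)
        assert np.all(band.inside(m.shape)[out.astype(bool)])


class TestEndToEnd:
    def test_deterministic_bit_exact(self, noisy_phantom):
        img, _, _ = noisy_phantom
        cfg = PipelineConfig()
        a = segment_image(img, cfg)
        b = segment_image(img, cfg)
        assert np.array_equal(a.mask, b.mask)
        assert a.fovea_column == b.fovea_column

    def test_hole_recovered_on_default_phantom(self, noisy_phantom):
        img, truth, _ = noisy_phantom
        seg = segment_image(img)
        from mhseg.features import evaluate_masks

        assert seg.has_hole
        assert evaluate_masks(seg.mask, truth).dsc > 0.8

    def test_valley_method_falls_back_and_completes(self, noisy_phantom):
        img, _, _ = noisy_phantom
        seg = segment_image(img, PipelineConfig(method="valley"))
        assert seg.mask.shape == img.shape
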