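"""Threshold-and-count extraction: binarisation, ROI areas, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import budhydro as bh
from budhydro.dendrometry import (
    ROIRect,
    ROISet,
    auto_threshold,
    binarize,
    bud_area,
    correct_and_normalize,
    extract_series,
    measure_areas,
)
from budhydro.render import default_rois, render_frame, render_frames


def brute_force_otsu(frame: np.ndarray) -> float:
    """Oracle: exhaustive between-class-variance scan over gray levels."""
    vals = frame.ravel()
    best_t, best_v = None, -1.0
    for t in range(int(vals.min()), int(vals.max()) + 1):
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestBinarize:
    def test_uniform_white_zero_foreground(self):
        frame = np.full((20, 20), 255, dtype=np.uint8)
        for thr in (0, 128, 255, "auto"):
            assert binarize(frame, thr).sum() == 0

    def test_uniform_black_all_foreground(self):
        frame = np.zeros((20, 20), dtype=np.uint8)
        assert binarize(frame, 128).all()
        assert binarize(frame, "auto").all()

    def test_bimodal_auto_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        frame = np.where(rng.random((64, 64)) < 0.3, 40, 200).astype(np.uint8)
        thr = auto_threshold(frame)
        assert 40 < thr < 200
        # agrees with the exhaustive-scan oracle up to the inter-mode gap
        oracle = brute_force_otsu(frame)
        assert 40 <= oracle < 200
        mask = binarize(frame, "auto")
        assert mask.sum() == (frame == 40).sum()

    def test_rejects_multichannel_and_bad_threshold(self):
        with pytest.raises(ValueError, match="single-channel"):
            binarize(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError, match="gray range"):
            binarize(np.zeros((4, 4)), 300)
        with pytest.raises(ValueError, match="empty"):
            binarize(np.zeros((0, 0)))


class TestMeasureAreas:
    def _rois(self):
        return ROISet(
            combined_roi=ROIRect(0, 0, 10, 20),
            stem_roi=ROIRect(0, 0, 10, 10),
            reference_roi=ROIRect(0, 25, 10, 35),
        )

    def test_full_mask_counts_roi_area(self):
        mask = np.ones((10, 40), dtype=bool)
        c, s, r = measure_areas(mask, self._rois())
        assert (c, s, r) == (200, 100, 100)

    def test_background_counts_zero(self):
        mask = np.zeros((10, 40), dtype=bool)
        assert measure_areas(mask, self._rois()) == (0, 0, 0)

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside frame"):
            measure_areas(np.zeros((5, 5), dtype=bool), self._rois())

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_disjoint_roi_counts_sum_to_union(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((30, 30)) < 0.4
        left, right = ROIRect(0, 0, 30, 15), ROIRect(0, 15, 30, 30)
        union = ROIRect(0, 0, 30, 30)
        counts = [int(mask[r.slice()].sum()) for r in (left, right, union)]
        assert counts[0] + counts[1] == counts[2]

    def test_reference_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlaps"):
            ROISet(
                combined_roi=ROIRect(0, 0, 10, 20),
                stem_roi=ROIRect(0, 0, 10, 10),
                reference_roi=ROIRect(0, 15, 10, 25),
            )


class TestBudArea:
    def test_subtraction(self):
        assert bud_area(628, 400) == 228

    def test_equal_areas_zero(self):
        assert bud_area(400, 400) == 0

    def test_negative_flags_misconfiguration(self):
        with pytest.raises(ValueError, match="ROI"):
            bud_area(100, 200)


class TestCorrectAndNormalize:
    def test_constant_reference_is_plain_normalisation(self):
        tissue = np.array([100.0, 110.0, 120.0])
        ref = np.full(3, 50.0)
        out = correct_and_normalize(tissue, ref)
        np.testing.assert_allclose(out, tissue / tissue[0])

    def test_pure_shared_drift_cancels(self):
        # tissue carrying exactly the reference's relative drift corrects to
        # a flat series of ones
        ref = np.array([50.0, 55.0, 48.0, 60.0])
        tissue = 200.0 * ref / ref[0]
        out = correct_and_normalize(tissue, ref)
        np.testing.assert_allclose(out, 1.0)
        # with an additive offset c the residual drift is second order:
        # |rel(t) - rel(0)| <= c/(1+c) * |1 - ref(t)/ref(0)|
        c = 0.25
        tissue_c = 200.0 * (ref / ref[0] + c)
        out_c = correct_and_normalize(tissue_c, ref)
        bound = c / (1 + c) * np.abs(1.0 - ref / ref[0]) + 1e-12
        assert (np.abs(out_c - out_c[0]) <= bound).all()

    def test_first_sample_is_one(self):
        rng = np.random.default_rng(1)
        tissue = 100 + rng.random(10)
        ref = 50 + rng.random(10)
        for mode in ("additive", "multiplicative"):
            assert correct_and_normalize(tissue, ref, mode)[0] == pytest.approx(1.0)

    def test_flat_reference_idempotent(self):
        rng = np.random.default_rng(2)
        tissue = 100 + rng.random(10)
        flat = np.ones(10)
        once = correct_and_normalize(tissue, flat)
        twice = correct_and_normalize(once, flat)
        np.testing.assert_allclose(twice, once)

    def test_errors(self):
        with pytest.raises(ValueError, match="aligned"):
            correct_and_normalize(np.ones(3), np.ones(4))
        with pytest.raises(ValueError, match="positive"):
            correct_and_normalize(np.array([0.0, 1.0]), np.ones(2))


class TestRenderRoundTrip:
    def test_ellipse_pixel_count_near_analytic_area(self):
        geom = bh.GeometrySpec()
        target = np.pi * 20 * 10
        frame = render_frame(0.0, target, 2000.0, geom)
        mask = binarize(frame, "auto")
        c, s, _ = measure_areas(mask, default_rois(geom))
        assert abs(bud_area(c, s) - target) < 80

    def test_zero_area_bud_renders_no_bud_pixels(self):
        geom = bh.GeometrySpec()
        frame = render_frame(4000.0, 0.0, 2000.0, geom)
        mask = binarize(frame, "auto")
        c, s, _ = measure_areas(mask, default_rois(geom))
        assert bud_area(c, s) == 0

    def test_constant_series_gives_identical_frames(self):
        import pandas as pd

        rows = []
        for i in range(3):
            for tis, area in (("bud", 600.0), ("stem", 4000.0), ("reference", 2000.0)):
                rows.append({"tissue": tis, "age_days": float(i), "area_px": area})
        stack = render_frames(pd.DataFrame(rows))
        assert (stack[0] == stack[1]).all() and (stack[1] == stack[2]).all()

    def test_geometry_overlap_rejected(self):
        geom = bh.GeometrySpec(bud_center=(70.0, 90.0))
        with pytest.raises(ValueError, match="overlap"):
            render_frame(4000.0, 1000.0, 2000.0, geom)

    def test_extraction_recovers_generator_truth(self):
        cfg = bh.ScenarioConfig(
            treatments=("D",), end_day=16, sampling_days=(15,), rng_seed=3, noise_sd=0.0015
        )
        area, _ = bh.simulate_area_series(cfg)
        sub = area[area["plant_id"] == "D1"]
        times = sub["age_days"].unique()[:12]
        sub = sub[sub["age_days"].isin(times)]
        geom = bh.GeometrySpec()
        stack = render_frames(sub, geom)
        ext = extract_series(stack, default_rois(geom), threshold="auto")
        for tissue in ("bud", "stem", "reference"):
            truth = sub[sub["tissue"] == tissue].sort_values("age_days")["area_px"].to_numpy()
            got = (
                ext[ext["tissue"] == tissue]
                .sort_values("timestamp")["raw_area_px"]
                .to_numpy()
            )
            assert np.max(np.abs(got - truth) / truth) <= 0.02
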