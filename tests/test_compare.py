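import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hawkman import (
    ReconstructionImage,
    artefact_scale_map,
    confidence_map,
    confidence_score,
    global_pcc,
    local_pcc,
    overlay_map,
    run_hawkman,
)
from hawkman.compare import SCALE_SENTINEL
from conftest import ridge_image, smooth_random_image
from oracles import global_pcc_bruteforce, local_pcc_bruteforce


class TestLocalPcc:
    def test_identical_inputs_correlate_perfectly(self, rng):
        a = rng.random((12, 12))
        pcc, defined = local_pcc(a, a, 5)
        assert defined.all()
        assert np.allclose(pcc, 1.0, atol=1e-12)

    def test_affine_anticorrelated_inputs(self, rng):
        a = rng.random((12, 12))
        b = -a + 2.0
        pcc, defined = local_pcc(a, b, 5)
        assert np.allclose(pcc[defined], -1.0, atol=1e-12)

    def test_matches_textbook_double_loop(self, rng):
        a = rng.random((9, 9))
        b = rng.random((9, 9))
        pcc, defined = local_pcc(a, b, 5)
        pcc_o, defined_o = local_pcc_bruteforce(a, b, 5)
        assert np.array_equal(defined, defined_o)
        assert np.max(np.abs(pcc[defined] - pcc_o[defined])) < 1e-12

    def test_even_window_rounds_down_to_odd(self, rng):
        a = rng.random((10, 10))
        b = rng.random((10, 10))
        pcc4, _ = local_pcc(a, b, 4)
        pcc3, _ = local_pcc(a, b, 3)
        assert np.allclose(np.nan_to_num(pcc4), np.nan_to_num(pcc3))

    def test_zero_variance_windows_flagged_undefined(self):
        a = np.zeros((8, 8))
        b = np.zeros((8, 8))
        pcc, defined = local_pcc(a, b, 3)
        assert not defined.any()
        assert np.all(np.isnan(pcc))

    def test_binary_policy_scores_constant_foreground_agreement(self):
        a = np.ones((8, 8))
        b = np.ones((8, 8))
        pcc, defined = local_pcc(a, b, 3, constant_policy="binary")
        assert defined.all()
        assert np.all(pcc == 1.0)
        pcc2, defined2 = local_pcc(a, np.zeros((8, 8)), 3, constant_policy="binary")
        assert defined2.all()
        assert np.all(pcc2 == -1.0)


class TestConfidenceScore:
    @pytest.mark.parametrize(
        "ps, pstr, expected",
        [
            (0.85, 0.85, 1.0),  # both terms saturate
            (0.425, 0.425, 0.5),  # half of the full-confidence correlation
            (-0.3, 1.0, 0.5),  # negative term clamps to zero
            (1.0, 1.0, 1.0),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_known_values(self, ps, pstr, expected):
        assert confidence_score(ps, pstr) == pytest.approx(expected, abs=1e-12)

    def test_undefined_correlation_contributes_nothing(self):
        assert confidence_score(float("nan"), 0.85) == pytest.approx(0.5)
        assert confidence_score(float("nan"), float("nan")) == 0.0

    @given(
        ps=st.floats(-1, 1, allow_nan=False),
        pstr=st.floats(-1, 1, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_range_and_symmetry(self, ps, pstr):
        s = confidence_score(ps, pstr)
        assert 0.0 <= s <= 1.0
        assert s == confidence_score(pstr, ps)

    def test_monotone_in_each_argument(self):
        grid = np.linspace(-1, 1, 101)
        vals = confidence_score(grid, np.full_like(grid, 0.3))
        assert np.all(np.diff(vals) >= 0)


class TestOverlayMap:
    def test_identical_masks_pure_yellow(self):
        m = np.zeros((6, 6), bool)
        m[2:4, 2:4] = True
        rgb = overlay_map(m.astype(float), m.astype(float))
        fg = rgb[m]
        assert np.all(fg == [255, 255, 0])
        assert np.all(rgb[~m] == 0)

    def test_disjoint_masks_magenta_and_cyan(self):
        t = np.zeros((6, 6), bool)
        r = np.zeros((6, 6), bool)
        t[1, 1] = True
        r[4, 4] = True
        rgb = overlay_map(t.astype(float), r.astype(float))
        assert np.all(rgb[1, 1] == [255, 0, 255])  # test-only: magenta
        assert np.all(rgb[4, 4] == [0, 255, 255])  # reference-only: cyan
        yellow = (rgb[..., 0] > 0) & (rgb[..., 1] > 0)
        assert not yellow.any()

    def test_swap_exchanges_magenta_and_cyan_exactly(self, rng):
        for _ in range(10):
            t = rng.random((12, 12)) > 0.6
            r = rng.random((12, 12)) > 0.6
            ab = overlay_map(t.astype(float), r.astype(float))
            ba = overlay_map(r.astype(float), t.astype(float))
            def colour_set(rgb, colour):
                return set(map(tuple, np.argwhere(np.all(rgb == colour, axis=-1))))
            magenta, cyan, yellow = [255, 0, 255], [0, 255, 255], [255, 255, 0]
            assert colour_set(ab, magenta) == colour_set(ba, cyan)
            assert colour_set(ab, cyan) == colour_set(ba, magenta)
            assert colour_set(ab, yellow) == colour_set(ba, yellow)


class TestConfidenceMap:
    def test_full_confidence_renders_cyan(self):
        combined = np.zeros((4, 8))
        combined[2] = 1.0
        rgb = confidence_map(combined, np.ones_like(combined))
        assert np.all(rgb[2] == [0, 255, 255])

    def test_zero_confidence_renders_red(self):
        combined = np.zeros((4, 8))
        combined[2] = 1.0
        rgb = confidence_map(combined, np.zeros_like(combined))
        assert np.all(rgb[2] == [255, 0, 0])

    def test_background_black_regardless_of_confidence(self):
        combined = np.zeros((4, 4))
        rgb = confidence_map(combined, np.ones_like(combined))
        assert np.all(rgb == 0)


class TestGlobalPcc:
    def test_identical_nonuniform_masks(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(float)
        assert global_pcc(m, m) == 1.0

    def test_complementary_masks(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(float)
        assert global_pcc(m, 1.0 - m) == -1.0

    def test_independent_masks_nearly_uncorrelated(self, rng):
        a = (rng.random((100, 100)) > 0.5).astype(float)
        b = (rng.random((100, 100)) > 0.5).astype(float)
        assert abs(global_pcc(a, b)) < 0.05

    def test_constant_input_undefined(self):
        assert global_pcc(np.ones((5, 5)), np.random.rand(5, 5)) is None

    def test_matches_bruteforce(self, rng):
        a = rng.random((14, 14))
        b = rng.random((14, 14))
        assert global_pcc(a, b) == pytest.approx(global_pcc_bruteforce(a, b), abs=1e-12)


class TestArtefactScaleMap:
    def test_always_confident_pixel_maps_to_scale_one(self):
        stack = [np.ones((3, 3))] * 4
        out = artefact_scale_map(stack, [1, 2, 3, 4], np.ones((3, 3)))
        assert np.all(out.scale_of_confidence == 1)

    def test_never_confident_pixel_keeps_sentinel(self):
        stack = [np.zeros((3, 3))] * 4
        out = artefact_scale_map(stack, [1, 2, 3, 4], np.ones((3, 3)))
        assert np.all(out.scale_of_confidence == SCALE_SENTINEL)
        # sentinel renders grey: equal RGB channels
        assert np.all(out.rgb[..., 0] == out.rgb[..., 1])
        assert np.all(out.rgb[..., 1] == out.rgb[..., 2])

    def test_first_crossing_of_threshold_recorded(self):
        values = [0.2, 0.5, 0.95, 0.99]
        stack = [np.full((2, 2), v) for v in values]
        out = artefact_scale_map(stack, [1, 2, 3, 4], np.ones((2, 2)))
        assert np.all(out.scale_of_confidence == 3)

    def test_non_contiguous_scales_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            artefact_scale_map([np.ones((2, 2))] * 2, [1, 3], np.ones((2, 2)))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            artefact_scale_map([], [], np.ones((2, 2)))


class TestRunHawkman:
    def test_self_comparison_full_confidence(self):
        img = ridge_image([40, 80], n=96)
        run = run_hawkman(img, img, psf_fwhm_nm=270, max_scale_no=8, render=False)
        for res in run.scales:
            assert res.pcc_sharp_global == pytest.approx(1.0, abs=1e-12)
            assert res.pcc_str_global == pytest.approx(1.0, abs=1e-12)
            assert np.all(res.s_conf[res.conf_defined] > 1.0 - 1e-12)
        assert np.all(
            run.artefact.scale_of_confidence[run.scales[0].conf_defined] == 1
        )

    def test_swapping_inputs_is_symmetric(self, rng):
        a = smooth_random_image(rng)
        b = smooth_random_image(rng)
        fwd = run_hawkman(a, b, psf_fwhm_nm=100, max_scale_no=5, render=True)
        rev = run_hawkman(b, a, psf_fwhm_nm=100, max_scale_no=5, render=True)
        for rf, rr in zip(fwd.scales, rev.scales):
            assert np.allclose(rf.s_conf, rr.s_conf, atol=1e-12)
            assert rf.pcc_sharp_global == pytest.approx(rr.pcc_sharp_global, abs=1e-12)
            assert rf.pcc_str_global == pytest.approx(rr.pcc_str_global, abs=1e-12)

    def test_collapsed_pair_agrees_only_at_large_scales(self):
        ref = ridge_image([60, 68], sigma_px=1.5)  # true pair, 8 px apart
        test = ridge_image([64], sigma_px=1.5)  # collapsed to the midline
        run = run_hawkman(test, ref, psf_fwhm_nm=270, max_scale_no=16, render=False)
        assert run.scales[1].pcc_str_global < run.scales[15].pcc_str_global

    def test_confidence_decreases_with_displacement_at_fixed_scale(self):
        ref = ridge_image([56])
        confs = []
        for delta in (2, 4, 8, 16):
            run = run_hawkman(ridge_image([56 + delta]), ref, psf_fwhm_nm=270, max_scale_no=20, render=False)
            confs.append(run.scales[-1].mean_conf)
        assert all(a > b for a, b in zip(confs, confs[1:]))

    def test_detection_scale_non_decreasing_in_displacement(self):
        ref = ridge_image([56])
        firsts = []
        for delta in (2, 4, 8, 16):
            run = run_hawkman(ridge_image([56 + delta]), ref, psf_fwhm_nm=270, max_scale_no=27, render=False)
            first = next(
                (r.scale.scale_no for r in run.scales if r.mean_conf >= 0.9),
                np.inf,
            )
            firsts.append(first)
        assert all(b >= a for a, b in zip(firsts, firsts[1:]))

    def test_mismatched_shapes_rejected(self):
        a = ReconstructionImage(np.ones((8, 8)), 10.0)
        b = ReconstructionImage(np.ones((8, 9)), 10.0)
        with pytest.raises(ValueError, match="shape"):
            run_hawkman(a, b, psf_fwhm_nm=270)

    def test_metrics_frame_columns(self):
        img = ridge_image([40], n=64)
        run = run_hawkman(img, img, psf_fwhm_nm=100, max_scale_no=3, render=False)
        frame = run.metrics_frame()
        assert list(frame.columns) == ["scale_no", "fwhm_nm", "pcc_sharp", "pcc_str", "mean_conf"]
        assert frame["scale_no"].tolist() == [1, 2, 3]
        assert frame["fwhm_nm"].tolist() == [10.0, 20.0, 30.0]
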