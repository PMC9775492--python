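"""Tests for the synthetic renderer and the quantification pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from valveflow.imaging import (Detection, ImagingError,
                               RenderParams, ROISpec, align_to_reference,
                               analyze_run, binarize, detect_chambers,
                               extract_roi, fit_calibration, magenta_of_roi,
                               quantify_image, render_assay_image,
                               rgb_to_cmyk, select_reagent_chamber,
                               two_point_concentration)


class TestRgbToCmyk:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), (0, 0, 0, 0)),    # white
        ((255, 0, 255), (0, 1, 0, 0)),      # pure magenta
        ((0, 0, 0), (0, 0, 0, 1)),          # black convention
        ((255, 0, 0), (0, 1, 1, 0)),        # red = magenta + yellow
        ((127.5, 127.5, 127.5), (0, 0, 0, 0.5)),
    ])
    def test_reference_colors(self, rgb, expected):
        assert rgb_to_cmyk(*rgb) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ImagingError):
            rgb_to_cmyk(256, 0, 0)
        with pytest.raises(ImagingError):
            rgb_to_cmyk(0, -1, 0)

    def test_lattice_sweep_against_formula(self):
        """All 17^3 points of an 8-bit lattice agree with an independent
        vectorized evaluation of the standard formula."""
        vals = np.linspace(0, 255, 17)
        r, g, b = np.meshgrid(vals, vals, vals, indexing="ij")
        rp, gp, bp = r / 255.0, g / 255.0, b / 255.0
        k = 1.0 - np.maximum.reduce([rp, gp, bp])
        with np.errstate(divide="ignore", invalid="ignore"):
            m_ref = np.where(k >= 1.0, 0.0, (1.0 - gp - k) / (1.0 - k))
            c_ref = np.where(k >= 1.0, 0.0, (1.0 - rp - k) / (1.0 - k))
        for i in range(17):
            for j in range(17):
                for l in range(17):
                    got = rgb_to_cmyk(r[i, j, l], g[i, j, l], b[i, j, l])
                    assert got.m == pytest.approx(m_ref[i, j, l], abs=1e-12)
                    assert got.c == pytest.approx(c_ref[i, j, l], abs=1e-12)
                    assert got.k == pytest.approx(k[i, j, l], abs=1e-12)

    @given(r=st.integers(0, 255), g=st.integers(0, 255), b=st.integers(0, 255))
    def test_channels_in_unit_interval(self, r, g, b):
        out = rgb_to_cmyk(r, g, b)
        for v in out:
            assert -1e-12 <= v <= 1.0 + 1e-12


class TestRenderer:
    def test_same_seed_identical_images(self):
        p = RenderParams(seed=11)
        a = render_assay_image(3.0, p)
        b = render_assay_image(3.0, p)
        assert np.array_equal(a, b)

    def test_blank_has_base_magenta(self):
        p = RenderParams(noise_sd=0.0)
        img = render_assay_image(0.0, p)
        _, rbox = p.chamber_boxes()
        roi = img[rbox[0]:rbox[2], rbox[1]:rbox[3]]
        assert magenta_of_roi(roi) == pytest.approx(p.base_magenta, abs=1e-3)

    def test_magenta_monotone_in_concentration(self):
        p = RenderParams(noise_sd=0.0)
        _, rbox = p.chamber_boxes()
        ms = []
        for conc in (0.0, 1.0, 4.0, 8.0, 10.0):
            img = render_assay_image(conc, p)
            ms.append(magenta_of_roi(img[rbox[0]:rbox[2], rbox[1]:rbox[3]]))
        assert all(b > a for a, b in zip(ms, ms[1:]))

    def test_saturation_ceiling(self):
        p = RenderParams(noise_sd=0.0)
        _, rbox = p.chamber_boxes()
        img = render_assay_image(1000.0, p)
        m = magenta_of_roi(img[rbox[0]:rbox[2], rbox[1]:rbox[3]])
        assert m == pytest.approx(p.saturation_ceiling, abs=1e-2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ImagingError):
            render_assay_image(-1.0, RenderParams())


class TestDetection:
    def test_constant_image_has_no_threshold(self):
        img = np.full((50, 50, 3), 128, dtype=np.uint8)
        with pytest.raises(ImagingError, match="no threshold"):
            binarize(img)

    def test_two_blob_mask(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[20:60, 50:150] = True     # top blob
        mask[120:160, 50:150] = True   # bottom blob
        dets = detect_chambers(mask, min_area=1000)
        assert len(dets) == 2
        assert dets[0].centroid[0] < dets[1].centroid[0]  # top first

    def test_min_area_filters_everything(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10:20, 10:20] = True
        with pytest.raises(ImagingError, match="chambers not found"):
            detect_chambers(mask, min_area=10_000)

    def test_rendered_image_yields_two_chambers(self):
        img = render_assay_image(4.0, RenderParams(seed=0))
        dets = detect_chambers(binarize(img))
        assert len(dets) == 2

    def test_select_reagent_is_bottom_most(self):
        img = render_assay_image(4.0, RenderParams(seed=0, noise_sd=0.0))
        p = RenderParams()
        dets = detect_chambers(binarize(img))
        reagent = select_reagent_chamber(dets)
        _, rbox = p.chamber_boxes()
        assert reagent.bbox == rbox
        with pytest.raises(ImagingError):
            select_reagent_chamber(dets[:1])


class TestExtractRoi:
    def test_centering_arithmetic(self):
        """Centroid (200, 400) with a 100x300 spec selects rows [150, 250)
        and cols [250, 550) (0-based half-open), checked by brute-force
        index comparison."""
        img = np.arange(500 * 900 * 3, dtype=np.float64).reshape(500, 900, 3)
        d = Detection(bbox=(100, 200, 300, 700), centroid=(200.0, 400.0),
                      area=1000)
        roi = extract_roi(img, d, ROISpec())
        assert np.array_equal(roi, img[150:250, 250:550])

    def test_single_pixel_roi(self):
        img = np.zeros((10, 10, 3))
        img[4, 7] = (9, 9, 9)
        d = Detection(bbox=(3, 6, 6, 9), centroid=(4.0, 7.0), area=9)
        roi = extract_roi(img, d, ROISpec(1, 1))
        assert roi.shape == (1, 1, 3)
        assert roi[0, 0, 0] == 9

    def test_half_away_rounding_of_centroid(self):
        img = np.zeros((300, 300, 3))
        d = Detection(bbox=(0, 0, 300, 300), centroid=(100.5, 100.4),
                      area=100)
        roi_spec = ROISpec(10, 10)
        roi = extract_roi(img, d, roi_spec)
        assert roi.shape == (10, 10, 3)
        # row rounds to 101 -> rows [96, 106); col rounds to 100
        assert np.shares_memory(roi, img[96:106, 95:105])

    def test_chamber_smaller_than_roi_errors(self):
        img = np.zeros((200, 200, 3))
        d = Detection(bbox=(10, 10, 60, 60), centroid=(35.0, 35.0), area=100)
        with pytest.raises(ImagingError, match="smaller than ROI"):
            extract_roi(img, d, ROISpec(100, 300))


class TestAlignment:
    def test_identity_zero_shift(self):
        img = render_assay_image(4.0, RenderParams(seed=2))
        out = align_to_reference(img, img)
        assert np.array_equal(out, img)

    def test_constructed_shift_recovered(self):
        """A copy shifted by (+5, -3) px aligns back onto the original."""
        p = RenderParams(seed=2, noise_sd=0.0)
        ref = render_assay_image(4.0, p)
        shifted = np.full_like(ref, int(p.background_gray))
        shifted[5:, :-3] = ref[:-5, 3:]
        realigned = align_to_reference(shifted, ref)
        q_ref = quantify_image(ref)
        q_re = quantify_image(realigned)
        assert q_re["detection"].bbox == q_ref["detection"].bbox
        assert q_re["magenta"] == pytest.approx(q_ref["magenta"], abs=1e-6)

    def test_blank_background_errors(self):
        blank = np.full((100, 100, 3), 60, dtype=np.uint8)
        ref = render_assay_image(4.0, RenderParams(seed=0))
        with pytest.raises(ImagingError):
            align_to_reference(blank, ref)

    def test_pipeline_shift_invariance(self):
        """Translating the input by up to 20 px changes the magenta
        estimate by < 1e-3 after alignment."""
        p = RenderParams(seed=5, noise_sd=2.0)
        ref = render_assay_image(4.0, p)
        m_ref = quantify_image(ref)["magenta"]
        for dr, dc in ((20, 0), (0, -20), (13, 17)):
            shifted = np.full_like(ref, int(p.background_gray))
            h, w = ref.shape[:2]
            src_r = slice(max(0, -dr), min(h, h - dr))
            src_c = slice(max(0, -dc), min(w, w - dc))
            dst_r = slice(max(0, dr), min(h, h + dr))
            dst_c = slice(max(0, dc), min(w, w + dc))
            shifted[dst_r, dst_c] = ref[src_r, src_c]
            m = quantify_image(shifted, ref=ref)["magenta"]
            assert abs(m - m_ref) < 1e-3


class TestMagentaOfRoi:
    def test_orders_agree_on_constant_roi(self):
        roi = np.full((10, 10, 3), 100, dtype=np.uint8)
        roi[..., 1] = 50
        assert magenta_of_roi(roi) == pytest.approx(
            magenta_of_roi(roi, per_pixel=True))

    def test_orders_differ_when_dominant_channel_varies(self):
        """Half orange-ish, half blue-ish pixels: every pixel has magenta
        0.5, but their mean triple is neutral gray with magenta 0 - the
        published mean-then-convert order is the canonical one."""
        roi = np.zeros((2, 2, 3), dtype=np.uint8)
        roi[0] = (200, 100, 0)
        roi[1] = (0, 100, 200)
        assert magenta_of_roi(roi, per_pixel=True) == pytest.approx(0.5,
                                                                    abs=1e-6)
        assert magenta_of_roi(roi) == pytest.approx(0.0, abs=1e-6)


class TestCalibration:
    def test_noiseless_exact_line(self):
        points = [(c, 0.1 + 0.05 * c) for c in (0.0, 2.0, 5.0, 10.0)]
        cal = fit_calibration(points, blank_sd=0.0)
        assert cal.slope == pytest.approx(0.05)
        assert cal.intercept == pytest.approx(0.1)
        assert cal.lod == 0.0
        assert cal.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        """{(0, 0.1), (5, 0.35), (10, 0.6)} with blank sd 0.002:
        slope 0.05, LOD = 3.3*0.002/0.05 = 0.132 mM."""
        cal = fit_calibration([(0, 0.1), (5, 0.35), (10, 0.6)],
                              blank_sd=0.002)
        assert cal.slope == pytest.approx(0.05)
        assert cal.lod == pytest.approx(0.132)

    def test_blank_replicates_sample_sd(self):
        d = 0.002 / np.sqrt(2.0)
        cal = fit_calibration([(0, 0.1), (5, 0.35), (10, 0.6)],
                              blank_replicates=[0.1 - d, 0.1 + d])
        assert cal.lod == pytest.approx(0.132)

    def test_too_few_concentrations(self):
        with pytest.raises(ImagingError):
            fit_calibration([(0, 0.1), (8, 0.5)], blank_sd=0.001)

    def test_negative_slope_rejected(self):
        with pytest.raises(ImagingError, match="non-responsive"):
            fit_calibration([(0, 0.6), (5, 0.35), (10, 0.1)], blank_sd=0.001)

    def test_noiseless_render_slope_equals_gain(self):
        """End-to-end calibration linearity: the fitted slope on noiseless
        synthetic images equals the renderer's magenta gain to 1e-6."""
        p = RenderParams(noise_sd=0.0, dtype="float64")
        points = []
        for conc in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0):
            m = quantify_image(render_assay_image(conc, p))["magenta"]
            points.append((conc, m))
        cal = fit_calibration(points, blank_sd=0.0)
        assert cal.slope == pytest.approx(p.magenta_gain_per_mM, abs=1e-6)
        assert cal.intercept == pytest.approx(p.base_magenta, abs=1e-6)


class TestTwoPoint:
    @pytest.mark.parametrize("ms,expected,flag", [
        (0.10, 0.0, False),
        (0.58, 8.0, False),
        (0.34, 4.0, False),
        (0.70, 10.0, True),    # above 8 mM: extrapolated
        (0.04, -1.0, True),    # below blank: extrapolated
    ])
    def test_linear_interpolation(self, ms, expected, flag):
        res = two_point_concentration(0.10, 0.58, ms)
        assert res.concentration_mM == pytest.approx(expected)
        assert res.extrapolated is flag

    def test_equal_references_rejected(self):
        with pytest.raises(ImagingError):
            two_point_concentration(0.3, 0.3, 0.3)


class TestAnalyzeRun:
    def test_recovers_known_concentration(self):
        p = lambda s: RenderParams(seed=s, noise_sd=2.0)
        samples = [render_assay_image(4.0, p(i)) for i in range(3)]
        cal0 = [render_assay_image(0.0, p(10 + i)) for i in range(2)]
        cal8 = [render_assay_image(8.0, p(20 + i)) for i in range(2)]
        frame, summary = analyze_run(samples, cal0, cal8)
        assert summary["n_samples"] == 3
        assert summary["concentration_mM"] == pytest.approx(4.0, rel=0.05)
        assert len(frame) == 7
        assert (frame["error"] == "").all()

    def test_failed_sample_becomes_error_row(self):
        good = render_assay_image(4.0, RenderParams(seed=0))
        blank = np.full_like(good, 60)
        frame, summary = analyze_run([blank], [good],
                                     [render_assay_image(8.0,
                                                         RenderParams(seed=1))])
        sample_rows = frame[frame["group"] == "sample"]
        assert (sample_rows["error"] != "").all()
        assert summary["n_samples"] == 0

    def test_failed_reference_group_fails_run(self):
        good = render_assay_image(4.0, RenderParams(seed=0))
        blank = np.full_like(good, 60)
        with pytest.raises(ImagingError, match="cal0"):
            analyze_run([good], [blank], [good])


def test_image_io_roundtrip(tmp_path):
    from valveflow.imaging import read_image, write_image
    img = render_assay_image(4.0, RenderParams(seed=3))
    path = tmp_path / "unit.png"
    write_image(path, img)
    assert np.array_equal(read_image(path), img)
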