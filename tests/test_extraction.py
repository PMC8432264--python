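"""Phantom rendering, ROI construction, drift correction, curve extraction."""

import numpy as np
import pytest

import cordmotion as cm
from cordmotion.config import PhantomGeometry
from cordmotion.extraction import (build_rois, correct_drift, extract_curve,
                                   curves_from_phantom)
from cordmotion.phantom import build_label_map, generate_phantom
from cordmotion.segments import SEGMENTS


@pytest.fixture(scope="module")
def subject(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="module")
def geometry():
    return PhantomGeometry()


class TestROIs:
    def test_central_third_rows(self, geometry):
        labels = build_label_map(geometry)
        rois = build_rois(labels, np.array(geometry.landmark_rows))
        a, b = geometry.landmark_rows[0], geometry.landmark_rows[1]
        span = b - a
        rows = np.nonzero(rois["C2/C3"].any(axis=1))[0]
        expected = [r for r in range(a, b)
                    if a + span / 3 <= r < a + 2 * span / 3]
        assert list(rows) == expected

    def test_rois_pairwise_disjoint_and_within_cord(self, geometry):
        labels = build_label_map(geometry)
        rois = build_rois(labels, np.array(geometry.landmark_rows))
        total = np.zeros_like(labels, dtype=int)
        for seg in SEGMENTS:
            assert rois[seg] is not None
            assert np.all(labels[rois[seg]] == geometry.LABEL_CORD)
            total += rois[seg]
        assert total.max() == 1  # no overlap

    def test_missing_cord_marks_segment_missing(self, geometry):
        labels = build_label_map(geometry)
        a, b = geometry.landmark_rows[2], geometry.landmark_rows[3]
        labels[a:b, :] = geometry.LABEL_STATIC  # erase cord in one interval
        rois = build_rois(labels, np.array(geometry.landmark_rows))
        assert rois["C4/C5"] is None
        assert rois["C5/C6"] is not None


class TestDriftCorrection:
    def test_injected_slope_recovered(self, subject, geometry):
        ph = generate_phantom(subject, geometry, drift_slope_sd=0.0,
                              noise_sd=0.0, rng=0)
        slope = 3.4e-4  # cm/s per ms
        drifted = ph.data + slope * ph.t[:, None, None]
        static = ph.labels == geometry.LABEL_STATIC
        corrected = correct_drift(drifted, static, t=ph.t)
        assert np.allclose(corrected, ph.data, atol=1e-6)
        # corrected static tissue has ~zero temporal slope
        m = corrected[:, static].mean(axis=1)
        assert abs(np.polyfit(ph.t, m, 1)[0]) < 1e-9

    def test_zero_drift_is_noop(self, subject, geometry):
        ph = generate_phantom(subject, geometry, drift_slope_sd=0.0,
                              noise_sd=0.0, rng=0)
        corrected = correct_drift(ph.data, ph.labels == geometry.LABEL_STATIC,
                                  t=ph.t)
        assert np.allclose(corrected, ph.data, atol=1e-9)

    def test_idempotence(self, subject, geometry):
        ph = generate_phantom(subject, geometry, drift_slope_sd=0.3,
                              noise_sd=0.05, rng=1)
        static = ph.labels == geometry.LABEL_STATIC
        once = correct_drift(ph.data, static, t=ph.t)
        twice = correct_drift(once, static, t=ph.t)
        assert np.allclose(once, twice, atol=1e-8)

    def test_empty_static_mask_raises(self, subject, geometry):
        ph = generate_phantom(subject, geometry, noise_sd=0.0, rng=0)
        with pytest.raises(ValueError, match="static"):
            correct_drift(ph.data, np.zeros_like(ph.labels, dtype=bool))


class TestExtraction:
    def test_uniform_roi_returns_pixel_series(self):
        data = np.zeros((10, 6, 6))
        data[:, 2:4, 2:4] = np.arange(10)[:, None, None] * 0.1
        roi = np.zeros((6, 6), dtype=bool)
        roi[2:4, 2:4] = True
        c = extract_curve(data, roi, hb=1000.0, segment="C5/C6")
        assert np.allclose(c.v, np.arange(10) * 0.1)

    def test_two_half_rois_average(self):
        data = np.zeros((10, 4, 4))
        data[:, 0, 0] = 1.0
        data[:, 3, 3] = 3.0
        roi = np.zeros((4, 4), dtype=bool)
        roi[0, 0] = roi[3, 3] = True
        c = extract_curve(data, roi, hb=500.0)
        assert np.allclose(c.v, 2.0)

    def test_extraction_is_linear_in_pixel_values(self, subject, geometry):
        ph = generate_phantom(subject, geometry, noise_sd=0.05, rng=3)
        rois = build_rois(ph.labels, ph.landmark_rows)
        roi = rois["C5/C6"]
        c1 = extract_curve(ph.data, roi, ph.hb, ph.t)
        c2 = extract_curve(2.5 * ph.data, roi, ph.hb, ph.t)
        assert np.allclose(c2.v, 2.5 * c1.v)


class TestEndToEnd:
    def test_noiseless_phantom_reproduces_curves_exactly(self, subject, geometry):
        ph = generate_phantom(subject, geometry, drift_slope_sd=0.0,
                              noise_sd=0.0, rng=0)
        extracted = curves_from_phantom(ph)
        for seg in SEGMENTS:
            assert np.allclose(extracted[seg].v, subject.curves[seg].v,
                               atol=1e-9)

    def test_drift_plus_motion_recovered_within_noise(self, subject, geometry):
        ph = generate_phantom(subject, geometry, drift_slope_sd=0.5,
                              noise_sd=0.05, rng=7)
        extracted = curves_from_phantom(ph)
        roi_size = min(int(np.sum(r)) for r in
                       build_rois(ph.labels, ph.landmark_rows).values())
        tol = 3 * 0.05 / np.sqrt(roi_size)
        for seg in SEGMENTS:
            rms = np.sqrt(np.mean((extracted[seg].v - subject.curves[seg].v) ** 2))
            assert rms <= tol + 1e-3  # small allowance for residual drift fit

    def test_missing_curve_rejected(self, subject, geometry):
        from dataclasses import replace
        crippled = replace(subject, curves={
            s: c for s, c in subject.curves.items() if s != "C4/C5"})
        with pytest.raises(ValueError, match="missing curves"):
            generate_phantom(crippled, geometry)

    def test_npz_round_trip(self, subject, geometry, tmp_path):
        ph = generate_phantom(subject, geometry, drift_slope_sd=0.2,
                              noise_sd=0.1, rng=5)
        ph.save_npz(tmp_path / "p.npz")
        back = cm.Phantom.load_npz(tmp_path / "p.npz")
        assert np.array_equal(back.data, ph.data)
        assert np.array_equal(back.labels, ph.labels)
        assert back.hb == ph.hb
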