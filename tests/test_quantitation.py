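"""SUV, contrast recovery, partial-volume correction and the CRC analysis."""

import dataclasses

import numpy as np
import pytest

import qspect as q
from qspect.errors import (ArgumentError, ContrastRecoveryWarning, DataError,
                           GeometryError)
from qspect.quantitation import VOI, background_vois, measure_voi


def _uniform_image(value=5.0, shape=(20, 20, 20), spacing=4.8):
    origin = tuple(-(n - 1) / 2 * spacing for n in shape)
    return q.ActivityImage(np.full(shape, float(value)), (spacing,) * 3,
                           "kBq_per_cm3", origin)


class TestMeasureVOI:
    def test_uniform_image_any_voi(self):
        img = _uniform_image(7.5)
        st = measure_voi(img, VOI("v", (0.0, 0.0, 0.0), 25.0))
        assert st.mean == st.max == 7.5

    def test_single_hot_voxel_drives_the_max(self):
        img = _uniform_image(1.0)
        img.voxels[10, 10, 10] = 99.0
        st = measure_voi(img, VOI("v", (2.4, 2.4, 2.4), 30.0))
        assert st.max == 99.0 and st.mean < 99.0

    def test_membership_matches_brute_force_center_test(self):
        img = _uniform_image(1.0, shape=(24, 24, 24))
        center, diameter = (3.1, -2.7, 5.0), 30.0
        st = measure_voi(img, VOI("v", center, diameter))
        brute = 0
        for i in range(24):
            for j in range(24):
                for k in range(24):
                    p = [img.origin[a] + 4.8 * n
                         for a, n in zip(range(3), (i, j, k))]
                    d2 = sum((pc - cc) ** 2 for pc, cc in zip(p, center))
                    brute += d2 <= (diameter / 2) ** 2
        assert st.n_voxels == brute > 0

    def test_empty_and_out_of_bounds_vois_rejected(self):
        img = _uniform_image()
        with pytest.raises(GeometryError):
            measure_voi(img, VOI("far", (900.0, 0.0, 0.0), 20.0))
        with pytest.raises(GeometryError):
            measure_voi(img, VOI("tiny", (2.0, 2.0, 2.0), 0.5))

    def test_explicit_mask_voi(self):
        img = _uniform_image(2.0)
        mask = np.zeros(img.shape, dtype=bool)
        mask[0, 0, 0] = True
        st = measure_voi(img, VOI("m", mask=mask))
        assert st.n_voxels == 1 and st.mean == 2.0


class TestSUV:
    def test_unity_by_construction(self):
        assert q.compute_suv(2.0, injected_kbq=2000.0, weight_g=1000.0) == 1.0

    def test_zero_activity(self):
        assert q.compute_suv(0.0, 1000.0, 500.0) == 0.0

    def test_phantom_worked_value(self):
        # 35.4 kBq/cm3 with the phantom's 106.2 MBq and 16 kg
        suv = q.compute_suv(35.4, 106200.0, 16000.0)
        assert suv == pytest.approx(35.4 * 16000.0 / 106200.0, rel=1e-12)
        assert suv == pytest.approx(5.333, abs=5e-4)

    @pytest.mark.parametrize("injected,weight", [(0.0, 1.0), (1.0, -2.0)])
    def test_nonpositive_normalization_rejected(self, injected, weight):
        with pytest.raises(ArgumentError):
            q.compute_suv(1.0, injected, weight)

    def test_measure_suv_units_flag(self):
        img = _uniform_image(35.4)
        m = q.measure_suv(img, VOI("s", (0, 0, 0), 20.0), 106200.0, 16000.0)
        assert m.units == "g_per_cm3"
        t = q.measure_suv(img, VOI("s", (0, 0, 0), 20.0), 106200.0, 16000.0,
                          tissue=True)
        assert t.units == "unitless" and t.mean_suv == m.mean_suv


class TestCRC:
    def test_perfect_recovery(self):
        assert q.compute_crc(3.218, 1.0, 35.4, 11.0) == pytest.approx(1.0, abs=2e-4)

    def test_no_contrast_recovered(self):
        assert q.compute_crc(1.7, 1.7, 35.4, 11.0) == 0.0

    def test_half_recovered_ratio_worked_value(self):
        crc = q.compute_crc(2.0, 1.0, 35.4, 11.0)
        assert crc == pytest.approx((2.0 - 1.0) / (35.4 / 11.0 - 1.0), rel=1e-12)
        assert crc == pytest.approx(0.4509, abs=1e-4)

    def test_undefined_contrast_rejected(self):
        with pytest.raises(ArgumentError):
            q.compute_crc(1.0, 1.0, 11.0, 11.0)
        with pytest.raises(DataError):
            q.compute_crc(1.0, 0.0, 35.4, 11.0)


class TestRecoverActivity:
    def test_crc_one_inverts_the_suv_formula(self):
        suv = q.compute_suv(17.3, 106200.0, 16000.0)
        assert q.recover_activity(suv, 106200.0, 16000.0, 1.0) == pytest.approx(
            17.3, rel=1e-12)

    def test_simple_worked_value(self):
        assert q.recover_activity(2.0, 1000.0, 1000.0, 0.5) == pytest.approx(3.0)

    def test_largest_sphere_published_value(self):
        # SUV 4.9661 at A/w = 106200/16000 kBq/g with CRC 0.82 -> 38.9 kBq/cm3
        rec = q.recover_activity(4.9661, 106200.0, 16000.0, 0.82)
        assert rec == pytest.approx(38.9, abs=0.05)

    def test_crc_above_one_warns_but_passes_through(self):
        with pytest.warns(ContrastRecoveryWarning):
            rec = q.recover_activity(2.0, 1000.0, 1000.0, 1.2)
        assert rec == pytest.approx(1.6)

    def test_negative_crc_rejected(self):
        with pytest.raises(ArgumentError):
            q.recover_activity(1.0, 1.0, 1.0, -0.1)

    def test_monotone_decreasing_in_crc(self):
        recs = [q.recover_activity(2.0, 1000.0, 1000.0, c)
                for c in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b < a for a, b in zip(recs, recs[1:]))


class TestPercentError:
    @pytest.mark.parametrize("measured,actual,reported", [
        (33.5, 35.4, -5), (37.2, 35.4, 5), (38.5, 35.4, 9),
        (38.9, 35.4, 10), (11.7, 11.0, 6), (35.4, 35.4, 0),
    ])
    def test_phantom_accuracy_reporting(self, measured, actual, reported):
        assert q.report_percent(q.percent_error(measured, actual)) == reported

    def test_signed_values(self):
        assert q.percent_error(33.5, 35.4) == pytest.approx(-5.367, abs=5e-4)
        assert q.percent_error(11.7, 11.0) == pytest.approx(6.364, abs=5e-4)

    def test_half_rounds_away_from_zero(self):
        assert q.report_percent(15.5) == 16
        assert q.report_percent(-5.5) == -6

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(ArgumentError):
            q.percent_error(1.0, 0.0)


class TestBackgroundVOIs:
    def test_default_placement(self, nema_spec):
        vois = background_vois(nema_spec)
        assert len(vois) == 12
        a, b = nema_spec.body_semi_axes_mm
        for v in vois:
            x, y, _ = v.center_mm
            assert (x / (a - 25.0)) ** 2 + (y / (b - 25.0)) ** 2 <= 1.0 + 1e-9
            for s in nema_spec.spheres:
                import math
                assert math.dist((x, y, 0.0), s.center_mm) >= 25.0 + s.radius_mm - 1e-9

    def test_infeasible_clearance_raises(self, nema_spec):
        with pytest.raises(GeometryError):
            background_vois(nema_spec, clearance_mm=100.0)


class TestCRCAnalysis:
    def test_perfect_system_recovers_crc_of_one(self, nema_spec, nema_truth_nn,
                                                 ideal_profile):
        """No blur, no noise, voxel-center rasterization: CRC exactly 1 and
        zero recovery error for every sphere."""
        counts = q.simulate_acquisition(nema_truth_nn, ideal_profile)
        k = 1.0 / (ideal_profile.sensitivity_counts_per_kbq_s
                   * ideal_profile.acquisition_seconds)
        conc = counts.replace(counts.voxels * k / counts.voxel_volume_cm3,
                              units="kBq_per_cm3")
        analysis = q.crc_analysis(conc, nema_spec, 106200.0, 16000.0)
        assert not analysis.not_visible_mm
        assert len(analysis.spheres) == 6
        for r in analysis.spheres:
            assert r.crc == pytest.approx(1.0, abs=1e-9)
            assert r.recovered_kbq_cm3 == pytest.approx(35.4, rel=1e-9)
            assert q.report_percent(r.percent_error) == 0
        assert analysis.background.percent_error == pytest.approx(0.0, abs=1e-9)

    def test_truth_image_as_input_recovers_truth(self, nema_spec, nema_truth_nn):
        analysis = q.crc_analysis(nema_truth_nn, nema_spec, 106200.0, 16000.0)
        for r in analysis.spheres:
            assert r.crc == pytest.approx(1.0, abs=1e-9)
            assert r.recovered_kbq_cm3 == pytest.approx(35.4, rel=1e-9)

    def test_crc_scale_invariant_under_global_rescaling(self, symbia_quiet):
        spec1 = q.nema_iec_body_phantom()
        spec3 = q.nema_iec_body_phantom(sphere_kbq_cm3=3 * 35.4,
                                        background_kbq_cm3=3 * 11.0)
        crc = {}
        for tag, spec in (("x1", spec1), ("x3", spec3)):
            truth = q.build_ground_truth(spec)
            counts = q.simulate_acquisition(truth, symbia_quiet)
            k = 1.0 / (symbia_quiet.sensitivity_counts_per_kbq_s
                       * symbia_quiet.acquisition_seconds)
            conc = counts.replace(counts.voxels * k / counts.voxel_volume_cm3,
                                  units="kBq_per_cm3")
            analysis = q.crc_analysis(conc, spec, 106200.0, 16000.0)
            crc[tag] = [r.crc for r in analysis.spheres]
        assert crc["x1"] == pytest.approx(crc["x3"], rel=1e-9)

    def test_counts_image_rejected(self, nema_spec):
        img = q.ActivityImage(np.ones((40, 40, 40)), (4.8,) * 3, "counts")
        with pytest.raises(ArgumentError):
            q.crc_analysis(img, nema_spec, 106200.0, 16000.0)
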