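"""Pion corrections of %dd, TMR, OAR and RDF, difference curves, and the
50%-isodose field width."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pioncorr as pc
from pioncorr.scan_correction import NoCrossingError
from conftest import make_zero_slope_cal


def pdd_curve(signals, depths=None, energy="10FFF", geometry="SSD"):
    if depths is None:
        depths = np.arange(len(signals), dtype=float) * 2 + 1.0
    return pc.ScanCurve("depth", depths, signals, energy, 10.0, geometry)


class TestCorrectPdd:
    def test_reproduces_published_6fff_correction(self, cal_6fff):
        curve = pdd_curve([100.0, 80.0, 63.4], depths=[1.5, 5.0, 10.0], energy="6FFF")
        cor, unc = pc.correct_pdd(curve, cal_6fff)
        assert unc.values[-1] == pytest.approx(63.4)
        assert round(float(cor.values[-1]), 1) == 63.2

    def test_10fff_correction_close_to_published(self, cal_10fff):
        # rounded published fit parameters land at 70.43 vs the printed 70.5
        curve = pdd_curve([100.0, 82.0, 70.8], depths=[1.5, 5.0, 10.0])
        cor, _ = pc.correct_pdd(curve, cal_10fff)
        assert float(cor.values[-1]) == pytest.approx(70.4282, abs=5e-4)
        assert abs(cor.values[-1] - 70.5) / 70.5 < 0.0015

    def test_zero_slope_calibration_is_identity(self, zero_cal):
        curve = pdd_curve([100.0, 80.0, 60.0, 40.0])
        cor, unc = pc.correct_pdd(curve, zero_cal(intercept=1.003))
        np.testing.assert_allclose(cor.values, unc.values, atol=1e-12)

    def test_correction_lowers_pdd_beyond_dmax(self, cal_10fff, depth_grid):
        curve, _ = pc.generate_pdd(pc.BEAM_10FFF, cal_10fff, depth_grid)
        cor, unc = pc.correct_pdd(curve, cal_10fff)
        beyond = depth_grid > depth_grid[np.argmax(curve.signals)]
        assert np.all(cor.values[beyond] <= unc.values[beyond] + 1e-12)

    def test_input_validation(self, cal_10fff):
        with pytest.raises(ValueError, match="energy"):
            pc.correct_pdd(pdd_curve([100, 50], energy="6FFF"), cal_10fff)
        with pytest.raises(ValueError, match="SSD"):
            pc.correct_pdd(pdd_curve([100, 50], geometry="SAD"), cal_10fff)
        with pytest.raises(ValueError):
            pc.correct_pdd(pdd_curve([0.0, 0.0]), cal_10fff)


class TestCorrectTmr:
    def test_worked_signal_magnitudes(self, cal_10fff):
        curve = pdd_curve(
            [100.0, 70.8, 57.2], depths=[1.6, 10.0, 20.0], geometry="SAD"
        )
        cor, unc = pc.correct_tmr(curve, cal_10fff)
        assert unc.values[-1] == pytest.approx(0.572)
        # frozen from direct evaluation of 0.572 * P(57.2)/P(100)
        assert float(cor.values[-1]) == pytest.approx(0.5675969210810811, abs=1e-12)

    def test_self_ratio_is_one_and_zero_slope_identity(self, cal_10fff, zero_cal):
        curve = pdd_curve([100.0, 60.0], depths=[1.6, 20.0], geometry="SAD")
        cor, unc = pc.correct_tmr(curve, cal_10fff)
        assert cor.values[0] == 1.0 and unc.values[0] == 1.0
        cor0, unc0 = pc.correct_tmr(curve, zero_cal())
        np.testing.assert_allclose(cor0.values, unc0.values, atol=1e-15)

    def test_requires_sad_geometry(self, cal_10fff):
        with pytest.raises(ValueError, match="isocenter"):
            pc.correct_tmr(pdd_curve([100, 50], geometry="SSD"), cal_10fff)


class TestCorrectOar:
    def test_flat_profile_stays_flat(self, cal_10fff):
        xs = np.linspace(-5, 5, 21)
        prof = pc.ScanCurve(
            "crossplane", xs, np.full_like(xs, 80.0), "10FFF", 10.0, depth_cm=1.6
        )
        cor, unc = pc.correct_oar(prof, cal_10fff)
        np.testing.assert_allclose(cor.values, 100.0, atol=1e-12)
        np.testing.assert_allclose(unc.values, 100.0, atol=1e-12)

    def test_correction_reduces_off_axis_values(self, cal_10fff, crossplane_grid):
        prof, _ = pc.generate_profile(
            pc.BEAM_10FFF, cal_10fff, 4.0, pc.BEAM_10FFF.dmax, crossplane_grid
        )
        cor, unc = pc.correct_oar(prof, cal_10fff)
        below = prof.signals < np.interp(0.0, prof.positions, prof.signals)
        assert np.all(cor.values[below] <= unc.values[below] + 1e-12)

    def test_difference_magnitude_decreases_with_depth(self, cal_10fff, crossplane_grid):
        maxima = []
        for depth in (pc.BEAM_10FFF.dmax, 35.0):
            prof, _ = pc.generate_profile(
                pc.BEAM_10FFF, cal_10fff, 4.0, depth, crossplane_grid
            )
            diff = pc.difference_curves(*pc.correct_oar(prof, cal_10fff))
            maxima.append(np.nanmax(np.abs(diff.delta_abs)))
        assert maxima[0] >= maxima[1]

    def test_cax_must_be_spanned(self, cal_10fff):
        xs = np.linspace(1.0, 5.0, 9)
        prof = pc.ScanCurve(
            "crossplane", xs, np.linspace(80, 10, 9), "10FFF", 10.0, depth_cm=1.6
        )
        with pytest.raises(ValueError, match="central axis"):
            pc.correct_oar(prof, cal_10fff)


class TestCorrectRdf:
    def test_equal_signals_give_unit_rdf(self, cal_10fff):
        cor, unc = pc.correct_rdf([(4.0, 100.0), (10.0, 100.0)], cal_10fff)
        assert cor.values == pytest.approx([1.0, 1.0])
        assert unc.values == pytest.approx([1.0, 1.0])

    def test_correction_magnitude_near_reference_signal(self, cal_10fff):
        readings = [(4, 90.0), (6, 95.0), (10, 100.0), (15, 105.0), (20, 110.0)]
        cor, unc = pc.correct_rdf(readings, cal_10fff)
        dmax = np.max(np.abs(cor.values - unc.values))
        assert 1e-4 < dmax < 1e-2  # order 1e-3 for signals within +-10 of 100

    def test_zero_slope_identity_and_missing_reference(self, cal_10fff, zero_cal):
        readings = [(4, 90.0), (10, 100.0)]
        cor, unc = pc.correct_rdf(readings, zero_cal())
        np.testing.assert_allclose(cor.values, unc.values, atol=1e-15)
        with pytest.raises(ValueError, match="reference"):
            pc.correct_rdf([(4, 90.0), (6, 95.0)], cal_10fff)


class TestDifferenceCurves:
    def test_identical_curves_give_zero(self):
        f = pc.DoseFunctionCurve([1.0, 2.0], [100.0, 60.0], "pdd", True)
        diff = pc.difference_curves(f, f)
        assert np.all(diff.delta_abs == 0) and np.all(diff.delta_rel == 0)

    def test_published_pdd10_pair(self):
        cor = pc.DoseFunctionCurve([1.5, 10.0], [100.0, 63.2], "pdd", True)
        unc = pc.DoseFunctionCurve([1.5, 10.0], [100.0, 63.4], "pdd", False)
        diff = pc.difference_curves(cor, unc)
        assert diff.delta_abs[-1] == pytest.approx(-0.2)
        assert diff.delta_rel[-1] == pytest.approx(100 * (-0.2) / 63.2)

    def test_synthetic_pdd_difference_structure(self, cal_10fff, depth_grid):
        curve, _ = pc.generate_pdd(pc.BEAM_10FFF, cal_10fff, depth_grid)
        diff = pc.difference_curves(*pc.correct_pdd(curve, cal_10fff))
        i_dmax = int(np.argmax(curve.signals))
        assert diff.delta_abs[i_dmax] == 0.0
        i_extremum = int(np.argmax(np.abs(diff.delta_abs)))
        assert 0 < i_extremum < depth_grid.size - 1  # interior extremum
        beyond = diff.delta_rel[i_dmax:]
        assert np.all(np.diff(np.abs(beyond)) >= -1e-9)  # |rel| grows with depth

    def test_mismatched_inputs_rejected(self):
        a = pc.DoseFunctionCurve([1.0, 2.0], [100.0, 60.0], "pdd", True)
        b = pc.DoseFunctionCurve([1.0, 3.0], [100.0, 60.0], "pdd", False)
        c = pc.DoseFunctionCurve([1.0, 2.0], [1.0, 0.6], "tmr", False)
        with pytest.raises(ValueError):
            pc.difference_curves(a, b)
        with pytest.raises(ValueError):
            pc.difference_curves(a, c)


def trapezoid_profile(shift=0.0, scale=1.0):
    xs = np.linspace(-4, 4, 161) + shift
    v = np.clip((3.0 - np.abs(xs - shift)) / 1.0, 0.0, 1.0) * 100.0 * scale
    return pc.DoseFunctionCurve(xs, v, "oar", False)


class TestFieldWidth:
    def test_trapezoid_analytic_crossings(self):
        fw = pc.field_width_50(trapezoid_profile())
        assert fw.left == pytest.approx(-2.5, abs=1e-9)
        assert fw.right == pytest.approx(2.5, abs=1e-9)
        assert fw.width == pytest.approx(5.0, abs=1e-9)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(shift=st.floats(-0.45, 0.45))
    def test_translation_invariance(self, shift):
        base = pc.field_width_50(trapezoid_profile())
        moved = pc.field_width_50(trapezoid_profile(shift=shift))
        assert moved.left == pytest.approx(base.left + shift, abs=1e-9)
        assert moved.right == pytest.approx(base.right + shift, abs=1e-9)
        assert moved.width == pytest.approx(base.width, abs=1e-9)

    def test_matches_fine_grid_brute_force_oracle(self, cal_10fff):
        from scipy.special import erfc

        edge, sigma = 2.05, 0.3
        f = lambda x: 100.0 * 0.5 * erfc((np.abs(x) - edge) / (np.sqrt(2) * sigma))
        coarse_step = 0.1
        xs = np.arange(-4.0, 4.0 + 1e-9, coarse_step)
        fw = pc.field_width_50(pc.DoseFunctionCurve(xs, f(xs), "oar", False))
        fine = np.arange(-4.0, 4.0 + 1e-12, coarse_step / 1000.0)
        vals = f(fine)
        right_idx = np.nonzero((fine > 0) & (vals < 50.0))[0][0]
        left_idx = np.nonzero((fine < 0) & (vals >= 50.0))[0][0]
        assert abs(fw.right - fine[right_idx]) <= coarse_step / 1000.0
        assert abs(fw.left - fine[left_idx]) <= coarse_step / 1000.0

    def test_no_crossing_raises(self):
        xs = np.linspace(-3, 3, 13)
        prof = pc.DoseFunctionCurve(xs, np.full_like(xs, 100.0), "oar", False)
        with pytest.raises(NoCrossingError):
            pc.field_width_50(prof)


class TestWidthDelta:
    def test_zero_slope_gives_zero_delta(self, crossplane_grid, zero_cal):
        cal = make_zero_slope_cal("10FFF")
        prof, _ = pc.generate_profile(
            pc.BEAM_10FFF, cal, 4.0, pc.BEAM_10FFF.dmax, crossplane_grid
        )
        wr = pc.width_delta(prof, zero_cal())
        assert wr.delta_w == pytest.approx(0.0, abs=1e-12)

    def test_correction_narrows_field_slightly(self, cal_10fff, crossplane_grid):
        prof, _ = pc.generate_profile(
            pc.BEAM_10FFF, cal_10fff, 4.0, pc.BEAM_10FFF.dmax, crossplane_grid
        )
        wr = pc.width_delta(prof, cal_10fff)
        assert wr.delta_w < 0
        assert abs(wr.delta_w) < 0.02  # cm

    def test_narrowing_shrinks_with_depth(self, cal_10fff, crossplane_grid):
        deltas = []
        for depth in (pc.BEAM_10FFF.dmax, 35.0):
            prof, _ = pc.generate_profile(
                pc.BEAM_10FFF, cal_10fff, 4.0, depth, crossplane_grid
            )
            deltas.append(abs(pc.width_delta(prof, cal_10fff).delta_w))
        assert deltas[1] <= deltas[0]
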