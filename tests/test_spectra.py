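import numpy as np
import pytest
from hypothesis import given, strategies as st

from phycolight import (
    Band, Spectrum, baseline_zero, decompose, default_grid,
    default_palmaria_profile, find_red_peak, find_reflectance_dip,
    gaussian_band, make_palmaria_spectra, psi_difference, psii_fraction_at_red,
    scale_to_pe_peaks, spectral_shift,
)
from phycolight.spectra import peak_in_window, smooth


class TestBaselineZero:
    def test_constant_spectrum_becomes_zero(self, grid):
        s = Spectrum(grid, np.full(grid.size, 0.2), "absorbance")
        out = baseline_zero(s)
        assert np.all(out.values == 0)

    def test_shifts_by_reference_value(self, grid):
        s = Spectrum(grid, np.linspace(0.5, 0.05, grid.size), "absorbance")
        out = baseline_zero(s)
        assert out.value_at(800.0) == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(out.values, s.values - s.value_at(800.0))

    def test_idempotent(self, grid):
        s = Spectrum(grid, np.linspace(0.5, 0.05, grid.size), "absorbance")
        once = baseline_zero(s)
        twice = baseline_zero(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_reference_outside_grid_errors(self, grid):
        s = Spectrum(grid, np.ones(grid.size), "absorbance")
        with pytest.raises(ValueError, match="outside grid"):
            baseline_zero(s, ref=900.0)


class TestScaleToPePeaks:
    def test_proportional_spectra(self, palmaria):
        total = palmaria.total
        half = total.with_values(total.values * 0.5)
        res = scale_to_pe_peaks(total, half)
        assert res.scale_factor == pytest.approx(2.0)
        assert res.pe_mismatch_545 == pytest.approx(0.0, abs=1e-12)

    def test_known_dilution_recovered(self, palmaria):
        res = scale_to_pe_peaks(palmaria.total, palmaria.extract)
        # PS I Soret tail at 495 nm perturbs the factor by < 0.5%
        assert res.scale_factor == pytest.approx(1.0 / palmaria.truth["dilution"],
                                                 rel=5e-3)

    def test_zero_extract_at_anchor_errors(self, grid):
        total = gaussian_band(Band(495, 30, 1.0), grid)
        empty = Spectrum(grid, np.zeros(grid.size), "absorbance")
        with pytest.raises(ValueError, match="495"):
            scale_to_pe_peaks(total, empty)

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance_of_output(self, c):
        grid = default_grid()
        fx = make_palmaria_spectra(default_palmaria_profile(0.4), grid, dilution=1.0)
        base = scale_to_pe_peaks(fx.total, fx.extract)
        rescaled = scale_to_pe_peaks(fx.total, fx.extract.with_values(fx.extract.values * c))
        np.testing.assert_allclose(rescaled.scaled.values, base.scaled.values,
                                   rtol=1e-9, atol=1e-12)

    def test_lsq_method_close_to_primary_on_clean_fixture(self, palmaria):
        primary = scale_to_pe_peaks(palmaria.total, palmaria.extract, method="primary")
        lsq = scale_to_pe_peaks(palmaria.total, palmaria.extract, method="lsq")
        assert lsq.scale_factor == pytest.approx(primary.scale_factor, rel=0.01)


class TestPsiDifference:
    def test_identical_spectra_give_zero(self, palmaria):
        d = psi_difference(palmaria.total, palmaria.total)
        assert np.all(d.values == 0)

    def test_difference_peaks_at_psi_band(self, palmaria):
        d = psi_difference(palmaria.total, palmaria.aPSII_true)
        assert find_red_peak(d) == pytest.approx(681.0, abs=0.1)

    def test_additivity_reconstruction(self, palmaria):
        d = psi_difference(palmaria.total, palmaria.aPSII_true)
        np.testing.assert_allclose(d.values + palmaria.aPSII_true.values,
                                   palmaria.total.values, rtol=0,
                                   atol=4 * np.finfo(float).eps)

    def test_grid_mismatch_errors(self, palmaria):
        other = Spectrum(default_grid(400, 799), np.zeros(400), "absorbance")
        with pytest.raises(ValueError, match="common"):
            psi_difference(palmaria.total, other)


class TestFindRedPeak:
    def test_single_gaussian_on_grid(self, grid):
        s = gaussian_band(Band(676, 24, 1.0), grid)
        assert find_red_peak(s) == pytest.approx(676.0, abs=0.1)

    def test_two_band_mixture_peak(self, grid):
        s = Spectrum(grid, Band(676, 24, 0.4)(grid) + Band(681, 24, 0.6)(grid),
                     "absorbance")
        # oracle: 0.01 nm brute-force argmax of the analytic sum
        fine = np.arange(660, 695, 0.01)
        oracle = fine[np.argmax(Band(676, 24, 0.4)(fine) + Band(681, 24, 0.6)(fine))]
        assert oracle == pytest.approx(679.0, abs=0.5)
        assert find_red_peak(s) == pytest.approx(oracle, abs=0.5)

    def test_flat_spectrum_errors(self, grid):
        s = Spectrum(grid, np.ones(grid.size), "absorbance")
        with pytest.raises(ValueError, match="no peak"):
            find_red_peak(s)

    def test_monotone_spectrum_errors(self, grid):
        s = Spectrum(grid, np.linspace(0, 1, grid.size), "absorbance")
        with pytest.raises(ValueError, match="no peak"):
            find_red_peak(s)

    @pytest.mark.parametrize("fwhm", [10.0, 24.0, 40.0])
    @pytest.mark.parametrize("center", [663.4, 676.0, 681.7])
    def test_detector_matches_oversampled_argmax(self, grid, fwhm, center):
        s = gaussian_band(Band(center, fwhm, 1.0), grid)
        fine = np.arange(640, 700, 0.01)
        oracle = fine[np.argmax(Band(center, fwhm, 1.0)(fine))]
        assert find_red_peak(s) == pytest.approx(oracle, abs=0.1)


class TestReflectanceDip:
    def test_symmetric_dip(self, grid):
        values = 1.0 - 0.5 * Band(664, 30, 1.0)(grid)
        s = Spectrum(grid, values, "reflectance")
        assert find_reflectance_dip(s) == pytest.approx(664.0, abs=0.1)

    def test_monotone_reflectance_errors(self, grid):
        s = Spectrum(grid, np.linspace(1, 0.2, grid.size), "reflectance")
        with pytest.raises(ValueError, match="no peak"):
            find_reflectance_dip(s)

    def test_dip_on_grid_point(self, grid):
        values = 1.0 - 0.4 * Band(651, 20, 1.0)(grid)
        s = Spectrum(grid, values, "reflectance")
        assert find_reflectance_dip(s) == pytest.approx(651.0, abs=1e-6)

    def test_wrong_kind_errors(self, grid):
        s = Spectrum(grid, np.ones(grid.size), "absorbance")
        with pytest.raises(ValueError, match="reflectance"):
            find_reflectance_dip(s)


class TestPsiiFraction:
    def test_default_fixture_recovers_40_percent(self, palmaria):
        res = decompose(palmaria.total, palmaria.extract)
        assert res.psii_fraction == pytest.approx(0.40, abs=0.02)

    def test_identical_spectra_give_one(self, palmaria):
        assert psii_fraction_at_red(palmaria.total, palmaria.total) == pytest.approx(1.0)

    @pytest.mark.parametrize("f", [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    @pytest.mark.parametrize("dilution", [0.1, 1.0, 10.0])
    def test_truth_sweep(self, f, dilution):
        fx = make_palmaria_spectra(default_palmaria_profile(f), dilution=dilution)
        res = decompose(fx.total, fx.extract)
        assert res.psii_fraction == pytest.approx(f, abs=0.02)

    def test_inconsistent_fraction_flagged(self, palmaria):
        inflated = palmaria.total.with_values(palmaria.total.values * 1.2)
        with pytest.warns(UserWarning, match="exceeds 1"):
            out = psii_fraction_at_red(palmaria.total, inflated)
        assert out <= 1.05


class TestShiftsAndDecomposition:
    def test_spectral_shift_examples(self):
        assert spectral_shift(681, 676) == 5
        assert spectral_shift(679, 676) == 3
        assert spectral_shift(676.5, 676.5) == 0

    @given(st.floats(-100, 100), st.floats(-100, 100))
    def test_shift_antisymmetry(self, a, b):
        assert spectral_shift(a, b) == -spectral_shift(b, a)

    def test_decomposition_additivity_exact(self, palmaria):
        # machine precision: a + (b - a) reconstructs b to within one ulp
        res = decompose(palmaria.total, palmaria.extract)
        total0 = baseline_zero(palmaria.total)
        np.testing.assert_allclose(res.aPSII_scaled.values + res.psI_diff.values,
                                   total0.values, rtol=0,
                                   atol=4 * np.finfo(float).eps)

    def test_decomposition_peaks_and_shifts(self, palmaria):
        res = decompose(palmaria.total, palmaria.extract)
        assert res.peak_total == pytest.approx(679.0, abs=0.5)
        assert res.peak_psii == pytest.approx(676.0, abs=0.5)
        assert res.peak_psi == pytest.approx(681.0, abs=0.5)
        assert res.shift_psi_vs_psii == pytest.approx(5.0, abs=0.5)
        assert res.shift_total_vs_psii == pytest.approx(3.0, abs=0.5)

    def test_negative_lobes_reported_not_clipped(self, palmaria):
        # over-scaled extract forces negative difference values
        inflated = palmaria.extract.with_values(palmaria.extract.values * 10)
        d = psi_difference(palmaria.total, inflated)
        assert d.values.min() < 0

    def test_smoother_preserves_clean_peak(self, palmaria):
        sm = smooth(palmaria.total)
        assert find_red_peak(sm) == pytest.approx(find_red_peak(palmaria.total),
                                                  abs=0.2)

    def test_peak_window_validation(self, palmaria):
        with pytest.raises(ValueError, match="window"):
            peak_in_window(palmaria.total, (700.0, 640.0))
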