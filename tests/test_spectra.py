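"""Spectrum synthesis and analysis-statistic closed forms vs scan oracles."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from tgaspec.constants import HARTREE_PER_INV_CM, INV_CM_PER_HARTREE
from tgaspec.spectra import (
    Autocorrelation,
    PeakTable,
    SpectrumResult,
    correlation_to_spectrum,
    envelope_width,
    find_peaks,
    fit_spectral_shift,
    mean_peak_spacing,
    mime_wavenumber,
    peak_spacing_shifts,
)


def single_line_correlation(omega0_au, dt=8.0, n=4000):
    t = dt * np.arange(n)
    return Autocorrelation(t, np.exp(-1j * omega0_au * t))


def poisson_sticks(s, omega_cm1, n_max=8, origin_cm1=40000.0):
    import math

    n = np.arange(n_max + 1)
    weights = np.exp(-s) * s**n / np.array([math.factorial(int(k)) for k in n])
    return PeakTable(origin_cm1 + omega_cm1 * n, weights)


class TestCorrelationToSpectrum:
    def test_single_line_position(self):
        omega0 = 0.02  # hartree
        spec = correlation_to_spectrum(single_line_correlation(omega0), None)
        peaks = find_peaks(spec, 0.5)
        grid = spec.wavenumbers[1] - spec.wavenumbers[0]
        assert len(peaks) == 1
        assert abs(peaks.positions[0] - omega0 * INV_CM_PER_HARTREE) < grid

    def test_lorentzian_hwhm_recovered(self):
        """Nonlinear fit of a damped line recovers the configured HWHM."""
        omega0, hwhm = 0.02, 100.0
        corr = single_line_correlation(omega0, dt=8.0, n=60000)
        spec = correlation_to_spectrum(corr, hwhm_cm1=hwhm)
        center = omega0 * INV_CM_PER_HARTREE
        sel = np.abs(spec.wavenumbers - center) < 12 * hwhm

        def lorentz(x, x0, gamma, amp):
            return amp * gamma**2 / ((x - x0) ** 2 + gamma**2)

        popt, _ = curve_fit(
            lorentz, spec.wavenumbers[sel], spec.intensities[sel],
            p0=[center, 0.8 * hwhm, 1.0],
        )
        assert popt[1] == pytest.approx(hwhm, rel=0.02)

    def test_hwhm_must_be_positive(self):
        with pytest.raises(ValueError):
            correlation_to_spectrum(single_line_correlation(0.02), hwhm_cm1=-5.0)

    def test_shift_moves_axis(self):
        corr = single_line_correlation(0.02)
        s0 = correlation_to_spectrum(corr, 50.0)
        s1 = correlation_to_spectrum(corr, 50.0, shift_cm1=200.0)
        p0 = find_peaks(s0, 0.5).positions[0]
        p1 = find_peaks(s1, 0.5).positions[0]
        assert p1 - p0 == pytest.approx(200.0, abs=1e-9)


class TestFindPeaks:
    def test_two_equal_lines(self):
        t = 8.0 * np.arange(6000)
        c = 0.5 * (np.exp(-1j * 0.02 * t) + np.exp(-1j * 0.03 * t))
        spec = correlation_to_spectrum(Autocorrelation(t, c), 80.0)
        peaks = find_peaks(spec, 0.2)
        assert len(peaks) == 2
        assert peaks.intensities[0] == pytest.approx(peaks.intensities[1], abs=1e-6)

    def test_poisson_progression_spacing(self):
        """Eight resolvable lines spaced by omega are all recovered."""
        import math

        omega, s, carrier = 0.005, 1.0, 0.01
        t = 8.0 * np.arange(20000)
        n = np.arange(12)
        fc = np.exp(-s) * s**n / np.array([math.factorial(int(k)) for k in n])
        c = np.sum(fc[None, :] * np.exp(-1j * np.outer(t, carrier + omega * n)), axis=1)
        spec = correlation_to_spectrum(Autocorrelation(t, c), 30.0)
        peaks = find_peaks(spec, 1.5e-4)  # n = 0..7 clear this threshold
        assert len(peaks) == 8
        spacing = np.diff(peaks.positions)
        np.testing.assert_allclose(spacing, omega * INV_CM_PER_HARTREE, rtol=0.01)


class TestEnvelopeWidth:
    def test_single_peak_zero(self):
        assert envelope_width(PeakTable([500.0], [1.0])) == 0.0

    def test_two_equal_peaks(self):
        assert envelope_width(PeakTable([900.0, 1100.0], [0.7, 0.7])) == pytest.approx(200.0)

    def test_poisson_closed_form(self):
        """Poisson progression: width = 2 omega sqrt(S)."""
        s, omega = 2.5, 930.0
        peaks = poisson_sticks(s, omega, n_max=60)
        assert envelope_width(peaks) == pytest.approx(2 * omega * np.sqrt(s), rel=1e-6)

    def test_invariances(self):
        peaks = poisson_sticks(1.7, 800.0, n_max=40)
        w = envelope_width(peaks)
        shifted = PeakTable(peaks.positions + 12345.6, peaks.intensities)
        scaled = PeakTable(peaks.positions, 7.5 * peaks.intensities)
        assert envelope_width(shifted) == pytest.approx(w, rel=1e-12)
        assert envelope_width(scaled) == pytest.approx(w, rel=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            envelope_width(PeakTable([], []))


class TestPeakSpacingShifts:
    def test_identical_spectra(self):
        peaks = poisson_sticks(1.0, 900.0)
        series = peak_spacing_shifts(peaks, peaks)
        np.testing.assert_array_equal(series.delta, 0.0)

    def test_linear_in_index_for_two_progressions(self):
        """Progressions with spacings w and w/sqrt(2) sharing the 0-0 line."""
        omega = 930.0
        a = PeakTable(46000 + omega * np.arange(6), np.ones(6))
        b = PeakTable(46000 + omega / np.sqrt(2) * np.arange(6), np.ones(6))
        series = peak_spacing_shifts(a, b)
        expected = np.arange(6) * omega * (1 - 1 / np.sqrt(2))
        np.testing.assert_allclose(series.delta, expected, atol=1e-10)

    def test_antisymmetric_under_swap(self):
        a = poisson_sticks(1.0, 900.0)
        b = poisson_sticks(1.0, 800.0)
        ab = peak_spacing_shifts(a, b)
        ba = peak_spacing_shifts(b, a)
        np.testing.assert_allclose(ab.delta, -ba.delta, atol=1e-12)

    def test_truncation_flagged(self):
        a = poisson_sticks(1.0, 900.0, n_max=6)
        b = poisson_sticks(1.0, 800.0, n_max=4)
        series = peak_spacing_shifts(a, b)
        assert series.truncated
        assert series.delta.size == 5


class TestMime:
    def test_single_mode(self):
        res = mime_wavenumber([930.0], [0.5])
        assert res.omega_m == pytest.approx(930.0, rel=1e-12)
        assert res.integers.tolist() == [1]

    def test_commensurate_two_to_one(self):
        res = mime_wavenumber([930.0, 1860.0], [0.6, 0.2])
        assert res.omega_m == pytest.approx(930.0, rel=1e-12)
        assert res.integers.tolist() == [1, 2]

    def test_single_dominant_mode_sets_frequency(self):
        """|dq| ratio > 10: the MIME frequency is the dominant mode's."""
        res = mime_wavenumber([800.0, 1290.0, 2070.0], [1.0, 0.05, 0.03])
        assert res.omega_m == pytest.approx(800.0, rel=0.02)

    def test_matches_grid_scan_oracle(self, rng):
        """Self-consistent minimizer agrees with a dense scan over t_M."""
        for _ in range(5):
            omegas = rng.uniform(500, 2500, 3)
            dq = rng.uniform(0.1, 1.0, 3)
            res = mime_wavenumber(omegas, dq)
            w = dq**2
            dominant = np.argmax(w)
            t_grid = np.linspace(
                0.5 * 2 * np.pi / omegas[dominant],
                1.5 * 2 * np.pi / omegas[dominant],
                200001,
            )
            n = np.round(np.outer(t_grid, omegas) / (2 * np.pi))
            f = np.sum(w * (np.outer(t_grid, omegas) - 2 * np.pi * n) ** 2, axis=1)
            t_best = t_grid[np.argmin(f)]
            # refine the scan winner with the closed-form minimizer
            n_best = np.round(omegas * t_best / (2 * np.pi))
            t_best = 2 * np.pi * np.sum(w * omegas * n_best) / np.sum(w * omegas**2)
            assert res.t_m == pytest.approx(t_best, rel=1e-6)

    def test_zero_displacements_rejected(self):
        with pytest.raises(ValueError):
            mime_wavenumber([930.0, 1860.0], [0.0, 0.0])


class TestFitSpectralShift:
    def test_pure_offset(self):
        peaks = poisson_sticks(1.0, 900.0)
        ref = PeakTable(peaks.positions + 200.0, peaks.intensities)
        shift, mae = fit_spectral_shift(peaks, ref)
        assert shift == pytest.approx(200.0, abs=1e-10)
        assert mae == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_perturbation_mae(self):
        peaks = poisson_sticks(1.0, 900.0, n_max=3)
        delta = 25.0
        ref = PeakTable(
            peaks.positions + np.array([delta, -delta, delta, -delta]),
            peaks.intensities,
        )
        shift, mae = fit_spectral_shift(peaks, ref)
        assert mae == pytest.approx(delta, abs=1e-10)

    def test_beats_dense_scan(self, rng):
        peaks = poisson_sticks(1.0, 900.0, n_max=6)
        ref = PeakTable(peaks.positions + 150.0 + rng.normal(0, 30, 7), peaks.intensities)
        shift, mae = fit_spectral_shift(peaks, ref)
        scan = np.linspace(0, 300, 30001)
        diffs = ref.positions - peaks.positions
        scan_mae = np.abs(diffs[None, :] - scan[:, None]).mean(axis=1)
        assert mae <= scan_mae.min() + 1e-9

    def test_no_peaks_rejected(self):
        with pytest.raises(ValueError):
            fit_spectral_shift(PeakTable([], []), PeakTable([], []))


class TestIO:
    def test_autocorrelation_uniform_grid_required(self):
        with pytest.raises(ValueError):
            Autocorrelation([0.0, 1.0, 3.0], [1.0, 0.5, 0.2])

    def test_autocorrelation_txt_roundtrip(self, tmp_path):
        corr = single_line_correlation(0.02, n=50)
        corr.save_txt(tmp_path / "corr.txt")
        loaded = Autocorrelation.load_txt(tmp_path / "corr.txt")
        np.testing.assert_allclose(loaded.values, corr.values, atol=1e-12)

    def test_spectrum_json_roundtrip(self, tmp_path):
        spec = correlation_to_spectrum(single_line_correlation(0.02), 50.0)
        spec.to_json(tmp_path / "spec.json", 0.5)
        loaded = SpectrumResult.from_json(tmp_path / "spec.json")
        np.testing.assert_allclose(loaded.intensities, spec.intensities, atol=1e-12)
        assert loaded.peaks is not None and len(loaded.peaks) == 1

    def test_mean_peak_spacing_requires_two(self):
        with pytest.raises(ValueError):
            mean_peak_spacing(PeakTable([500.0], [1.0]))
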