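"""Preprocessing tests: reference-fit recovery, outlier rejection,
frequency/phase correction and condition averaging."""

import numpy as np
import pytest

from mrsdyn import (
    GroundTruth,
    VC_PROFILE,
    apply_freq_phase_correction,
    average_and_difference,
    fit_reference_peak,
    frequency_drift,
    reject_outlier_transients,
    simulate_cohort,
    synthesize_transient,
)
from mrsdyn.preprocess import fit_reference_peaks, preprocess_cohort


class TestReferenceFit:
    def test_noiseless_cr_recovery(self, amplitudes):
        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF")
        fit = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        assert fit.ok
        assert fit.freq_ppm == pytest.approx(3.000, abs=1e-3)
        assert fit.fwhm_hz == pytest.approx(8.5, abs=0.05)

    def test_shifted_peak_center(self, amplitudes):
        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF", freq_offset_ppm=0.02)
        fit = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        assert fit.freq_ppm == pytest.approx(3.020, abs=1e-3)

    def test_applied_phase_is_recovered(self, amplitudes):
        # isolated Cr: exact inverse of the applied rotation
        t = synthesize_transient(VC_PROFILE, {"tcr": 1.0}, "OFF", phase_deg=30.0)
        fit = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        assert fit.phase_deg == pytest.approx(30.0, abs=0.01)
        # full spectrum: the tNAA dispersion tail biases the estimate by ~1 deg
        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF", phase_deg=30.0)
        fit = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        assert fit.phase_deg == pytest.approx(30.0, abs=1.5)

    def test_scale_equivariance(self, amplitudes, rng):
        t = synthesize_transient(
            VC_PROFILE, amplitudes, "OFF", noise_sd=0.02, rng=rng
        )
        f1 = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        t.spectrum = t.spectrum * 3.0
        f2 = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        assert f2.area == pytest.approx(3.0 * f1.area, rel=1e-4)
        assert f2.freq_ppm == pytest.approx(f1.freq_ppm, abs=1e-6)
        assert f2.fwhm_hz == pytest.approx(f1.fwhm_hz, rel=1e-5)
        assert f2.phase_deg == pytest.approx(f1.phase_deg, abs=1e-3)


class TestOutlierRejection:
    @staticmethod
    def _fits(freq, phase=None, area=None, fwhm=None, ok=None):
        n = len(freq)
        return {
            "freq_ppm": np.asarray(freq, dtype=float),
            "phase_deg": np.zeros(n) if phase is None else np.asarray(phase),
            "area": np.ones(n) if area is None else np.asarray(area),
            "fwhm_hz": np.full(n, 8.5) if fwhm is None else np.asarray(fwhm),
            "ok": np.ones(n, dtype=bool) if ok is None else np.asarray(ok),
        }

    def test_identical_fits_all_retained(self):
        fits = self._fits(np.full(20, 3.0))
        assert reject_outlier_transients(fits).all()

    def test_single_gross_outlier_dropped(self, rng):
        freq = 3.0 + 0.001 * rng.standard_normal(100)
        freq[17] += 0.010 * 10  # 10 SDs out
        mask = reject_outlier_transients(self._fits(freq))
        assert not mask[17]
        assert mask.sum() == 99

    def test_failed_fits_always_dropped(self):
        ok = np.ones(10, dtype=bool)
        ok[3] = False
        mask = reject_outlier_transients(self._fits(np.full(10, 3.0), ok=ok))
        assert not mask[3] and mask.sum() == 9

    def test_retention_fraction_matches_brute_force(self, rng):
        """Gaussian parameters: retention fraction equals a direct
        brute-force evaluation of P(all four |z| <= 3)."""
        n = 10000
        fits = self._fits(
            rng.standard_normal(n),
            phase=rng.standard_normal(n),
            area=10 + rng.standard_normal(n),
            fwhm=8.5 + rng.standard_normal(n),
        )
        mask = reject_outlier_transients(fits, k=3.0)
        # independent oracle: z-scores computed directly
        keep = np.ones(n, dtype=bool)
        for key in ("freq_ppm", "phase_deg", "area", "fwhm_hz"):
            v = fits[key]
            keep &= np.abs(v - v.mean()) <= 3.0 * v.std(ddof=1)
        assert mask.sum() == keep.sum()
        assert np.array_equal(mask, keep)

    def test_mask_monotone_in_threshold(self, rng):
        fits = self._fits(
            rng.standard_normal(50),
            phase=rng.standard_normal(50),
            area=10 + rng.standard_normal(50),
            fwhm=8.5 + rng.standard_normal(50),
        )
        m2 = reject_outlier_transients(fits, k=2.0)
        m3 = reject_outlier_transients(fits, k=3.0)
        assert not np.any(m2 & ~m3)  # k=2 never retains more

    def test_too_few_fits_rejected(self):
        with pytest.raises(ValueError):
            reject_outlier_transients(self._fits([3.0, 3.0]))


class TestCorrection:
    def test_correction_restores_center_and_phase(self, amplitudes):
        t = synthesize_transient(
            VC_PROFILE, amplitudes, "OFF", freq_offset_ppm=0.01, phase_deg=20.0
        )
        fit = fit_reference_peak(t, VC_PROFILE.hz_per_ppm)
        t2 = apply_freq_phase_correction(t, fit)
        fit2 = fit_reference_peak(t2, VC_PROFILE.hz_per_ppm)
        assert fit2.freq_ppm == pytest.approx(3.0, abs=1e-4)
        assert fit2.phase_deg == pytest.approx(0.0, abs=0.1)

    def test_zero_offset_correction_is_identity(self, amplitudes):
        from mrsdyn.preprocess import RefFit

        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF")
        fit = RefFit(freq_ppm=3.0, phase_deg=0.0, area=1.0, fwhm_hz=8.5, ok=True)
        t2 = apply_freq_phase_correction(t, fit)
        np.testing.assert_allclose(t2.spectrum, t.spectrum, atol=1e-12)

    def test_correction_idempotent(self, amplitudes):
        t = synthesize_transient(
            VC_PROFILE, amplitudes, "OFF", freq_offset_ppm=0.015, phase_deg=15.0
        )
        t1 = apply_freq_phase_correction(t, fit_reference_peak(t, 127.7))
        t2 = apply_freq_phase_correction(t1, fit_reference_peak(t1, 127.7))
        assert np.abs(t2.spectrum - t1.spectrum).max() < 5e-3

    def test_imaginary_channel_vanishes_at_center_after_phasing(self, amplitudes):
        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF", phase_deg=30.0)
        t2 = apply_freq_phase_correction(t, fit_reference_peak(t, 127.7))
        i0 = np.argmin(np.abs(t2.ppm - 3.0))
        assert abs(t2.spectrum.imag[i0]) < 0.05 * abs(t2.spectrum.real[i0])

    def test_failed_fit_rejected(self, amplitudes):
        from mrsdyn.preprocess import RefFit

        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF")
        bad = RefFit(freq_ppm=3.0, phase_deg=0.0, area=1.0, fwhm_hz=8.5, ok=False)
        with pytest.raises(ValueError):
            apply_freq_phase_correction(t, bad)

    def test_degenerate_shift_rejected(self, amplitudes):
        from mrsdyn.preprocess import RefFit

        t = synthesize_transient(VC_PROFILE, amplitudes, "OFF")
        far = RefFit(freq_ppm=30.0, phase_deg=0.0, area=1.0, fwhm_hz=8.5, ok=True)
        with pytest.raises(ValueError, match="half the spectral width"):
            apply_freq_phase_correction(t, far)


class TestFrequencyDrift:
    def test_constant_positions_zero_drift(self):
        assert frequency_drift(np.full(10, 3.0)) == 0.0

    def test_two_point_sd(self):
        assert frequency_drift([3.00, 3.01]) == pytest.approx(0.00707, abs=1e-4)

    def test_needs_two_fits(self):
        with pytest.raises(ValueError):
            frequency_drift([3.0])

    def test_recovers_injected_jitter_sd(self):
        """The per-subject drift metric estimates the injected 0.0088 ppm
        frequency jitter from OFF-transient Cr fits."""
        truth = GroundTruth.null()
        coh = simulate_cohort(VC_PROFILE, truth, 6, seed=11)
        pre = preprocess_cohort(coh)
        est = np.nanmean(pre.freq_drift_ppm)
        assert est == pytest.approx(0.0088, rel=0.15)


class TestAverageAndDifference:
    def test_identical_conditions_give_zero_difference(self, rng):
        spec = rng.standard_normal((10, 64)) + 1j * rng.standard_normal((10, 64))
        spec[1::2] = spec[0::2]
        is_on = np.arange(10) % 2 == 1
        _, _, diff = average_and_difference(spec, is_on, np.ones(10, bool))
        np.testing.assert_allclose(diff, 0, atol=1e-12)

    def test_selection_without_condition_errors(self, rng):
        spec = rng.standard_normal((10, 8)).astype(complex)
        is_on = np.arange(10) % 2 == 1
        retained = np.ones(10, bool)
        retained[1::2] = False  # all ON dropped
        with pytest.raises(ValueError, match="ON"):
            average_and_difference(spec, is_on, retained, (0, 10))

    def test_difference_noise_scales_as_sqrt_2_over_n(self, rng):
        """DIFF noise SD ~ s*sqrt(2/n) for n transients per condition."""
        s, n = 0.5, 64
        diffs = []
        for _ in range(300):
            spec = s * (rng.standard_normal((2 * n, 32))
                        + 1j * rng.standard_normal((2 * n, 32)))
            is_on = np.arange(2 * n) % 2 == 1
            _, _, d = average_and_difference(spec, is_on, np.ones(2 * n, bool))
            diffs.append(d.real)
        sd = np.std(diffs)
        assert sd == pytest.approx(s * np.sqrt(2 / n), rel=0.05)


class TestPreprocessCohort:
    def test_ratio_pipeline_scale_invariant(self, mini_cohort):
        from mrsdyn.quantify import static_estimates
        import copy

        pre1 = preprocess_cohort(mini_cohort)
        scaled = copy.copy(mini_cohort)
        scaled.spectra = mini_cohort.spectra * 3.0
        pre2 = preprocess_cohort(scaled)
        np.testing.assert_allclose(pre2.area, 3.0 * pre1.area, rtol=1e-3)
        np.testing.assert_allclose(pre2.freq_ppm, pre1.freq_ppm, atol=1e-6)
        assert np.array_equal(pre1.retained, pre2.retained)
        s1 = static_estimates(pre1)
        s2 = static_estimates(pre2)
        for met in ("gaba", "glx", "tnaa"):
            np.testing.assert_allclose(
                s2[f"{met}_tcr"], s1[f"{met}_tcr"], rtol=1e-6
            )

    def test_retention_and_drift_populated(self, mini_cohort):
        pre = preprocess_cohort(mini_cohort)
        assert pre.retained.mean() > 0.9
        assert np.isfinite(pre.freq_drift_ppm).all()
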