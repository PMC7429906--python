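"""Quantification tests: peak models, referencing, CSF correction,
participant exclusion and the statistical helpers."""

import numpy as np
import pytest
import pandas as pd
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsdyn import (
    VC_PROFILE,
    compare_groups,
    csf_correct,
    exclude_participants_by_fwhm,
    fit_peak,
    partial_correlation,
    quantify_selection,
    synthesize_transient,
)
from mrsdyn.quantify import fit_peaks_batch, static_estimates
from mrsdyn.preprocess import preprocess_cohort


@pytest.fixture(scope="module")
def clean_selection(amplitudes):
    """Noiseless mean OFF and difference spectra with known areas."""
    off = synthesize_transient(VC_PROFILE, amplitudes, "OFF").spectrum
    on = synthesize_transient(VC_PROFILE, amplitudes, "ON").spectrum
    return off, on - off


class TestFitPeak:
    def test_noiseless_gaussian_closed_forms(self):
        ppm = VC_PROFILE.ppm_axis()
        y = np.exp(-0.5 * ((ppm - 3.0) / 0.04) ** 2)
        pk = fit_peak(y, ppm, "gaussian", 3.0, (2.8, 3.3), 127.7)
        assert pk.area == pytest.approx(0.04 * np.sqrt(2 * np.pi), rel=1e-4)
        assert pk.fwhm_hz == pytest.approx(12.03, abs=0.02)
        assert pk.fit_error_pct < 0.01

    def test_noiseless_lorentzian_fwhm(self, clean_selection):
        off, _ = clean_selection
        pk = fit_peak(off.real, VC_PROFILE.ppm_axis(), "lorentzian", 3.0,
                      (2.6, 3.4), 127.7)
        assert pk.fwhm_hz == pytest.approx(8.5, abs=0.05)
        assert pk.ok

    def test_center_outside_window_rejected(self, clean_selection):
        off, _ = clean_selection
        with pytest.raises(ValueError, match="window"):
            fit_peak(off.real, VC_PROFILE.ppm_axis(), "lorentzian", 3.0,
                     (1.8, 2.2), 127.7)

    def test_noisy_area_median_unbiased_and_fit_error_monotone(self, rng):
        """Median fitted area within 2% of truth; fit error grows with
        noise."""
        ppm = VC_PROFILE.ppm_axis()
        truth = 0.6 * np.exp(-0.5 * ((ppm - 3.0) / 0.083) ** 2)
        true_area = 0.6 * 0.083 * np.sqrt(2 * np.pi)
        med_err = []
        for noise in (0.005, 0.02, 0.05):
            Y = truth[None, :] + noise * rng.standard_normal((100, len(ppm)))
            r = fit_peaks_batch(Y, ppm, "gaussian", (2.8, 3.3), 127.7,
                                center_ppm=3.0, w_init=0.08)
            assert np.median(r["area"]) == pytest.approx(true_area, rel=0.02)
            med_err.append(np.median(r["fit_error_pct"]))
        assert med_err[0] < med_err[1] < med_err[2]

    def test_inverse_lorentzian_magnitude_positive(self, clean_selection):
        _, diff = clean_selection
        pk = fit_peak(diff.real, VC_PROFILE.ppm_axis(), "inverse_lorentzian",
                      2.0, (1.8, 2.2), 127.7)
        assert pk.area == pytest.approx(0.4, rel=1e-3)
        assert pk.amplitude > 0
        assert pk.ok


class TestQuantifySelection:
    def test_recovers_injected_ratios(self, clean_selection):
        off, diff = clean_selection
        est = quantify_selection(off, diff, VC_PROFILE.ppm_axis(), 127.7)
        assert est.ok
        assert est.ratios["gaba"] == pytest.approx(0.120, abs=0.002)
        assert est.ratios["glx"] == pytest.approx(1.0, abs=0.02)
        assert est.ratios["tnaa"] == pytest.approx(1.4, abs=0.02)

    def test_global_scaling_leaves_ratios_unchanged(self, clean_selection):
        off, diff = clean_selection
        a = quantify_selection(off, diff, VC_PROFILE.ppm_axis(), 127.7)
        b = quantify_selection(3 * off, 3 * diff, VC_PROFILE.ppm_axis(), 127.7)
        for met in ("gaba", "glx", "tnaa"):
            assert b.ratios[met] == pytest.approx(a.ratios[met], abs=1e-10)

    def test_reference_switch_is_algebraic(self, clean_selection):
        off, diff = clean_selection
        a = quantify_selection(off, diff, VC_PROFILE.ppm_axis(), 127.7, "tcr")
        b = quantify_selection(off, diff, VC_PROFILE.ppm_axis(), 127.7, "tnaa")
        expect = a.ratios["gaba"] * a.areas["tcr"] / a.areas["tnaa"]
        assert b.ratios["gaba"] == pytest.approx(expect, abs=1e-10)

    def test_unknown_reference_rejected(self, clean_selection):
        off, diff = clean_selection
        with pytest.raises(ValueError):
            quantify_selection(off, diff, VC_PROFILE.ppm_axis(), 127.7, "water")


class TestCsfCorrect:
    def test_worked_values(self):
        assert csf_correct(1.0, 0.0) == 1.0
        assert csf_correct(1.2, 0.25) == pytest.approx(1.6)
        for x in (0.3, 1.0, 2.5):
            assert csf_correct(x, 0.5) == pytest.approx(2 * x)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            csf_correct(1.0, 1.0)
        with pytest.raises(ValueError):
            csf_correct(1.0, -0.1)

    def test_strictly_increasing_in_csf_fraction(self):
        f = np.linspace(0, 0.9, 50)
        out = csf_correct(np.ones_like(f), f)
        assert np.all(np.diff(out) > 0)
        assert out[0] == 1.0

    @given(
        c=st.floats(1e-6, 1e3),
        f1=st.one_of(st.just(0.0), st.floats(1e-6, 0.99)),
        f2=st.floats(1e-6, 0.99),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_correction_properties(self, c, f1, f2):
        out = csf_correct(c, f1)
        assert out >= c  # never shrinks a concentration
        if f1 == 0.0:
            assert out == c
        else:
            assert out > c
        if f2 > f1 * (1 + 1e-9) + 1e-9:
            assert csf_correct(c, f2) > out  # monotone in CSF fraction
        assert csf_correct(2 * c, f1) == pytest.approx(2 * out, rel=1e-12)


class TestParticipantExclusion:
    def test_homogeneous_cohort_keeps_everyone(self, rng):
        fwhm = pd.DataFrame(8.5 + 0.1 * rng.standard_normal((20, 4)),
                            columns=["gaba", "glx", "tnaa", "tcr"])
        assert exclude_participants_by_fwhm(fwhm).all()

    def test_one_gross_outlier_among_58(self, rng):
        fwhm = pd.DataFrame(8.5 + 0.3 * rng.standard_normal((58, 4)),
                            columns=["gaba", "glx", "tnaa", "tcr"])
        fwhm.loc[13, "tcr"] += 0.3 * 12
        mask = exclude_participants_by_fwhm(fwhm)
        assert not mask[13]
        assert mask.sum() == 57

    def test_fixed_point_after_removal(self, rng):
        fwhm = pd.DataFrame(8.5 + 0.3 * rng.standard_normal((58, 4)),
                            columns=["gaba", "glx", "tnaa", "tcr"])
        fwhm.loc[5, "gaba"] += 5.0
        mask = exclude_participants_by_fwhm(fwhm)
        retained = fwhm[mask].reset_index(drop=True)
        assert exclude_participants_by_fwhm(retained).all()

    def test_needs_three_participants(self):
        with pytest.raises(ValueError):
            exclude_participants_by_fwhm(
                pd.DataFrame({"gaba": [8.0, 9.0]})
            )

    def test_broad_linewidth_subject_excluded_end_to_end(self, mini_profile, mini_truth):
        from mrsdyn.synthetic import simulate_cohort

        # |z| can reach at most (n-1)/sqrt(n), so the cohort must be large
        # enough for a 3 SD exclusion to be possible at all
        coh = simulate_cohort(mini_profile, mini_truth, 14, seed=3,
                              broad_linewidth_subjects=1)
        pre = preprocess_cohort(coh)
        df = static_estimates(pre)
        assert not df["included"].iloc[0]
        assert df["included"].iloc[1:].all()


class TestStaticEstimates:
    def test_static_ratio_is_time_average_of_ramp(self, quiet_truth):
        """With a linear ramp the all-transient static estimate equals the
        baseline times (1 + drift/2)."""
        from mrsdyn import GroundTruth
        from mrsdyn.synthetic import simulate_cohort

        truth = GroundTruth.null(quiet_truth)
        truth.drift_total = {"gaba": -0.10, "glx": 0.0, "tnaa": 0.0, "tcr": 0.0}
        coh = simulate_cohort(VC_PROFILE, truth, 3, seed=5)
        pre = preprocess_cohort(coh)
        df = static_estimates(pre)
        expect = 0.12 * (1 - 0.10 / 2)
        assert df["gaba_tcr"].mean() == pytest.approx(expect, rel=0.01)

    def test_zero_csf_means_no_correction(self, mini_cohort):
        pre = preprocess_cohort(mini_cohort)
        df = static_estimates(pre)
        manual = df["gaba_tcr"] / (1 - df["csf"])
        np.testing.assert_allclose(df["gaba_tcr_corr"], manual, rtol=1e-12)


class TestPartialCorrelation:
    def test_reduces_to_pearson_when_control_orthogonal(self):
        # project z onto the orthogonal complement of span{1, x, y}
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        z0 = np.array([1.0, -1.0, 0.0, 1.0, -1.0])
        design = np.stack([np.ones_like(x), x, y], axis=1)
        coef, *_ = np.linalg.lstsq(design, z0, rcond=None)
        z = z0 - design @ coef
        r, _ = partial_correlation(x, y, z)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-9)

    def test_degenerate_control_errors(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            partial_correlation(x, x[::-1], x)

    def test_formula_value(self, rng):
        """r_xy = r_xz = r_yz = 0.5 gives r_xy.z = 1/3, checked against both
        the closed form and independent implementations."""
        n = 2000
        a, b, c = rng.standard_normal((3, n))
        base = rng.standard_normal(n)
        # equal shared/unique variance gives pairwise correlation ~0.5
        x = base + a
        y = base + b
        z = base + c
        r, p = partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expect = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(expect, abs=1e-12)
        assert r == pytest.approx(1 / 3, abs=0.1)

    def test_agrees_with_regression_residuals_and_pingouin(self, rng):
        x, y, z = rng.standard_normal((3, 40))
        y = y + 0.5 * x + 0.3 * z
        r, p = partial_correlation(x, y, z)
        # oracle 1: correlation of OLS residuals
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)
        # oracle 2: pingouin
        import pingouin as pg

        tab = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert r == pytest.approx(float(tab["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(tab["p_val"].iloc[0]), abs=1e-8)


class TestCompareGroups:
    def test_identical_groups(self, rng):
        a = rng.standard_normal(30)
        res = compare_groups(a, a.copy())
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_normal_data_uses_t_test_with_power(self):
        hits = 0
        t_picks = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            a = r.standard_normal(100)
            b = r.standard_normal(100) + 1.0
            res = compare_groups(a, b)
            hits += res["p"] < 1e-3
            t_picks += res["test"] == "t"
        assert hits >= 95
        # the Shapiro gate keeps ~5% false positives per group, so the t
        # test is selected in roughly 90% of draws
        assert t_picks >= 80

    def test_heavy_tailed_data_selects_ranksum(self):
        picks = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            a = r.standard_cauchy(40)
            b = r.standard_cauchy(40)
            picks.append(compare_groups(a, b)["test"])
        assert picks.count("wilcoxon_ranksum") > 25

    def test_all_ties_handled(self):
        res = compare_groups(np.ones(10), np.ones(10))
        assert res["test"] == "wilcoxon_ranksum"
        assert np.isfinite(res["p"])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
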