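import numpy as np
import pytest

from osteoquant.raman import (
    BANDS,
    BandDefinition,
    RamanSpectrum,
    average_accumulations,
    band_area,
    band_fwhm,
    compute_metrics,
    intensity_at,
    rcf_baseline,
    truncate,
)
from osteoquant.synthetic import Band, SpectrumTruth, gen_raman_spectrum

GAUSS_FWHM = 2 * np.sqrt(2 * np.log(2))


class TestAverage:
    def test_identical_spectra(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        out = average_accumulations([spec] * 10)
        assert np.allclose(out.intensity, spec.intensity)
        assert out.n_accumulations == 10

    def test_noise_reduction(self):
        # averaging 10 accumulations cuts the noise sd by ~ sqrt(10)
        truth = SpectrumTruth(bands=[Band(960.0, 100.0, 6.0)], noise_sd=5.0)
        specs = [gen_raman_spectrum(truth, step=1.0, seed=s)[0] for s in range(10)]
        avg = average_accumulations(specs)
        flat = (avg.wavenumber > 1500) & (avg.wavenumber < 1900)
        sd = np.std(avg.intensity[flat])
        assert sd == pytest.approx(5.0 / np.sqrt(10), rel=0.25)

    def test_mismatched_axes_error(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        other = RamanSpectrum(spec.wavenumber + 0.5, spec.intensity)
        with pytest.raises(ValueError, match="identical"):
            average_accumulations([spec, other])


class TestTruncate:
    def test_wide_axis(self):
        wn = np.arange(100.0, 2500.0)
        spec = truncate(RamanSpectrum(wn, np.ones_like(wn)))
        assert spec.wavenumber[0] >= 280
        assert spec.wavenumber[-1] <= 2000

    def test_already_truncated_unchanged(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        out = truncate(spec)
        assert np.array_equal(out.wavenumber, spec.wavenumber)

    def test_beyond_data_warns(self):
        wn = np.arange(300.0, 1500.0)
        with pytest.warns(UserWarning, match="exceeds"):
            out = truncate(RamanSpectrum(wn, np.ones_like(wn)), 280, 2000)
        assert out.wavenumber[-1] == 1499.0


class TestBandArea:
    def test_gaussian_closed_form(self):
        # unit-height Gaussian sigma=5 at 955 integrated over 930-980 (+-5 sigma)
        truth = SpectrumTruth(bands=[Band(955.0, 1.0, 5.0)])
        spec, _ = gen_raman_spectrum(truth, step=1.0, seed=0)
        area = band_area(spec, BandDefinition("x", 930.0, 980.0))
        assert area == pytest.approx(5.0 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_linearity(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        scaled = RamanSpectrum(spec.wavenumber, 10 * spec.intensity)
        b = BANDS["nu1PO4"]
        assert band_area(scaled, b) == pytest.approx(10 * band_area(spec, b), rel=1e-12)

    def test_band_outside_axis(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        with pytest.raises(ValueError, match="outside"):
            band_area(spec, BandDefinition("x", 2100.0, 2200.0))

    def test_trapezoid_matches_analytic_band_sum(self, bone_spectrum_clean):
        # noise 0, baseline 0: sampled areas equal analytic profile integrals
        spec, truth = bone_spectrum_clean
        fine = np.arange(930.0, 980.0, 0.01)
        analytic = np.trapezoid(truth.band_sum(fine), fine)
        assert band_area(spec, BANDS["nu1PO4"]) == pytest.approx(analytic, rel=1e-3)


class TestFWHM:
    def test_gaussian(self):
        truth = SpectrumTruth(bands=[Band(960.0, 1000.0, 6.0)])
        spec, _ = gen_raman_spectrum(truth, step=1.0, seed=0)
        assert band_fwhm(spec) == pytest.approx(GAUSS_FWHM * 6.0, rel=0.005)

    def test_lorentzian(self):
        truth = SpectrumTruth(bands=[Band(955.0, 1000.0, 7.0, "lorentzian")])
        spec, _ = gen_raman_spectrum(truth, step=1.0, seed=0)
        assert band_fwhm(spec) == pytest.approx(14.0, rel=0.005)

    def test_noisy_recovery(self):
        truth = SpectrumTruth(noise_sd=10.0)  # 1% of the nu1 height
        errs = []
        for seed in range(10):
            spec, truth = gen_raman_spectrum(truth, step=1.0, seed=seed)
            corr, _ = rcf_baseline(spec)
            fwhm = band_fwhm(corr)
            errs.append(abs(fwhm * truth.true_metrics["crystallinity"] - 1))
        assert np.mean(errs) < 0.03

    def test_no_peak_invalid(self):
        wn = np.arange(280.0, 2001.0)
        rising = np.linspace(0, 1, len(wn))
        with pytest.raises(ValueError):
            band_fwhm(RamanSpectrum(wn, rising))


class TestRCFBaseline:
    def test_flat_zero_baseline_identity(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        corr, baseline = rcf_baseline(spec)
        assert np.abs(baseline).max() < 0.02 * spec.intensity.max()
        assert np.allclose(corr.intensity, spec.intensity, atol=0.02 * spec.intensity.max())

    def test_cubic_baseline_band_recovery(self):
        truth = SpectrumTruth(baseline_coeffs=(100.0, -80.0, 60.0, 300.0))
        spec, truth = gen_raman_spectrum(truth, step=1.0, seed=0)
        corr, _ = rcf_baseline(spec)
        fine = np.arange(930.0, 980.0, 0.01)
        analytic = np.trapezoid(truth.band_sum(fine), fine)
        assert band_area(corr, BANDS["nu1PO4"]) == pytest.approx(analytic, rel=0.02)

    def test_baseline_only_near_zero(self):
        from scipy.ndimage import gaussian_filter1d

        truth = SpectrumTruth(
            bands=[Band(960.0, 1e-9, 6.0)],
            baseline_coeffs=(30.0, 40.0, 200.0),
            noise_sd=2.0,
        )
        spec, _ = gen_raman_spectrum(truth, step=1.0, seed=1)
        corr, _ = rcf_baseline(spec)
        # the baseline error (noise suppressed) stays below 3 noise sd
        assert np.abs(gaussian_filter1d(corr.intensity, 3.0)).max() < 3 * 2.0

    def test_idempotence_band_areas(self):
        # strictly idempotent for the isolated nu1 PO4 band; bands sitting in
        # broad overlapping envelopes are shaved a further 1-3% per pass
        truth = SpectrumTruth(baseline_coeffs=(100.0, -80.0, 60.0, 300.0), noise_sd=3.0)
        spec, _ = gen_raman_spectrum(truth, step=1.0, seed=5)
        c1, _ = rcf_baseline(spec)
        c2, _ = rcf_baseline(c1)
        assert band_area(c2, BANDS["nu1PO4"]) == pytest.approx(
            band_area(c1, BANDS["nu1PO4"]), rel=0.005
        )
        for b in BANDS.values():
            assert band_area(c2, b) == pytest.approx(band_area(c1, b), rel=0.03)


class TestMetrics:
    def test_scaling_invariance(self, bone_spectrum_clean):
        spec, _ = bone_spectrum_clean
        m1 = compute_metrics(spec)
        m2 = compute_metrics(RamanSpectrum(spec.wavenumber, 7.0 * spec.intensity))
        for name in (
            "mineral_matrix", "carbonate_phosphate", "crystallinity",
            "collagen_maturity", "pen_ratio",
        ):
            assert getattr(m2, name) == pytest.approx(getattr(m1, name), rel=1e-9)

    def test_clean_round_trip_within_1pct(self, bone_spectrum_clean):
        spec, truth = bone_spectrum_clean
        corr, _ = rcf_baseline(spec)
        m = compute_metrics(corr)
        for name, expected in truth.true_metrics.items():
            assert getattr(m, name) == pytest.approx(expected, rel=0.011), name

    def test_noisy_round_trip_within_3pct(self):
        # protocol: ten accumulations averaged per point; noise 1% of nu1 height
        truth = SpectrumTruth(
            baseline_coeffs=(100.0, -80.0, 60.0, 300.0), noise_sd=10.0
        )
        sums = {k: [] for k in truth.true_metrics}
        for rep in range(30):
            accs = [
                gen_raman_spectrum(truth, step=1.0, seed=300 + rep * 10 + a)[0]
                for a in range(10)
            ]
            corr, _ = rcf_baseline(average_accumulations(accs))
            m = compute_metrics(corr)
            for k in sums:
                sums[k].append(getattr(m, k))
        for k, vals in sums.items():
            assert np.mean(vals) == pytest.approx(truth.true_metrics[k], rel=0.03), k

    def test_crystallinity_monotone_in_width(self):
        values = []
        for sigma in (4.0, 6.0, 8.0, 10.0, 12.0):
            truth = SpectrumTruth(bands=[Band(960.0, 1000.0, sigma)])
            spec, _ = gen_raman_spectrum(truth, step=1.0, seed=0)
            values.append(1.0 / band_fwhm(spec))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_missing_band_coverage_error(self):
        wn = np.arange(280.0, 1600.0)
        spec = RamanSpectrum(wn, np.ones_like(wn))
        with pytest.raises(ValueError, match="1690"):
            compute_metrics(spec)

    def test_pen_snr_flag_set_on_noisy_spectrum(self):
        truth = SpectrumTruth(noise_sd=12.0)
        spec, _ = gen_raman_spectrum(truth, step=1.0, seed=4)
        corr, _ = rcf_baseline(spec)
        m = compute_metrics(corr)
        assert m.pen_snr_flag  # PEN peak ~40 counts vs noise ~12

    def test_intensity_interpolation(self):
        wn = np.array([1000.0, 1002.0])
        spec = RamanSpectrum(wn, np.array([1.0, 3.0]))
        assert intensity_at(spec, 1001.0) == pytest.approx(2.0)


class TestSyntheticSpectrum:
    def test_step_limit(self):
        with pytest.raises(ValueError, match="step"):
            gen_raman_spectrum(SpectrumTruth(), step=3.0, seed=0)

    def test_band_center_range_enforced(self):
        with pytest.raises(ValueError, match="280-2000"):
            SpectrumTruth(bands=[Band(100.0, 10.0, 5.0)])

    def test_determinism(self):
        t = SpectrumTruth(noise_sd=5.0)
        s1, _ = gen_raman_spectrum(t, step=1.0, seed=8)
        s2, _ = gen_raman_spectrum(t, step=1.0, seed=8)
        assert np.array_equal(s1.intensity, s2.intensity)
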