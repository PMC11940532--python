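import numpy as np
import pytest

from ramanid import (
    ConfigError,
    PreprocessConfig,
    RamanSpectrum,
    ValidationError,
    baseline_iarpls,
    denoise_savgol,
    despike_whitaker_hayes,
    normalize_minmax,
    run_pipeline,
)
from ramanid.preprocess import preprocess_spectrum
from ramanid.spectrum import SpectrumSet

from .conftest import lorentzian, make_peak_spectrum


class TestDespike:
    def test_smooth_spectrum_untouched(self, three_peak_spectrum):
        out, flags = despike_whitaker_hayes(three_peak_spectrum)
        assert flags.sum() == 0
        np.testing.assert_array_equal(out.intensities, three_peak_spectrum.intensities)

    @pytest.mark.parametrize("noise_sd", [0.01, 0.02])
    def test_injected_spike_recovered_at_exact_index(self, noise_sd):
        clean = make_peak_spectrum(noise_sd=noise_sd, seed=3)
        y = clean.intensities.copy()
        y[700] += 50.0
        out, flags = despike_whitaker_hayes(clean.with_intensities(y))
        assert list(np.nonzero(flags)[0]) == [700]
        assert abs(out.intensities[700] - clean.intensities[700]) < 3 * noise_sd

    def test_adjacent_spikes_both_replaced_from_clean_neighbours(self):
        clean = make_peak_spectrum(noise_sd=0.02, seed=4)
        y = clean.intensities.copy()
        y[700] += 50.0
        y[701] += 45.0
        out, flags = despike_whitaker_hayes(clean.with_intensities(y))
        assert list(np.nonzero(flags)[0]) == [700, 701]
        for i in (700, 701):
            assert abs(out.intensities[i] - clean.intensities[i]) < 0.1

    def test_constant_differences_return_input(self):
        s = RamanSpectrum(np.arange(400.0, 420.0), np.full(20, 3.0))
        out, flags = despike_whitaker_hayes(s)
        assert flags.sum() == 0
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_only_flagged_indices_modified(self):
        clean = make_peak_spectrum(noise_sd=0.02, seed=5)
        y = clean.intensities.copy()
        for i in (123, 456, 900):
            y[i] += 40.0
        out, flags = despike_whitaker_hayes(clean.with_intensities(y))
        untouched = ~flags
        np.testing.assert_array_equal(out.intensities[untouched], y[untouched])


class TestIarpls:
    def test_straight_line_is_its_own_baseline(self):
        nu = np.arange(400.0, 1701.0)
        s = RamanSpectrum(nu, 3.0 + 0.01 * nu)
        res = baseline_iarpls(s)
        assert np.abs(res.corrected).max() < 1e-6 * np.abs(s.intensities).max()

    def test_recovers_known_linear_baseline_under_peaks(self):
        nu = np.arange(400.0, 1701.0)
        true_base = 0.02 * (nu - 400.0)
        y = true_base.copy()
        for c, h in ((600, 1.0), (1000, 0.6), (1400, 0.3)):
            y += lorentzian(nu, c, h, 10.0)
        res = baseline_iarpls(RamanSpectrum(nu, y))
        rmse = np.sqrt(np.mean((res.baseline - true_base) ** 2))
        assert rmse < 0.02  # < 2% of the unit max peak height
        corrected = res.corrected
        for c, h in ((600, 1.0), (1000, 0.6), (1400, 0.3)):
            rec = corrected[np.argmin(np.abs(nu - c))]
            assert abs(rec - h) < 0.05 * h

    def test_all_zero_spectrum(self):
        s = RamanSpectrum(np.arange(400.0, 420.0), np.zeros(20))
        res = baseline_iarpls(s)
        np.testing.assert_allclose(res.baseline, 0.0)
        np.testing.assert_allclose(res.corrected, 0.0)

    def test_conservation_to_machine_precision(self):
        s = make_peak_spectrum(baseline_slope=0.01, noise_sd=0.02, seed=6)
        res = baseline_iarpls(s)
        np.testing.assert_allclose(res.corrected + res.baseline, s.intensities,
                                   rtol=1e-14, atol=1e-14)

    def test_offset_invariance(self):
        s = make_peak_spectrum(baseline_slope=0.01, noise_sd=0.02, seed=7)
        r0 = baseline_iarpls(s)
        r1 = baseline_iarpls(s.with_intensities(s.intensities + 5.0))
        shift_err = np.sqrt(np.mean((r1.baseline - r0.baseline - 5.0) ** 2))
        assert shift_err < 1e-3 * np.sqrt(np.mean(r0.baseline**2))

    def test_bad_lambda_rejected(self):
        s = make_peak_spectrum()
        with pytest.raises(ConfigError):
            baseline_iarpls(s, lam=0.0)


class TestSavgolAndNormalize:
    def test_polynomial_reproduced_exactly(self):
        nu = np.arange(400.0, 500.0)
        y = 1.0 + 0.5 * nu + 0.01 * nu**2  # degree 2 <= order 3
        out = denoise_savgol(RamanSpectrum(nu, y), window=9, order=3)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-9)

    def test_white_noise_variance_reduced(self):
        nu = np.arange(0.0, 2000.0)
        y = np.random.default_rng(0).normal(0, 1, nu.size)
        out = denoise_savgol(RamanSpectrum(nu, y), window=9, order=3)
        assert out.intensities.var() < y.var()

    @pytest.mark.parametrize("window,order", [(6, 3), (5, 5)])
    def test_bad_savgol_params(self, window, order):
        s = make_peak_spectrum()
        with pytest.raises(ConfigError):
            denoise_savgol(s, window=window, order=order)

    def test_minmax_affine_map(self):
        nu = np.arange(400.0, 410.0)
        out = normalize_minmax(RamanSpectrum(nu, np.linspace(2, 6, 10)))
        assert out.intensities.min() == 0.0
        assert out.intensities.max() == 1.0
        assert np.isclose(out.intensities[4], (np.linspace(2, 6, 10)[4] - 2) / 4)

    def test_minmax_idempotent(self, three_peak_spectrum):
        once = normalize_minmax(three_peak_spectrum)
        twice = normalize_minmax(once)
        np.testing.assert_allclose(twice.intensities, once.intensities)

    def test_constant_spectrum_rejected(self):
        s = RamanSpectrum(np.arange(400.0, 410.0), np.full(10, 5.0))
        with pytest.raises(ValidationError):
            normalize_minmax(s)


class TestPipeline:
    def test_empty_set(self):
        res = run_pipeline(SpectrumSet())
        assert len(res.spectra) == 0
        assert res.errors == []

    def test_end_to_end_against_generator_truth(self):
        s = make_peak_spectrum(baseline_slope=0.005, noise_sd=0.01, seed=8)
        y = s.intensities.copy()
        y[650] += 30.0  # cosmic spike
        out, log = preprocess_spectrum(s.with_intensities(y))
        assert log.spikes_removed >= 1
        assert out.intensities.min() == 0.0 and out.intensities.max() == 1.0
        # flat region far from the three peaks should sit near the floor
        region = (out.wavenumbers > 1550) & (out.wavenumbers < 1650)
        assert np.median(out.intensities[region]) < 0.05

    def test_approximate_idempotence_on_clean_data(self):
        s = make_peak_spectrum(noise_sd=0.0)
        once, _ = preprocess_spectrum(s)
        twice, _ = preprocess_spectrum(once)
        rms = np.sqrt(np.mean((twice.intensities - once.intensities) ** 2))
        assert rms < 0.01

    def test_failures_isolated_and_reported(self):
        good = make_peak_spectrum(label="unknown")
        outside = RamanSpectrum(np.arange(2000.0, 2020.0), np.linspace(0, 1, 20),
                                source_path="outside.csv")  # no overlap with crop
        res = run_pipeline(SpectrumSet.from_spectra([good, outside]))
        assert len(res.spectra) == 1
        assert len(res.errors) == 1
        assert res.errors[0][0] == "outside.csv"

    def test_config_invariants_enforced(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(savgol_window=8)
        with pytest.raises(ConfigError):
            PreprocessConfig(iarpls_lambda=-1)
        with pytest.raises(ConfigError):
            PreprocessConfig(despike_z_threshold=0)


def test_peak_position_recovery_across_seeds(library):
    """Full pipeline keeps peak positions within one grid step on average."""
    from ramanid import SyntheticConfig, detect_peaks, simulate_spectrum

    errors = []
    rec = library[0]
    for seed in range(10):
        cfg = SyntheticConfig(seed=seed, noise_sd=0.02, position_jitter_sd=0.0,
                              spike_prob_per_spectrum=0.3)
        s = simulate_spectrum(rec, cfg, 0)
        out, _ = preprocess_spectrum(s)
        detected = np.array([p.position for p in detect_peaks(out)])
        for true_pos in rec.major_peaks:
            errors.append(np.abs(detected - true_pos).min())
    assert np.mean(errors) < 1.0
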