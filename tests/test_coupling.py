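"""Imaginary coherency, phase delays, PAC modulation index, shift predictor."""

import numpy as np
import pytest

from oscnet import coupling as cp
from oscnet import spectral as sp
from oscnet.containers import EpochSet


def _narrowband_pair_epochs(lag_rad, n_trials=200, freq=8.0, fs=200.0, n_samp=200, noise=0.0, mix=0.0, rng=None):
    """Two channels with a fixed phase lag (x leads y by lag_rad), optional
    common zero-lag mixture and additive noise."""
    rng = np.random.default_rng(0) if rng is None else rng
    t = np.arange(n_samp) / fs
    data = np.empty((n_trials, 2, n_samp))
    for e in range(n_trials):
        p = rng.uniform(0, 2 * np.pi)
        x = np.cos(2 * np.pi * freq * t + p)
        y = np.cos(2 * np.pi * freq * t + p - lag_rad)
        common = rng.standard_normal() * np.cos(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        data[e, 0] = x + mix * common + noise * rng.standard_normal(n_samp)
        data[e, 1] = y + mix * common + noise * rng.standard_normal(n_samp)
    return EpochSet(data, fs)


def _spectra(epochs, f=8.0):
    return sp.tf_transform(epochs, sp.frequency_grid(f, f, 0.25))


class TestImaginaryCoherency:
    def test_identical_signals_give_zero(self, rng):
        data = rng.standard_normal((50, 1, 200))
        ep = EpochSet(np.concatenate([data, data], axis=1), 200.0)
        imc = cp.imaginary_coherency(_spectra(ep), np.array([[0, 1]]))
        assert np.allclose(imc.values, 0.0, atol=1e-10)

    def test_quarter_cycle_lag_approaches_unity(self):
        ep = _narrowband_pair_epochs(np.pi / 2, n_trials=200)
        imc = cp.imaginary_coherency(_spectra(ep), np.array([[0, 1]]))
        interior = imc.values[0, 0, 2:-2]
        assert (np.abs(interior) > 0.95).all()
        assert (interior > 0).all()  # x leads y -> positive under (0,1) order

    def test_antisymmetric_under_pair_swap(self, rng):
        ep = _narrowband_pair_epochs(1.0, n_trials=50, noise=0.5, rng=rng)
        spec = _spectra(ep)
        fwd = cp.imaginary_coherency(spec, np.array([[0, 1]]))
        rev = cp.imaginary_coherency(spec, np.array([[1, 0]]))
        assert np.allclose(fwd.values, -rev.values, atol=1e-12)

    def test_values_bounded_by_one(self, rng):
        ep = EpochSet(rng.standard_normal((30, 4, 200)), 200.0)
        imc = cp.imaginary_coherency(_spectra(ep))
        assert (np.abs(imc.values) <= 1.0 + 1e-12).all()

    def test_zero_power_bin_masked_not_nan(self):
        ep = EpochSet(np.zeros((10, 2, 200)), 200.0)
        imc = cp.imaginary_coherency(_spectra(ep), np.array([[0, 1]]))
        assert np.isfinite(imc.values).all()
        assert imc.mask.all()

    def test_zero_lag_common_mixture_alone_stays_small(self, rng):
        # volume-conduction robustness: instantaneous mixing only
        ep = _narrowband_pair_epochs(0.0, n_trials=200, noise=0.3, mix=1.0, rng=rng)
        imc = cp.imaginary_coherency(_spectra(ep), np.array([[0, 1]]))
        assert (np.abs(imc.values[0, 0, 2:-2]) < 0.05).all()

    def test_single_trial_rejected(self, rng):
        ep = EpochSet(rng.standard_normal((1, 2, 200)), 200.0)
        with pytest.raises(ValueError):
            cp.imaginary_coherency(_spectra(ep))


class TestPairwisePhaseDelay:
    def test_constant_delay_recovered(self):
        ep = _narrowband_pair_epochs(0.8, n_trials=40)
        phases, mean = cp.pairwise_phase_delay(_spectra(ep), (0, 1), 0, 4)
        assert mean == pytest.approx(0.8, abs=0.05)

    def test_uniform_delays_give_small_resultant(self, rng):
        n = 400
        t = np.arange(200) / 200.0
        data = np.empty((n, 2, 200))
        for e in range(n):
            p = rng.uniform(0, 2 * np.pi)
            data[e, 0] = np.cos(2 * np.pi * 8 * t + p)
            data[e, 1] = np.cos(2 * np.pi * 8 * t + p - rng.uniform(-np.pi, np.pi))
        phases, _ = cp.pairwise_phase_delay(_spectra(EpochSet(data, 200.0)), (0, 1), 0, 4)
        assert np.abs(np.exp(1j * phases).mean()) < 3 / np.sqrt(n)

    def test_von_mises_delays_recover_center(self, rng):
        n = 500
        t = np.arange(200) / 200.0
        data = np.empty((n, 2, 200))
        for e in range(n):
            p = rng.uniform(0, 2 * np.pi)
            lag = rng.vonmises(1.0, 5.0)
            data[e, 0] = np.cos(2 * np.pi * 8 * t + p)
            data[e, 1] = np.cos(2 * np.pi * 8 * t + p - lag)
        _, mean = cp.pairwise_phase_delay(_spectra(EpochSet(data, 200.0)), (0, 1), 0, 4)
        assert abs(mean - 1.0) < 0.1

    def test_all_zero_coefficients_rejected(self):
        ep = EpochSet(np.zeros((5, 2, 200)), 200.0)
        with pytest.raises(ValueError):
            cp.pairwise_phase_delay(_spectra(ep), (0, 1), 0, 4)


class TestSelectPacSites:
    def test_uniform_map_falls_back_to_top_location(self):
        with pytest.warns(UserWarning):
            sel = cp.select_pac_sites(np.ones(5))
        assert len(sel) == 1

    def test_dominant_location_selected(self):
        stat = np.array([1.0, 1.0, 10.0, 1.0, 1.0])
        assert list(cp.select_pac_sites(stat)) == [2]

    def test_affine_rescaling_invariance(self, rng):
        stat = rng.standard_normal(20)
        a = cp.select_pac_sites(stat)
        b = cp.select_pac_sites(3.7 * stat + 11.0)
        assert list(a) == list(b)


class TestModulationIndex:
    def test_phase_independent_amplitude_gives_near_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 100_000)
        amp = rng.random(100_000) + 0.5
        assert cp.pac_modulation_index(phase, amp) < 0.01

    def test_cosine_modulation_matches_analytic_binning(self):
        # oracle: KL divergence of the analytic bin means of 1 + cos(phase)
        n_bins = 18
        phase = np.linspace(-np.pi, np.pi, 2_000_000, endpoint=False)
        amp = 1.0 + np.cos(phase)
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        centers = (edges[:-1] + edges[1:]) / 2
        width = 2 * np.pi / n_bins
        analytic_means = 1.0 + np.sinc(width / (2 * np.pi)) * np.cos(centers)
        p = analytic_means / analytic_means.sum()
        expected = (np.log(n_bins) + (p * np.log(p)).sum()) / np.log(n_bins)
        assert cp.pac_modulation_index(phase, amp, n_bins) == pytest.approx(expected, abs=1e-3)

    def test_all_amplitude_in_one_bin_gives_one(self):
        phase = np.zeros(1000)
        amp = np.ones(1000)
        assert cp.pac_modulation_index(phase, amp) == pytest.approx(1.0)

    def test_amplitude_rescaling_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        amp = 1.0 + 0.5 * np.cos(phase) + 0.1 * rng.random(5000)
        a = cp.pac_modulation_index(phase, amp)
        b = cp.pac_modulation_index(phase, 7.3 * amp)
        assert a == pytest.approx(b, rel=1e-12)

    def test_bounds_and_errors(self, rng):
        assert 0.0 <= cp.pac_modulation_index(rng.uniform(-np.pi, np.pi, 100), rng.random(100)) <= 1.0
        with pytest.raises(ValueError):
            cp.pac_modulation_index(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            cp.pac_modulation_index(np.zeros(10), np.ones(10), n_phase_bins=2)


def _pac_epochs(depth, n_ep=40, n_samp=800, fs=200.0, rng=None):
    """Trial-varying theta phase; amplitude modulated by that phase."""
    rng = np.random.default_rng(1) if rng is None else rng
    t = np.arange(n_samp) / fs
    phases = np.empty((n_ep, n_samp))
    amps = np.empty((n_ep, n_samp))
    for e in range(n_ep):
        phi = 2 * np.pi * 6 * t + rng.uniform(0, 2 * np.pi)
        phases[e] = np.angle(np.exp(1j * phi))
        amps[e] = 1.0 + depth * np.cos(phi) + 0.05 * rng.standard_normal(n_samp)
    return phases, np.abs(amps)


class TestShiftPredictor:
    def test_derangement_never_maps_to_self(self, rng):
        for n in (3, 5, 20):
            for _ in range(20):
                p = cp._derangement(n, rng)
                assert not np.any(p == np.arange(n))

    def test_surrogates_below_raw_for_planted_pac(self):
        hits = 0
        for run in range(20):
            rng = np.random.default_rng(run)
            phases, amps = _pac_epochs(0.8, rng=rng)
            raw = cp.pac_modulation_index(phases, amps)
            sur = cp.shift_predictor_mi(phases, amps, n_surrogates=20, rng=rng)
            hits += (sur < raw).mean() >= 0.95
        assert hits >= 19

    def test_null_raw_within_3sd_of_surrogates(self):
        rng = np.random.default_rng(5)
        phases, amps = _pac_epochs(0.0, rng=rng)
        raw = cp.pac_modulation_index(phases, amps)
        sur = cp.shift_predictor_mi(phases, amps, n_surrogates=50, rng=rng)
        assert abs(raw - sur.mean()) <= 3 * sur.std(ddof=1)

    def test_surrogate_count_validation(self, rng):
        phases, amps = _pac_epochs(0.5, n_ep=5)
        with pytest.raises(ValueError):
            cp.shift_predictor_mi(phases, amps, n_surrogates=0, rng=rng)


class TestPacContrast:
    def test_zero_when_raw_equals_surrogate_mean(self):
        res = cp.pac_contrast(0.02, np.array([0.01, 0.02, 0.03]))
        assert res.contrast == pytest.approx(0.0)

    def test_planted_pac_contrast_significant_across_subjects(self):
        from scipy.stats import ttest_1samp

        n_sig = 0
        for run in range(20):
            contrasts = []
            for subj in range(12):
                rng = np.random.default_rng(1000 * run + subj)
                phases, amps = _pac_epochs(0.8, n_ep=20, rng=rng)
                raw = cp.pac_modulation_index(phases, amps)
                sur = cp.shift_predictor_mi(phases, amps, n_surrogates=10, rng=rng)
                contrasts.append(cp.pac_contrast(raw, sur).contrast)
            t = ttest_1samp(contrasts, 0.0, alternative="greater")
            n_sig += t.pvalue < 0.05
        assert n_sig >= 18

    def test_contrast_robust_to_phase_independent_offset(self):
        rng = np.random.default_rng(9)
        phases, amps = _pac_epochs(0.5, n_ep=20, n_samp=5000, rng=rng)
        raw_a = cp.pac_modulation_index(phases, amps)
        sur_a = cp.shift_predictor_mi(phases, amps, 20, np.random.default_rng(1))
        raw_b = cp.pac_modulation_index(phases, amps + 0.2)
        sur_b = cp.shift_predictor_mi(phases, amps + 0.2, 20, np.random.default_rng(1))
        a = cp.pac_contrast(raw_a, sur_a).contrast
        b = cp.pac_contrast(raw_b, sur_b).contrast
        assert abs(a - b) < 0.01


def test_bandpass_phase_amplitude_tracks_planted_oscillation(rng):
    fs, n, trim = 400.0, 8000, 1600
    t = np.arange(n) / fs
    theta = np.cos(2 * np.pi * 6 * t + 1.0)
    ep = EpochSet(theta[None, None, :] + 0.01 * rng.standard_normal((1, 1, n)), fs)
    phase = cp.bandpass_phase_amplitude(ep, 0, (5, 7), "phase")[0]
    expected = np.angle(np.exp(1j * (2 * np.pi * 6 * t + 1.0)))
    err = np.angle(np.exp(1j * (phase[trim:-trim] - expected[trim:-trim])))
    assert np.abs(err).mean() < 0.1
    amp = cp.bandpass_phase_amplitude(ep, 0, (5, 7), "amplitude")[0]
    assert np.allclose(amp[trim:-trim], 1.0, atol=0.1)
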