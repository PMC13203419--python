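"""Botteron filtering, Welch spectra, DF picking and the Organization
Index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdfmap import (
    PowerSpectrum,
    SimConfig,
    SpectralConfig,
    botteron_filter,
    compute_df_point,
    organization_index,
    pick_df,
    welch_psd,
)
from hdfmap.quality import RejectReason
from hdfmap.synthetic import DFField, render_pulse_train, simulate_egm, simulate_trajectory

from oracles import oi_bruteforce

FS = 1000.0
CFG = SpectralConfig()


def grid_spectrum(power_fn, step=0.05, top=20.0):
    freqs = np.round(np.arange(0, top + step / 2, step), 10)
    power = np.array([power_fn(f) for f in freqs])
    return PowerSpectrum(freqs, power)


class TestBotteron:
    def test_out_of_band_tone_rejected(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        env = botteron_filter(x, FS)
        assert np.sum(env**2) < 0.01 * np.sum(x**2)

    def test_zero_in_zero_out(self):
        assert not botteron_filter(np.zeros(2000), FS).any()

    def test_envelope_energy_below_30hz(self):
        x = render_pulse_train(np.arange(0.05, 2.0, 1 / 6.0), 2000, FS)
        env = botteron_filter(x, FS)
        spec = np.abs(np.fft.rfft(env - env.mean())) ** 2
        freqs = np.fft.rfftfreq(env.size, 1 / FS)
        assert spec[freqs > 30].sum() < 0.01 * spec.sum()

    def test_pulse_train_envelope_peaks_at_rate(self):
        """FFT oracle on the envelope: largest 4-10 Hz peak at the rate."""
        x = render_pulse_train(np.arange(0.05, 2.0, 1 / 6.0), 2000, FS)
        env = botteron_filter(x, FS)
        spec = np.abs(np.fft.rfft(env - env.mean(), n=20000)) ** 2
        freqs = np.fft.rfftfreq(20000, 1 / FS)
        band = (freqs >= 4) & (freqs <= 10)
        peak = freqs[band][np.argmax(spec[band])]
        assert peak == pytest.approx(6.0, abs=0.1)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            botteron_filter(np.zeros(800), 400.0)


class TestWelch:
    def test_single_tone_peak_on_grid(self):
        t = np.arange(2000) / FS
        env = np.sin(2 * np.pi * 6.0 * t)
        spec = welch_psd(env, FS)
        in_band = spec.freqs <= 20.0
        peak = spec.freqs[in_band][np.argmax(spec.power[in_band])]
        assert peak == pytest.approx(6.0, abs=0.05)
        assert spec.step == pytest.approx(0.05)

    def test_zero_envelope_zero_spectrum(self):
        spec = welch_psd(np.zeros(2000), FS)
        assert not spec.power.any()

    def test_white_noise_total_power_stable_across_seeds(self):
        totals = []
        for seed in (0, 1):
            env = np.random.default_rng(seed).normal(size=2000)
            totals.append(welch_psd(env, FS).power.sum())
        assert max(totals) < 3 * min(totals)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError, match="expected"):
            welch_psd(np.zeros(1500), FS)


class TestPickDF:
    def test_out_of_band_peak_ignored(self):
        spec = grid_spectrum(lambda f: 100.0 if f == 3.0 else (1.0 if f == 5.0 else 0.0))
        assert pick_df(spec) == pytest.approx(5.0)

    def test_tie_breaks_to_lowest_frequency(self):
        spec = grid_spectrum(lambda f: 1.0 if f in (5.0, 7.0) else 0.0)
        assert pick_df(spec) == pytest.approx(5.0)

    def test_no_band_power_returns_none(self):
        spec = grid_spectrum(lambda f: 1.0 if f < 3.0 else 0.0)
        assert pick_df(spec) is None

    def test_worked_example_6p7(self):
        """A 6.7 Hz activation train shows its spectral peak near 6.7 Hz."""
        x = render_pulse_train(np.arange(0.03, 2.0, 1 / 6.7), 2000, FS)
        spec = welch_psd(botteron_filter(x, FS), FS)
        assert pick_df(spec) == pytest.approx(6.7, abs=0.05)


class TestOrganizationIndex:
    def test_all_power_in_df_and_harmonic_bands_gives_one(self):
        spec = grid_spectrum(
            lambda f: 1.0 if any(abs(f - c) <= 0.375 for c in (6.0, 12.0, 18.0)) else 0.0
        )
        assert organization_index(spec, 6.0) == pytest.approx(1.0)

    def test_no_band_power_gives_zero(self):
        spec = grid_spectrum(
            lambda f: 0.0 if any(abs(f - c) <= 0.8 for c in (6.0, 12.0, 18.0)) else 1.0
        )
        assert organization_index(spec, 6.0) == pytest.approx(0.0)

    def test_piecewise_constant_spectrum_matches_oracle(self):
        spec = grid_spectrum(
            lambda f: 1.0 if 5.625 - 1e-9 <= f <= 6.375 + 1e-9 else 0.1
        )
        oi = organization_index(spec, 6.0)
        expected = oi_bruteforce(spec.freqs, spec.power, 6.0)
        assert oi == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_undefined(self):
        spec = grid_spectrum(lambda f: 0.0)
        assert organization_index(spec, 6.0) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_random_spectra_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.round(np.arange(0, 20.05, 0.05), 10)
        power = rng.gamma(1.5, 1.0, size=freqs.size)
        spec = PowerSpectrum(freqs, power)
        df = float(rng.uniform(4.0, 10.0))
        oi = organization_index(spec, df)
        assert 0.0 <= oi <= 1.0
        assert oi == pytest.approx(oi_bruteforce(freqs, power, df), rel=1e-9)

    @given(st.integers(0, 10_000), st.floats(4.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_on_arbitrary_nonnegative_spectra(self, seed, df):
        rng = np.random.default_rng(seed)
        freqs = np.round(np.arange(0, 20.05, 0.05), 10)
        power = rng.exponential(1.0, freqs.size) * rng.integers(0, 2, freqs.size)
        if power.sum() == 0:
            power[0] = 1.0
        oi = organization_index(PowerSpectrum(freqs, power), df)
        assert 0.0 <= oi <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_broadband_noise_outside_bands_strictly_lowers_oi(self, seed):
        rng = np.random.default_rng(seed)
        df = float(np.round(rng.uniform(4.5, 9.5) / 0.05) * 0.05)
        centers = [df * m for m in range(1, 5) if df * m <= 20]

        def peaked(f):
            return sum(np.exp(-((f - c) ** 2) / 0.02) for c in centers)

        spec = grid_spectrum(peaked)
        base_oi = organization_index(spec, df)
        far = np.array([min(abs(f - c) for c in centers) for f in spec.freqs])
        noisy = spec.power.copy()
        noisy[far > 1.0] += 0.5
        noisy_oi = organization_index(PowerSpectrum(spec.freqs, noisy), df)
        assert noisy_oi < base_oi

    def test_pulse_train_more_organized_than_with_added_noise(self):
        x = render_pulse_train(np.arange(0.05, 2.0, 1 / 6.0), 2000, FS)
        noise = np.random.default_rng(0).normal(size=2000)
        noise *= np.sqrt(np.sum(x**2) / np.sum(noise**2))
        for_clean = welch_psd(botteron_filter(x, FS), FS)
        for_noisy = welch_psd(botteron_filter(x + noise, FS), FS)
        df_c, df_n = pick_df(for_clean), pick_df(for_noisy)
        assert organization_index(for_clean, df_c) > organization_index(for_noisy, df_n)


@pytest.fixture(scope="module")
def clean_recording():
    cfg = SimConfig(seed=13, duration_s=8.0, n_channels=1, noise_sd=0.0,
                    artifact_rate=0.0, dropout_rate=0.0, powerline_amp=0.0,
                    cycle_jitter_frac=0.0)
    stream = simulate_trajectory(cfg)
    return simulate_egm(cfg, stream, DFField(base_df=6.0)), stream


class TestComputeDFPoint:
    def test_clean_point_recovers_true_df(self, clean_recording):
        rec, stream = clean_recording
        p = compute_df_point(rec, "ch_01", 4000.0, stream.xyz_mm[160])
        assert p.valid
        assert p.df_hz == pytest.approx(6.0, abs=0.1)
        assert p.oi >= 0.2

    def test_dropout_window_invalid_low_amp(self, clean_recording):
        rec, stream = clean_recording
        rec2 = type(rec)(rec.fs, rec.channels,
                         {c: rec.samples[c].copy() for c in rec.channels})
        rec2.samples["ch_01"][3000:5000] *= 0.01
        p = compute_df_point(rec2, "ch_01", 4000.0, stream.xyz_mm[160])
        assert not p.valid and p.reason == RejectReason.LOW_AMP

    def test_window_straddling_start_invalid(self, clean_recording):
        rec, stream = clean_recording
        p = compute_df_point(rec, "ch_01", 500.0, stream.xyz_mm[20])
        assert not p.valid and p.reason == RejectReason.OUT_OF_BOUNDS
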