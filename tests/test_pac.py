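import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from lfpac import (comodulogram, compute_mi, extract_amplitude, extract_phase,
                   modulation_index, phase_amplitude_distribution,
                   phase_binned_amplitude_map)
from _oracles import mi_from_distribution, mi_from_series


class TestPhaseExtraction:
    def test_phase_slope_matches_frequency(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        phase = extract_phase(np.sin(2 * np.pi * 6.0 * t), fs, (4.0, 8.0))
        slope = np.polyfit(t[2000:-2000],
                           np.unwrap(phase)[2000:-2000], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6.0, rel=0.01)

    def test_cosine_reference_convention(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        phase = extract_phase(np.cos(2 * np.pi * 6.0 * t), fs, (4.0, 8.0))
        # mid-record sample where the cosine peaks: phase must return ~0
        peak = 2000 + int(np.argmax(np.cos(2 * np.pi * 6.0 * t[2000:3000])))
        assert abs(phase[peak]) < 0.1

    def test_sinusoid_traverses_phase_bins_uniformly(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        phase = extract_phase(np.sin(2 * np.pi * 6.0 * t), fs, (4.0, 8.0))
        counts = np.bincount(
            ((np.mod(phase[1000:-1000], 2 * np.pi) / (2 * np.pi)) * 18).astype(int),
            minlength=18)
        assert sst.chisquare(counts).pvalue > 0.01

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="invalid band"):
            extract_phase(np.zeros(100), 1000.0, (8.0, 4.0))


class TestAmplitudeExtraction:
    def test_unit_tone_envelope_is_one(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        env = extract_amplitude(np.sin(2 * np.pi * 40.0 * t), fs, (30.0, 50.0))
        assert np.abs(env[2000:-2000] - 1.0).max() < 0.02

    def test_zero_signal_zero_envelope(self):
        env = extract_amplitude(np.zeros(5000), 1000.0, (30.0, 50.0))
        np.testing.assert_allclose(env, 0.0, atol=1e-12)

    def test_am_tone_demodulation(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        modulator = 1.0 + 0.5 * np.cos(2 * np.pi * 2.0 * t)
        env = extract_amplitude(modulator * np.cos(2 * np.pi * 70.0 * t),
                                fs, (50.0, 90.0))
        k = 2000
        rms = np.sqrt(np.mean((env[k:-k] - modulator[k:-k]) ** 2))
        assert rms / np.sqrt(np.mean(modulator ** 2)) < 0.05


class TestPhaseAmplitudeDistribution:
    def test_uniform_coverage_gives_flat_distribution(self):
        phase = np.linspace(0, 2 * np.pi, 18000, endpoint=False)
        pad = phase_amplitude_distribution(phase, np.ones(18000))
        np.testing.assert_allclose(pad.p, 1 / 18, atol=1e-12)
        assert pad.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mass_in_single_bin(self):
        phase = np.linspace(0, 2 * np.pi, 1800, endpoint=False)
        amp = np.zeros(1800)
        bin5 = (phase >= 5 * 2 * np.pi / 18) & (phase < 6 * 2 * np.pi / 18)
        amp[bin5] = 1.0
        pad = phase_amplitude_distribution(phase, amp)
        assert pad.p[5] == pytest.approx(1.0)
        assert np.delete(pad.p, 5).max() == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            phase_amplitude_distribution(np.array([]), np.array([]))

    def test_mode_recovers_preferred_phase(self, coupled_60s):
        x, spec = coupled_60s
        res = compute_mi(x, 1000.0, (4.0, 8.0), (50.0, 90.0))
        mode_deg = res.pad.bin_centers_deg[np.argmax(res.pad.p)]
        pref_deg = np.rad2deg(spec.preferred_phase)
        diff = abs((mode_deg - pref_deg + 180) % 360 - 180)
        assert diff <= 20.0  # within one 20-degree bin


class TestModulationIndex:
    def test_uniform_distribution_gives_zero(self):
        pad = phase_amplitude_distribution(
            np.linspace(0, 2 * np.pi, 18000, endpoint=False), np.ones(18000))
        kl, mi = modulation_index(pad)
        assert kl == 0.0 and mi == 0.0

    def test_degenerate_distribution_gives_one(self):
        phase = np.full(100, 5.5 * 2 * np.pi / 18)
        kl, mi = modulation_index(phase_amplitude_distribution(phase, np.ones(100)))
        assert mi == 1.0
        assert kl == pytest.approx(np.log(18))

    def test_hand_computed_two_level_distribution(self):
        """p = (0.5 in one bin, 0.5/17 elsewhere):
        kl = 0.5 log 9 + 0.5 log(18/34)."""
        n = 18 * 100
        phase = np.linspace(0, 2 * np.pi, n, endpoint=False)
        amp = np.where(phase < 2 * np.pi / 18, 17.0, 1.0)  # means 17 vs 1
        pad = phase_amplitude_distribution(phase, amp)
        np.testing.assert_allclose(pad.p[0], 0.5, atol=1e-12)
        kl, mi = modulation_index(pad)
        expected_kl = 0.5 * np.log(9.0) + 0.5 * np.log(18.0 / 34.0)
        assert kl == pytest.approx(expected_kl, abs=1e-12)
        assert mi == pytest.approx(expected_kl / np.log(18), abs=1e-12)

    def test_agrees_with_direct_summation_oracle_on_distributions(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            amp = rng.exponential(size=5000)
            phase = rng.uniform(0, 2 * np.pi, size=5000)
            pad = phase_amplitude_distribution(phase, amp)
            _, mi = modulation_index(pad)
            assert mi == pytest.approx(mi_from_distribution(list(pad.p)), abs=1e-12)

    def test_agrees_with_direct_summation_oracle_on_signals(self):
        rng = np.random.default_rng(7)
        fs = 1000.0
        for _ in range(10):
            x = rng.standard_normal(5000)
            phase = extract_phase(x, fs, (4.0, 8.0))
            amp = extract_amplitude(x, fs, (30.0, 50.0))
            pad = phase_amplitude_distribution(phase, amp)
            _, mi = modulation_index(pad)
            assert mi == pytest.approx(mi_from_series(phase.tolist(),
                                                      amp.tolist()), abs=1e-12)

    def test_log_base_invariance(self):
        rng = np.random.default_rng(3)
        pad = phase_amplitude_distribution(rng.uniform(0, 2 * np.pi, 2000),
                                           rng.exponential(size=2000))
        _, mi = modulation_index(pad)
        p = pad.p[pad.p > 0]
        mi_log10 = np.sum(p * np.log10(p * 18)) / np.log10(18)
        assert mi == pytest.approx(mi_log10, abs=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1e6,
                              allow_nan=False), min_size=18, max_size=18))
    def test_mi_bounded_for_any_amplitude_profile(self, amps):
        phase = np.linspace(0, 2 * np.pi, 18, endpoint=False) + 0.01
        pad = phase_amplitude_distribution(phase, np.asarray(amps))
        kl, mi = modulation_index(pad)
        assert 0.0 <= mi <= 1.0 and kl >= 0.0


class TestComputeMI:
    def test_white_noise_mi_is_tiny(self, rng):
        x = rng.standard_normal(60000)
        assert compute_mi(x, 1000.0, (4.0, 8.0), (50.0, 90.0)).mi < 0.01

    def test_mi_scale_invariant(self, coupled_60s):
        x, _ = coupled_60s
        mi1 = compute_mi(x, 1000.0, (4.0, 8.0), (50.0, 90.0)).mi
        mi2 = compute_mi(250.0 * x, 1000.0, (4.0, 8.0), (50.0, 90.0)).mi
        assert mi1 == pytest.approx(mi2, abs=1e-12)

    def test_uncoupled_signal_within_surrogate_null(self):
        """kappa=0: the observed MI must not exceed the 95th percentile of a
        time-shift surrogate null."""
        from lfpac import CouplingSpec, generate_coupled_signal

        fs = 1000.0
        spec = CouplingSpec(f_phase=6.0, f_amp=70.0, kappa=0.0)
        x = generate_coupled_signal(spec, 60.0, fs, noise_amp=0.1, seed=21)
        phase = extract_phase(x, fs, (4.0, 8.0))[1000:-1000]
        amp = extract_amplitude(x, fs, (50.0, 90.0))[1000:-1000]
        _, mi_obs = modulation_index(phase_amplitude_distribution(phase, amp))
        rng = np.random.default_rng(22)
        null = []
        for _ in range(200):
            shifted = np.roll(amp, rng.integers(fs, amp.size - fs))
            null.append(modulation_index(
                phase_amplitude_distribution(phase, shifted))[1])
        assert mi_obs <= np.quantile(null, 0.95)

    def test_overlapping_bands_warn(self, rng):
        with pytest.warns(UserWarning, match="overlap"):
            compute_mi(rng.standard_normal(8000), 1000.0, (4.0, 12.0), (10.0, 20.0))


class TestComodulogram:
    def test_white_noise_grid_is_flat_and_bounded(self, rng):
        x = rng.standard_normal(30000)
        grid = comodulogram(x, 1000.0)
        assert grid.mi_matrix.shape == (11, 17)
        assert grid.mi_matrix.max() < 0.01
        assert (grid.mi_matrix >= 0).all() and (grid.mi_matrix <= 1).all()

    def test_amplitude_grid_nyquist_guard(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            comodulogram(rng.standard_normal(5000), 200.0)


class TestPhaseBinnedAmplitudeMap:
    def test_two_cycle_tiling(self, coupled_60s):
        x, _ = coupled_60s
        m = phase_binned_amplitude_map(x, 1000.0, (4.0, 8.0), (50.0, 90.0))
        assert m.size == 36
        np.testing.assert_array_equal(m[:18], m[18:])
        # unimodal distribution -> two identical peaks 360 degrees apart
        assert np.argmax(m[18:]) == np.argmax(m[:18])

    def test_uniform_case_is_flat(self, rng):
        m = phase_binned_amplitude_map(rng.standard_normal(60000), 1000.0,
                                       (4.0, 8.0), (50.0, 90.0))
        assert np.ptp(m) < 0.2 / 18
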