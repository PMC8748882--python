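"""Modulation index, peak selection, phase/amplitude extraction, surrogates."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from imagispeech.cfc import (
    DEFAULT_PAIRS,
    find_spectral_peak,
    find_spectral_peak_epochs,
    mi_contrast_from_profiles,
    mi_from_profile,
    modulation_index,
    phase_amp_series,
    phase_bin_profile,
    single_trial_mi,
    widen_carrier_band,
)
from imagispeech.core_io import DEFAULT_CARRIERS
from imagispeech.synthetic_ecog import generate_background, generate_pac_signal

from conftest import make_epochs


def mi_oracle(phases, amplitudes, n_bins=18):
    """Independent histogram implementation of the KL modulation index."""
    phases = np.asarray(phases).ravel()
    amplitudes = np.asarray(amplitudes).ravel()
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = np.zeros(n_bins)
    for i in range(n_bins):
        sel = (phases >= edges[i]) & (phases < edges[i + 1])
        if sel.any():
            means[i] = amplitudes[sel].mean()
    p = means / means.sum()
    p = np.maximum(p, 1e-12)
    return (np.log(n_bins) + np.sum(p * np.log(p))) / np.log(n_bins)


class TestModulationIndex:
    def test_uniform_profile_gives_zero(self):
        assert mi_from_profile(np.ones(18)) == 0.0

    def test_single_bin_gives_one(self):
        p = np.zeros(18)
        p[4] = 3.0
        assert mi_from_profile(p) == pytest.approx(1.0)

    def test_two_bin_closed_form(self):
        p = np.zeros(18)
        p[0] = p[1] = 0.5
        assert mi_from_profile(p) == pytest.approx(1 - np.log(2) / np.log(18), abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(100):
            phases = rng.uniform(-np.pi, np.pi, size=500)
            amps = rng.gamma(2.0, 1.0, size=500)
            ours = modulation_index(phases, amps)
            assert ours == pytest.approx(mi_oracle(phases, amps), abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_amplitude_scaling(self, scale):
        rng = np.random.default_rng(99)
        phases = rng.uniform(-np.pi, np.pi, size=400)
        amps = rng.gamma(2.0, 1.0, size=400) * (1 + 0.5 * np.cos(phases))
        assert modulation_index(phases, amps * scale) == pytest.approx(
            modulation_index(phases, amps), abs=1e-9
        )

    @given(st.integers(min_value=0, max_value=17))
    @settings(max_examples=18, deadline=None)
    def test_invariant_to_bin_rotation(self, shift):
        rng = np.random.default_rng(7)
        profile = rng.gamma(2.0, 1.0, size=18)
        assert mi_from_profile(np.roll(profile, shift)) == pytest.approx(
            mi_from_profile(profile), abs=1e-12
        )

    def test_constant_amplitude_near_zero(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=5000)
        assert modulation_index(phases, np.ones(5000)) < 1e-4


class TestPeakSelection:
    def test_tone_peak_found(self, rng):
        fs = 400.0
        t = np.arange(int(8 * fs)) / fs
        x = np.cos(2 * np.pi * 6.0 * t) + 0.3 * generate_background(
            8, fs, line_amp=0, rng=rng
        )
        peak = find_spectral_peak(x, fs, "theta")
        assert peak.peak_freq == pytest.approx(6.0, abs=0.5)
        lo, hi = peak.passband
        assert hi - lo == pytest.approx(2.0)  # half the 4-8 Hz band width

    def test_pure_one_over_f_has_no_peak(self, rng):
        absent = 0
        total = 0
        for _ in range(20):
            x = generate_background(8, 400, line_amp=0, rng=rng)
            for band in ("theta", "low_beta", "low_gamma"):
                total += 1
                if find_spectral_peak(x, 400, band).peak_freq is None:
                    absent += 1
        assert absent / total >= 0.9

    def test_maximal_amplitude_peak_selected(self, rng):
        fs = 400.0
        t = np.arange(int(16 * fs)) / fs
        x = (0.5 * np.cos(2 * np.pi * 13.0 * t) + 1.5 * np.cos(2 * np.pi * 16.0 * t)
             + 0.1 * generate_background(16, fs, line_amp=0, rng=rng))
        peak = find_spectral_peak(x, fs, "low_beta")
        assert peak.peak_freq == pytest.approx(16.0, abs=0.5)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="4 s"):
            find_spectral_peak(np.zeros(400), 400.0, "theta")


class TestPhaseAmpSeries:
    def test_phase_advances_at_peak_frequency(self, rng):
        fs = 400.0
        x = generate_pac_signal(6.0, 115.0, 0.0, 8.0, fs, snr=np.inf, rng=rng)
        peak = find_spectral_peak_epochs(x, fs=fs, band_name="theta")
        phase, _, _, _ = phase_amp_series(x, fs, peak, DEFAULT_CARRIERS["bha"])
        unwrapped = np.unwrap(phase)
        n = len(unwrapped)
        rate = (unwrapped[3 * n // 4] - unwrapped[n // 4]) / (n / 2 / fs)
        assert rate == pytest.approx(2 * np.pi * 6.0, rel=0.02)

    def test_unmodulated_envelope_nearly_constant(self, rng):
        fs = 400.0
        x = generate_pac_signal(6.0, 115.0, 0.0, 8.0, fs, snr=20.0, rng=rng)
        peak = find_spectral_peak_epochs(x, fs=fs, band_name="theta")
        _, amp, _, _ = phase_amp_series(x, fs, peak, DEFAULT_CARRIERS["bha"])
        core = amp[len(amp) // 8 : -len(amp) // 8]
        assert core.std() / core.mean() < 0.15

    def test_phase_histogram_uniform(self, rng):
        """The phase of a steady oscillation occupies all 18 bins evenly."""
        fs = 400.0
        x = generate_pac_signal(6.0, 115.0, 0.0, 30.0, fs, snr=20.0, rng=rng)
        peak = find_spectral_peak_epochs(x, fs=fs, band_name="theta")
        phase, _, _, _ = phase_amp_series(x, fs, peak, DEFAULT_CARRIERS["bha"])
        counts, _ = np.histogram(phase, bins=18, range=(-np.pi, np.pi))
        chi2, p = scipy.stats.chisquare(counts)
        assert p > 0.001

    def test_carrier_band_widening(self):
        # low-beta phase (up to 18 Hz) into the 25-50 Hz gamma band: too
        # narrow to hold +-18 Hz sidebands, widened and flagged
        band, limited = widen_carrier_band((25.0, 50.0), 18.0, 400.0)
        assert limited
        assert band[1] - band[0] == pytest.approx(36.0)
        # theta into broadband high-frequency activity: wide enough already
        band, limited = widen_carrier_band((80.0, 150.0), 8.0, 400.0)
        assert not limited
        assert band == (80.0, 150.0)

    def test_flagged_pairs_match_bandwidth_rule(self):
        from imagispeech.core_io import DEFAULT_BANDS

        flagged = set()
        for pband, aband in DEFAULT_PAIRS:
            lo, hi = DEFAULT_CARRIERS[aband]
            if hi - lo < 2 * DEFAULT_BANDS[pband][1]:
                flagged.add((pband, aband))
        assert flagged == {("theta", "beta"), ("low_beta", "gamma")}


class TestSurrogateContrast:
    def test_identical_pools_give_null_result(self, rng):
        profiles = rng.gamma(2.0, 1.0, size=(20, 18))
        res = mi_contrast_from_profiles(profiles, profiles, n_surrogates=100, rng=rng)
        assert res["x_d"] == pytest.approx(0.0, abs=1e-12)
        assert 0.2 < res["p"] < 0.8

    def test_degenerate_surrogates_marked_invalid(self, rng):
        profiles = np.ones((10, 18))
        res = mi_contrast_from_profiles(profiles, profiles, n_surrogates=20, rng=rng)
        assert not res["valid"]

    def test_injected_coupling_detected(self, rng):
        fs = 400.0
        task = np.stack([generate_pac_signal(6.0, 115.0, 0.9, 1.0, fs, snr=10.0, rng=rng)
                         for _ in range(20)])
        base = np.stack([generate_pac_signal(6.0, 115.0, 0.0, 1.0, fs, snr=10.0, rng=rng)
                         for _ in range(20)])
        task_ep = make_epochs(task[:, None, :], fs)
        base_ep = make_epochs(base[:, None, :], fs)
        from imagispeech.cfc import mi_contrast_zscore

        est = mi_contrast_zscore(task_ep, base_ep, "ch0", "theta", "bha",
                                 n_surrogates=100, rng=rng)
        assert est.valid
        assert est.z > 3.0
        assert est.p < 0.01
        assert est.peak_freq == pytest.approx(6.0, abs=1.0)


class TestSingleTrialMI:
    def test_separates_modulated_trials(self, rng):
        fs = 400.0
        mod = np.stack([generate_pac_signal(6.0, 115.0, 0.9, 1.0, fs, snr=10.0, rng=rng)
                        for _ in range(15)])
        flat = np.stack([generate_pac_signal(6.0, 115.0, 0.0, 1.0, fs, snr=10.0, rng=rng)
                         for _ in range(15)])
        ep = make_epochs(np.concatenate([mod, flat])[:, None, :], fs,
                         items=["m"] * 15 + ["f"] * 15)
        ft = single_trial_mi(ep, "ch0", "theta", "bha")
        mis = ft.values[:, 0]
        assert np.all((mis >= 0) & (mis <= 1))
        # AUC of modulated vs flat trials
        from sklearn.metrics import roc_auc_score

        auc = roc_auc_score([1] * 15 + [0] * 15, mis)
        assert auc > 0.8
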