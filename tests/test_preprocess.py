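"""Filter contracts, referencing, resampling, epoching, contamination check."""

import numpy as np
import pandas as pd
import pytest

from imagispeech.core_io import ChannelInfo, Recording, validate_events
from imagispeech.preprocess import (
    acoustic_contamination_check,
    common_average_reference,
    extract_epochs,
    highpass_dc_correct,
    notch_line_noise,
    reject_artifact_epochs,
    resample,
)
from imagispeech.synthetic_ecog import generate_background

from conftest import make_recording, sinusoid_recording


def tone_amplitude(rec, freq):
    """Amplitude of a sinusoid at `freq` estimated by quadrature projection."""
    n = rec.n_samples
    t = np.arange(n) / rec.fs
    x = rec.data[0, n // 4 : 3 * n // 4]  # trim transients
    t = t[n // 4 : 3 * n // 4]
    c = 2 * np.mean(x * np.cos(2 * np.pi * freq * t))
    s = 2 * np.mean(x * np.sin(2 * np.pi * freq * t))
    return np.hypot(c, s)


def butter_mag(f, fc, order, kind):
    """Closed-form analog Butterworth magnitude (one pass)."""
    ratio = (f / fc) if kind == "lowpass" else (fc / f)
    return 1.0 / np.sqrt(1.0 + ratio ** (2 * order))


class TestHighpass:
    def test_removes_dc(self):
        rec = make_recording(np.full((1, 4000), 100.0))
        out = highpass_dc_correct(rec)
        mid = out.data[0, 1000:3000]
        assert np.abs(mid).max() < 1.0

    def test_passband_preserved(self):
        rec = sinusoid_recording(10.0, duration=20.0)
        out = highpass_dc_correct(rec)
        assert tone_amplitude(out, 10.0) == pytest.approx(1.0, rel=0.01)

    def test_stopband_matches_squared_butterworth(self):
        # zero-phase = forward+backward, so attenuation is the squared
        # one-pass order-6 response
        rec = sinusoid_recording(0.1, duration=120.0, fs=100.0)
        out = highpass_dc_correct(rec)
        expected = butter_mag(0.1, 0.5, 6, "highpass") ** 2
        assert tone_amplitude(out, 0.1) == pytest.approx(expected, rel=0.10)


class TestNotch:
    def test_line_attenuated_40db(self):
        rec = sinusoid_recording(60.0, duration=20.0)
        out = notch_line_noise(rec, "us_60")
        assert tone_amplitude(out, 60.0) <= 0.01

    def test_neighbor_preserved(self):
        rec = sinusoid_recording(30.0, duration=20.0)
        out = notch_line_noise(rec, "us_60")
        assert tone_amplitude(out, 30.0) == pytest.approx(1.0, rel=0.01)

    def test_eu_scheme_notches_50hz_harmonics(self):
        for f in (50.0, 100.0, 150.0):
            rec = sinusoid_recording(f, fs=512.0, duration=20.0)
            out = notch_line_noise(rec, "eu_50")
            assert tone_amplitude(out, f) <= 0.01
        rec = sinusoid_recording(75.0, fs=512.0, duration=20.0)
        assert tone_amplitude(notch_line_noise(rec, "eu_50"), 75.0) == pytest.approx(1.0, rel=0.01)

    def test_harmonic_above_nyquist_dropped(self):
        rec = sinusoid_recording(60.0, fs=300.0, duration=10.0)
        out = notch_line_noise(rec, "us_60")  # 178-182 Hz band > Nyquist
        assert out.n_samples == rec.n_samples


class TestZeroPhase:
    def test_time_reversal_symmetry(self, rng):
        """Filtering a reversed signal equals reversing the filtered signal
        (no net group delay).  A compactly supported burst keeps the finite
        recording's edge transients out of the comparison."""
        x = np.zeros((1, 12000))
        x[:, 5000:7000] = rng.normal(size=(1, 2000))
        fwd = notch_line_noise(highpass_dc_correct(make_recording(x))).data
        bwd = notch_line_noise(highpass_dc_correct(make_recording(x[:, ::-1].copy()))).data
        np.testing.assert_allclose(fwd, bwd[:, ::-1], atol=1e-4)


class TestCAR:
    def test_identical_channels_zeroed(self):
        x = np.tile(np.sin(np.arange(100)), (2, 1))
        rec = make_recording(x)
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_zero_mean_pair_unchanged(self):
        rec = make_recording(np.array([[1.0] * 50, [-1.0] * 50]))
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.data, rec.data)

    def test_cross_channel_mean_is_zero(self, rng):
        rec = make_recording(rng.normal(size=(5, 200)))
        out = common_average_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_excluded_channels_dropped(self, rng):
        chans = [ChannelInfo(name="a"), ChannelInfo(name="b"),
                 ChannelInfo(name="bad", excluded=True)]
        rec = Recording(data=rng.normal(size=(3, 100)), fs=400, channels=chans)
        out = common_average_reference(rec)
        assert out.channel_names() == ["a", "b"]

    def test_all_excluded_rejected(self, rng):
        chans = [ChannelInfo(name="a", excluded=True), ChannelInfo(name="b", excluded=True)]
        rec = Recording(data=rng.normal(size=(2, 100)), fs=400, channels=chans)
        with pytest.raises(ValueError):
            common_average_reference(rec)


class TestResample:
    def test_downsample_preserves_slow_tone(self):
        rec = sinusoid_recording(10.0, fs=9600.0, duration=5.0)
        out = resample(rec, 400.0)
        assert out.fs == 400.0
        assert out.n_samples == round(rec.n_samples * 400 / 9600)
        assert tone_amplitude(out, 10.0) == pytest.approx(1.0, rel=0.02)

    def test_identity_at_same_rate(self, rng):
        rec = make_recording(rng.normal(size=(1, 1000)))
        out = resample(rec, 400.0)
        np.testing.assert_allclose(out.data, rec.data)

    def test_antialiasing(self):
        keep = sinusoid_recording(80.0, fs=1600.0, duration=5.0)
        kill = sinusoid_recording(250.0, fs=1600.0, duration=5.0)
        assert tone_amplitude(resample(keep, 400.0), 80.0) == pytest.approx(1.0, rel=0.02)
        # 250 Hz exceeds the new Nyquist: the antialiasing filter removes it
        out = resample(kill, 400.0)
        assert np.sqrt(np.mean(out.data**2)) < 0.05

    def test_upsampling_rejected(self):
        rec = sinusoid_recording(10.0, fs=400.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 800.0)


class TestExtractEpochs:
    def _events(self, rows):
        cols = ["trial_id", "condition", "item", "onset_s", "offset_s",
                "expected_onset_s", "expected_offset_s"]
        return validate_events(pd.DataFrame(rows, columns=cols))

    def test_cue_window_sample_count(self, rng):
        rec = make_recording(rng.normal(size=(1, 4000)))
        ev = self._events([(0, "overt", "w", 2.0, 3.0, np.nan, np.nan)])
        ep = extract_epochs(rec, ev, "cue_window")
        assert ep.data.shape == (1, 1, 400)

    def test_production_window_padding(self, rng):
        rec = make_recording(rng.normal(size=(1, 4000)))
        ev = self._events([(0, "overt", "w", 3.5, 4.5, 3.7, 4.2)])
        ep = extract_epochs(rec, ev, "production_window", pad_s=0.25)
        # [3.45, 4.45) s at 400 Hz
        assert ep.data.shape[2] == 400
        np.testing.assert_array_equal(ep.data[0, 0], rec.data[0, 1380:1780])

    def test_out_of_bounds_names_trial(self, rng):
        rec = make_recording(rng.normal(size=(1, 400)))
        ev = self._events([(7, "overt", "w", 0.5, 2.0, np.nan, np.nan)])
        with pytest.raises(ValueError, match="7"):
            extract_epochs(rec, ev, "cue_window")

    def test_unequal_lengths_rejected(self, rng):
        rec = make_recording(rng.normal(size=(1, 4000)))
        ev = self._events([(0, "overt", "w", 1.0, 2.0, np.nan, np.nan),
                           (1, "overt", "w", 3.0, 3.5, np.nan, np.nan)])
        with pytest.raises(ValueError, match="zero-padding"):
            extract_epochs(rec, ev, "cue_window")

    def test_artifact_rejection_drops_spiked_trial(self, rng):
        data = rng.normal(size=(12, 2, 200))
        data[4, 1, 50] = 500.0  # gross artifact
        from conftest import make_epochs

        ep = make_epochs(data)
        kept, bad = reject_artifact_epochs(ep, sd_threshold=8.0)
        assert bad[4] and bad.sum() == 1
        assert kept.n_trials == 11


class TestContamination:
    def test_mixed_audio_flagged(self, rng):
        fs = 400.0
        n = int(40 * fs)
        audio = generate_background(40, fs, one_over_f_exponent=0.5, line_amp=0, rng=rng)
        audio *= 1 + 0.8 * np.sin(2 * np.pi * 0.7 * np.arange(n) / fs)  # AM envelope
        neural = np.stack([generate_background(40, fs, line_amp=0, rng=rng) for _ in range(3)])
        neural[1] += 0.5 * audio  # leak voice into one channel
        rec = make_recording(neural, fs)
        out = acoustic_contamination_check(rec, audio, fs, n_perm=100, rng=rng)
        assert bool(out.loc[1, "flagged"])
        assert not out.loc[[0, 2], "flagged"].any()

    def test_silent_audio_no_flags(self, rng):
        rec = make_recording(rng.normal(size=(2, 8000)))
        out = acoustic_contamination_check(rec, np.zeros(8000), 400.0, n_perm=50, rng=rng)
        assert not out["flagged"].any()

    def test_duration_mismatch_rejected(self, rng):
        rec = make_recording(rng.normal(size=(1, 8000)))
        with pytest.raises(ValueError, match="duration"):
            acoustic_contamination_check(rec, np.zeros(4000), 400.0, rng=rng)
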