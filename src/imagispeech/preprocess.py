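"""Signal conditioning chain and epoch extraction.

The fixed chain order is high-pass (DC correction) -> notch -> common
average reference -> resample.  All IIR filters are Butterworth designs in
zero-pole-gain (second-order-section) form applied forward-backward, i.e.
zero phase: the effective attenuation is the squared one-pass magnitude and
there is no net group delay.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.signal

from .core_io import Epochs, Recording

logger = logging.getLogger("imagispeech")

NOTCH_SCHEMES = {
    "us_60": [(58.0, 62.0), (118.0, 122.0), (178.0, 182.0)],
    "eu_50": [(48.0, 52.0), (98.0, 102.0), (148.0, 152.0), (198.0, 202.0)],
}


def _sos(kind: str, cutoffs, order: int, fs: float) -> np.ndarray:
    z, p, k = scipy.signal.butter(order, cutoffs, btype=kind, fs=fs, output="zpk")
    return scipy.signal.zpk2sos(z, p, k)


def _filtfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def highpass_dc_correct(rec: Recording, cutoff_hz: float = 0.5, order: int = 6) -> Recording:
    """Remove DC shifts with a zero-phase high-pass Butterworth filter."""
    if rec.fs <= 1.0:
        raise ValueError("sampling rate too low for the DC-correction filter")
    sos = _sos("highpass", cutoff_hz, order, rec.fs)
    return rec.with_data(_filtfilt(sos, rec.data))


def notch_line_noise(rec: Recording, scheme: str = "us_60", order: int = 6) -> Recording:
    """Remove mains noise with zero-phase band-stop filters at each harmonic.

    Stop bands at or above Nyquist are dropped with a logged warning.
    """
    if scheme not in NOTCH_SCHEMES:
        raise ValueError(f"unknown notch scheme {scheme!r}")
    data = rec.data
    for lo, hi in NOTCH_SCHEMES[scheme]:
        if hi >= rec.fs / 2:
            logger.warning("dropping notch band %s-%s Hz above Nyquist (fs=%s)", lo, hi, rec.fs)
            continue
        sos = _sos("bandstop", (lo, hi), order, rec.fs)
        data = _filtfilt(sos, data)
    return rec.with_data(data)


def common_average_reference(rec: Recording) -> Recording:
    """Re-reference to the mean over included channels.

    Channels flagged ``excluded`` are dropped from the recording before the
    average is formed (stand-in for visual rejection of bad contacts).
    """
    keep = [i for i, c in enumerate(rec.channels) if not c.excluded]
    if len(keep) < 2:
        raise ValueError("common average reference needs at least 2 non-excluded channels")
    data = rec.data[keep]
    data = data - data.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=rec.fs, channels=[rec.channels[i] for i in keep])


def resample(rec: Recording, new_fs: float) -> Recording:
    """Downsample with an FIR antialiasing low-pass (polyphase resampling)."""
    if new_fs > rec.fs:
        raise ValueError("upsampling not supported")
    if new_fs == rec.fs:
        return rec.with_data(rec.data.copy())
    from fractions import Fraction

    frac = Fraction(new_fs / rec.fs).limit_denominator(1000)
    data = scipy.signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    n_target = int(round(rec.n_samples * new_fs / rec.fs))
    data = data[:, :n_target]
    return rec.with_data(data, fs=new_fs)


def trim_edges(rec: Recording, trim_s: float = 1.0) -> Recording:
    """Drop filter transients at both recording edges before epoching."""
    n = int(round(trim_s * rec.fs))
    if 2 * n >= rec.n_samples:
        raise ValueError("recording too short to trim edges")
    return rec.with_data(rec.data[:, n : rec.n_samples - n])


def preprocess_chain(
    rec: Recording,
    notch_scheme: str = "us_60",
    target_fs: float | None = None,
    highpass_cutoff: float = 0.5,
    order: int = 6,
) -> Recording:
    rec = highpass_dc_correct(rec, highpass_cutoff, order)
    rec = notch_line_noise(rec, notch_scheme, order)
    rec = common_average_reference(rec)
    if target_fs is not None and target_fs < rec.fs:
        rec = resample(rec, target_fs)
    return rec


def extract_epochs(
    rec: Recording,
    events: pd.DataFrame,
    window_rule: str = "cue_window",
    pad_s: float = 0.25,
    conditions: list[str] | None = None,
) -> Epochs:
    """Slice equal-length epochs out of a recording.

    ``cue_window`` uses ``[onset_s, offset_s)``; ``production_window`` pads
    the expected production interval by ``pad_s`` on both ends, i.e.
    ``[expected_onset_s - pad_s, expected_offset_s + pad_s)``.  All selected
    events must yield the same epoch length (zero-padding is forbidden).
    """
    if window_rule not in ("cue_window", "production_window"):
        raise ValueError(f"unknown window rule {window_rule!r}")
    rows = events if conditions is None else events[events["condition"].isin(conditions)]
    if len(rows) == 0:
        raise ValueError("no events selected")
    starts, n_samp = [], None
    for _, row in rows.iterrows():
        if window_rule == "cue_window":
            t0, t1 = row["onset_s"], row["offset_s"]
        else:
            t0 = row["expected_onset_s"] - pad_s
            t1 = row["expected_offset_s"] + pad_s
            if not (np.isfinite(t0) and np.isfinite(t1)):
                raise ValueError(
                    f"trial_id {row['trial_id']}: production window requires expected times"
                )
        i0 = int(round(t0 * rec.fs))
        n = int(round((t1 - t0) * rec.fs))
        if i0 < 0 or i0 + n > rec.n_samples:
            raise ValueError(f"trial_id {row['trial_id']}: window exceeds recording bounds")
        if n_samp is None:
            n_samp = n
        elif n != n_samp:
            raise ValueError(
                f"trial_id {row['trial_id']}: epoch length {n} differs from {n_samp}; "
                "zero-padding is forbidden"
            )
        starts.append(i0)
    data = np.stack([rec.data[:, i0 : i0 + n_samp] for i0 in starts])
    anchor = "cue" if window_rule == "cue_window" else "expected_production"
    return Epochs(
        data=data,
        fs=rec.fs,
        conditions=rows["condition"].to_numpy(dtype=object),
        items=rows["item"].to_numpy(dtype=object),
        trial_ids=rows["trial_id"].to_numpy(),
        channels=list(rec.channels),
        window=(0.0, n_samp / rec.fs) if window_rule == "cue_window" else (-pad_s, n_samp / rec.fs - pad_s),
        anchor=anchor,
    )


def reject_artifact_epochs(ep: Epochs, sd_threshold: float = 8.0) -> tuple[Epochs, np.ndarray]:
    """Drop trials whose peak amplitude exceeds ``sd_threshold`` robust SDs.

    The robust SD is 1.4826 x the median absolute deviation, per channel
    across all trials.  Stands in for visual trial rejection.
    """
    flat = ep.data.transpose(1, 0, 2).reshape(ep.data.shape[1], -1)
    med = np.median(flat, axis=1, keepdims=True)
    mad = np.median(np.abs(flat - med), axis=1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd[robust_sd == 0] = np.inf
    peak = np.abs(ep.data - med[None, :, :]).max(axis=2)  # trials x channels
    bad = (peak > sd_threshold * robust_sd.T).any(axis=1)
    if bad.any():
        logger.info("rejecting %d/%d trials exceeding %.1f robust SD", bad.sum(), len(bad), sd_threshold)
    return ep.select(~bad), bad


def acoustic_contamination_check(
    rec: Recording,
    audio: np.ndarray,
    audio_fs: float,
    window_s: float = 0.25,
    n_perm: int = 200,
    percentile: float = 99.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Screen channels for acoustic leakage of the participant's voice.

    Both audio and neural signals are reduced to spectrogram magnitudes on a
    common time grid; a channel's contamination score is the maximum over
    frequency bins of the correlation across time frames between the audio
    and neural spectrograms.  A channel is flagged when its score exceeds the
    chosen percentile of a null built by circularly shifting the audio frames.
    """
    rng = np.random.default_rng() if rng is None else rng
    if audio_fs != rec.fs:
        from fractions import Fraction

        frac = Fraction(rec.fs / audio_fs).limit_denominator(1000)
        audio = scipy.signal.resample_poly(audio, frac.numerator, frac.denominator)
    if abs(len(audio) - rec.n_samples) > rec.fs * 0.5:
        raise ValueError("audio and neural durations differ beyond tolerance")
    n = min(len(audio), rec.n_samples)
    nperseg = int(round(window_s * rec.fs))
    noverlap = nperseg // 2
    _, _, s_audio = scipy.signal.spectrogram(audio[:n], fs=rec.fs, nperseg=nperseg, noverlap=noverlap)
    if not np.any(s_audio > 0):  # silent audio: nothing can be contaminated
        return pd.DataFrame(
            {"channel": rec.channel_names(), "score": 0.0, "threshold": np.inf, "flagged": False}
        )

    def _corr_max(s_ch: np.ndarray, s_au: np.ndarray) -> float:
        a = s_ch - s_ch.mean(axis=1, keepdims=True)
        b = s_au - s_au.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a * b).sum(axis=1) / denom
        r = np.nan_to_num(r)
        return float(r.max())

    n_frames = s_audio.shape[1]
    shifts = rng.integers(1, n_frames, size=n_perm)
    rows = []
    for ci, name in enumerate(rec.channel_names()):
        _, _, s_ch = scipy.signal.spectrogram(
            rec.data[ci, :n], fs=rec.fs, nperseg=nperseg, noverlap=noverlap
        )
        score = _corr_max(s_ch, s_audio)
        null = np.array([_corr_max(s_ch, np.roll(s_audio, s, axis=1)) for s in shifts])
        thr = float(np.percentile(null, percentile))
        rows.append({"channel": name, "score": score, "threshold": thr, "flagged": score > thr})
    return pd.DataFrame(rows)
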