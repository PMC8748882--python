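"""Morlet band-power features, effect-size maps and task-vs-baseline tests.

Band power is the mean over in-band wavelet frequencies and epoch samples of
the magnitude (not squared power) of the analytic Morlet transform, with no
per-band normalization.  Effect sizes are Cohen's d with the pooled standard
deviation, tested with a two-tailed two-sample t-test and corrected with the
Benjamini-Hochberg FDR step-up procedure over all (channel, band) cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .core_io import DEFAULT_BANDS, Epochs, FeatureTable

logger = logging.getLogger("imagispeech")


@dataclass
class BandPowerTable:
    """Band magnitudes ``values[trial, channel, band]`` with descriptors."""

    values: np.ndarray
    bands: list  # (name, f_low, f_high)
    channels: list
    trials: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("band magnitudes must be non-negative")

    def to_feature_table(self) -> FeatureTable:
        n_tr, n_ch, n_b = self.values.shape
        desc = pd.DataFrame(
            {
                "channel": [c.name for c in self.channels for _ in self.bands],
                "band": [b[0] for _ in self.channels for b in self.bands],
            }
        )
        return FeatureTable(
            values=self.values.reshape(n_tr, n_ch * n_b),
            descriptors=desc,
            trials=self.trials.copy(),
        )


def band_frequencies(
    band: tuple[float, float], step: float = 1.0, bha_step: float = 2.0
) -> np.ndarray:
    """In-band frequency grid: 1 Hz steps, 2 Hz within the high-frequency band."""
    lo, hi = band
    use = bha_step if hi >= 80 else step
    return np.arange(lo, hi + 1e-9, use)


def _morlet_magnitude(data: np.ndarray, fs: float, freqs: np.ndarray, cycles: int) -> np.ndarray:
    """|W| of the analytic Morlet transform, shape (trials, channels, freqs, samples).

    Epochs shorter than the longest wavelet are reflection-padded and cropped
    back after the transform: reflection continues the in-band amplitude into
    the pad, so the epoch-mean magnitude stays comparable across epochs of
    different lengths (zero padding would attenuate short epochs more).
    """
    from mne.time_frequency import tfr_array_morlet

    n = data.shape[-1]
    # mne builds wavelets spanning +-5 SD of the Gaussian envelope
    sigma_t = cycles / (2 * np.pi * freqs.min())
    half = int(np.ceil(5 * sigma_t * fs)) + 1
    pad = max(0, half - n // 2 + 1)
    if pad:
        data = np.pad(data, [(0, 0), (0, 0), (pad, pad)], mode="reflect")
    out = tfr_array_morlet(
        data, sfreq=fs, freqs=freqs, n_cycles=cycles, output="complex", verbose="error"
    )
    if pad:
        out = out[..., pad : pad + n]
    return np.abs(out)


def wavelet_band_power(
    epochs: Epochs,
    bands: dict | None = None,
    cycles: int = 7,
    freq_step: float = 1.0,
    bha_freq_step: float = 2.0,
) -> BandPowerTable:
    """Mean in-band Morlet magnitude per trial and channel.

    Requires the epoch to hold at least 3 cycles of the lowest analysis
    frequency; rejects bands reaching the Nyquist frequency.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    f_max = max(hi for _, hi in bands.values())
    # the epoch must hold >= 3 cycles of the slowest band's center frequency
    # (a 0.5 s baseline then just accommodates the 4-8 Hz band)
    f_center_min = min(0.5 * (lo + hi) for lo, hi in bands.values())
    if epochs.n_samples / epochs.fs < 3.0 / f_center_min - 1e-9:
        raise ValueError("epoch shorter than 3 cycles of the lowest band")
    if f_max >= epochs.fs / 2:
        raise ValueError("band extends to or beyond Nyquist")
    grids = {
        name: band_frequencies(rng, freq_step, bha_freq_step) for name, rng in bands.items()
    }
    values = np.empty((epochs.n_trials, len(epochs.channels), len(bands)))
    for bi, name in enumerate(bands):
        # per-band transform so each band only pays its own wavelet padding
        mag = _morlet_magnitude(epochs.data, epochs.fs, grids[name], cycles)
        values[:, :, bi] = mag.mean(axis=(2, 3))
    trials = pd.DataFrame(
        {
            "trial_id": epochs.trial_ids,
            "condition": epochs.conditions.astype(str),
            "item": epochs.items.astype(str),
        }
    )
    return BandPowerTable(
        values=values,
        bands=[(name, bands[name][0], bands[name][1]) for name in bands],
        channels=list(epochs.channels),
        trials=trials,
        provenance={"cycles": cycles, "freq_step": freq_step, "bha_freq_step": bha_freq_step,
                    "window": list(epochs.window), "anchor": epochs.anchor},
    )


def wavelet_band_power_windows(
    rec,
    events: pd.DataFrame,
    bands: dict | None = None,
    cycles: int = 7,
    freq_step: float = 1.0,
    bha_freq_step: float = 2.0,
    conditions=None,
) -> BandPowerTable:
    """Band power from the continuous recording, averaged per event window.

    The Morlet transform runs on the full time series and its magnitude is
    averaged within each event's ``[onset_s, offset_s)`` window, so short
    windows carry no epoch-edge artifacts and windows of different lengths
    (e.g. 0.5 s baselines vs 1 s task periods) are directly comparable.
    """
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    f_max = max(hi for _, hi in bands.values())
    if f_max >= rec.fs / 2:
        raise ValueError("band extends to or beyond Nyquist")
    rows = events if conditions is None else events[events["condition"].isin(conditions)]
    if len(rows) == 0:
        raise ValueError("no events selected")
    bounds = []
    for _, row in rows.iterrows():
        i0 = int(round(row["onset_s"] * rec.fs))
        i1 = int(round(row["offset_s"] * rec.fs))
        if i0 < 0 or i1 > rec.n_samples or i1 <= i0:
            raise ValueError(f"trial_id {row['trial_id']}: window exceeds recording bounds")
        bounds.append((i0, i1))
    grids = {name: band_frequencies(r, freq_step, bha_freq_step) for name, r in bands.items()}
    values = np.empty((len(bounds), rec.n_channels, len(bands)))
    for ci in range(rec.n_channels):
        chunk = rec.data[None, ci : ci + 1, :]
        for bi, name in enumerate(bands):
            mag = _morlet_magnitude(chunk, rec.fs, grids[name], cycles)[0, 0]
            band_mean = mag.mean(axis=0)  # over in-band frequencies
            for ti, (i0, i1) in enumerate(bounds):
                values[ti, ci, bi] = band_mean[i0:i1].mean()
    trials = pd.DataFrame(
        {
            "trial_id": rows["trial_id"].to_numpy(),
            "condition": rows["condition"].to_numpy(),
            "item": rows["item"].to_numpy(),
        }
    )
    return BandPowerTable(
        values=values,
        bands=[(name, bands[name][0], bands[name][1]) for name in bands],
        channels=list(rec.channels),
        trials=trials,
        provenance={"cycles": cycles, "freq_step": freq_step,
                    "bha_freq_step": bha_freq_step, "windows": "event"},
    )


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, significance flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def pooled_sd(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = len(x1), len(x2)
    s1, s2 = np.var(x1, ddof=1), np.var(x2, ddof=1)
    return float(np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)))


def cohens_d(x1: np.ndarray, x2: np.ndarray) -> float:
    """(mean1 - mean2) / pooled SD; positive when group 1 exceeds group 2."""
    s = pooled_sd(x1, x2)
    if s == 0:
        return np.nan
    return float((np.mean(x1) - np.mean(x2)) / s)


def cohens_d_map(
    task: BandPowerTable, baseline: BandPowerTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(channel, band) effect size of task vs baseline with BH-corrected t-tests.

    d is positive when the task mean exceeds the baseline mean.  Cells with
    zero pooled variance are excluded from the FDR family and flagged invalid.
    """
    if task.values.shape[1:] != baseline.values.shape[1:]:
        raise ValueError("task and baseline tables must share channels and bands")
    if task.values.shape[0] < 2 or baseline.values.shape[0] < 2:
        raise ValueError("need at least 2 trials per group")
    rows = []
    for ci, ch in enumerate(task.channels):
        for bi, (bname, lo, hi) in enumerate(task.bands):
            x1 = task.values[:, ci, bi]
            x2 = baseline.values[:, ci, bi]
            s = pooled_sd(x1, x2)
            if s == 0:
                logger.info("zero pooled variance for (%s, %s); excluded", ch.name, bname)
                rows.append(dict(channel=ch.name, band=bname, d=np.nan, p=np.nan, valid=False,
                                 mean_task=np.mean(x1), mean_baseline=np.mean(x2),
                                 var_task=np.var(x1, ddof=1), var_baseline=np.var(x2, ddof=1),
                                 n_task=len(x1), n_baseline=len(x2), pooled_sd=s))
                continue
            d = (np.mean(x1) - np.mean(x2)) / s
            t = scipy.stats.ttest_ind(x1, x2, equal_var=True)
            rows.append(dict(channel=ch.name, band=bname, d=float(d), p=float(t.pvalue),
                             valid=True,
                             mean_task=float(np.mean(x1)), mean_baseline=float(np.mean(x2)),
                             var_task=float(np.var(x1, ddof=1)),
                             var_baseline=float(np.var(x2, ddof=1)),
                             n_task=len(x1), n_baseline=len(x2), pooled_sd=float(s)))
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["significant"] = False
    valid = df["valid"].to_numpy()
    if valid.any():
        q, rej = bh_fdr(df.loc[valid, "p"].to_numpy(), alpha=alpha)
        df.loc[valid, "q"] = q
        df.loc[valid, "significant"] = rej
    return df


def low_frequency_amplitude(
    epochs: Epochs, cutoff_hz: float = 20.0, order: int = 8
) -> np.ndarray:
    """Low-pass-filtered amplitude time series, one concatenated vector per trial.

    Zero-phase Butterworth low-pass below ``cutoff_hz``; features are signal
    amplitude (not power), concatenated across channels.
    """
    if epochs.fs <= 2 * cutoff_hz:
        raise ValueError("sampling rate too low for the requested cutoff")
    from .preprocess import _filtfilt, _sos

    sos = _sos("lowpass", cutoff_hz, order, epochs.fs)
    filt = _filtfilt(sos, epochs.data)
    return filt.reshape(epochs.n_trials, -1)


def band_amplitude_timeseries(
    epochs: Epochs,
    band: tuple[float, float],
    cycles: int = 7,
    freq_step: float = 1.0,
    bha_freq_step: float = 2.0,
) -> np.ndarray:
    """Time-resolved in-band Morlet magnitude, concatenated per trial.

    Used for task discrimination from concatenated power time series.
    """
    freqs = band_frequencies(band, freq_step, bha_freq_step)
    mag = _morlet_magnitude(epochs.data, epochs.fs, freqs, cycles)
    ts = mag.mean(axis=2)  # trials x channels x samples
    return ts.reshape(epochs.n_trials, -1)
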