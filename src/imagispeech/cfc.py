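"""Peak-anchored phase-amplitude coupling and its surrogate statistics.

The modulating phase is taken from a narrow band centered on a detected
spectral peak (bandwidth half the width of the band the peak lies in); the
modulated amplitude comes from a carrier band widened when needed to contain
the modulation sidebands.  Coupling strength is the Kullback-Leibler-based
modulation index over an 18-bin phase histogram, MI = KL / log(n_bins), which
is 0 for a flat amplitude profile and 1 when all amplitude concentrates in a
single phase bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.special
import scipy.stats

from .core_io import (
    DEFAULT_BANDS,
    DEFAULT_CARRIERS,
    PHASE_BANDWIDTHS,
    Epochs,
    FeatureTable,
)
from .preprocess import _filtfilt, _sos

logger = logging.getLogger("imagispeech")

EPS_FLOOR = 1e-12

#: A local maximum of the log spectrum counts as a peak only when it rises
#: above the fitted 1/f trend by this many SDs of the fit residuals.  Set so
#: that pure 1/f noise yields a peak in under ~5% of cases while oscillatory
#: peaks at the SNRs of interest are always found.
PEAK_PROMINENCE_SD = 3.0

#: (phase band, carrier band) combinations analysed: the carrier band must
#: start at or above the top of the phase band.
DEFAULT_PAIRS = (
    ("theta", "beta"),
    ("theta", "gamma"),
    ("theta", "bha"),
    ("low_beta", "gamma"),
    ("low_beta", "bha"),
    ("low_gamma", "bha"),
)


@dataclass
class SpectralPeak:
    """A spectral peak within a modulating band, or its recorded absence."""

    channel: str
    band: str
    peak_freq: float | None
    passband: tuple[float, float] | None


@dataclass
class CFCEstimate:
    """Surrogate-referenced MI contrast for one (channel, phase, carrier) triple."""

    channel: str
    phase_band: str
    amp_band: str
    mi_task: float
    mi_baseline: float
    x_d: float
    surrogate_mean: float
    surrogate_sd: float
    z: float
    p: float
    peak_freq: float | None
    bandwidth_limited: bool
    valid: bool
    n_bins: int = 18
    n_surrogates: int = 200


# ---------------------------------------------------------------------------
# peak detection


def _robust_loglog_fit(freqs: np.ndarray, log_psd: np.ndarray) -> tuple[np.ndarray, float]:
    """1/f trend of the log spectrum: straight line in log-log coordinates,
    refit once without gross outliers (peaks).  Returns (trend, residual SD)."""
    x = np.log10(freqs)
    coef = np.polyfit(x, log_psd, 1)
    resid = log_psd - np.polyval(coef, x)
    sd = resid.std()
    keep = np.abs(resid) <= 2 * sd if sd > 0 else np.ones_like(resid, dtype=bool)
    if keep.sum() >= 2:
        coef = np.polyfit(x[keep], log_psd[keep], 1)
        resid = log_psd - np.polyval(coef, x)
        sd = resid[keep].std()
    return np.polyval(coef, x), sd


def _find_peak_in_spectrum(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float],
    bandwidth: float,
    channel: str = "",
    band_name: str = "",
) -> SpectralPeak:
    fit_mask = (freqs >= 2.0) & (freqs <= min(200.0, freqs[-1]))
    log_psd = np.log10(np.maximum(psd, np.finfo(float).tiny))
    trend, resid_sd = _robust_loglog_fit(freqs[fit_mask], log_psd[fit_mask])
    excess = np.full_like(log_psd, -np.inf)
    excess[fit_mask] = log_psd[fit_mask] - trend
    peaks, _ = scipy.signal.find_peaks(log_psd)
    in_band = [i for i in peaks if band[0] <= freqs[i] <= band[1]]
    prominent = [i for i in in_band if excess[i] > PEAK_PROMINENCE_SD * resid_sd]
    if not prominent:
        return SpectralPeak(channel=channel, band=band_name, peak_freq=None, passband=None)
    best = max(prominent, key=lambda i: log_psd[i])
    f0 = float(freqs[best])
    return SpectralPeak(
        channel=channel,
        band=band_name,
        peak_freq=f0,
        passband=(f0 - bandwidth / 2.0, f0 + bandwidth / 2.0),
    )


def find_spectral_peak(
    signal: np.ndarray,
    fs: float,
    band_name: str,
    band: tuple[float, float] | None = None,
    channel: str = "",
) -> SpectralPeak:
    """Maximal-amplitude peak of the Welch log spectrum within a band.

    Absence (no local maximum exceeding the fitted 1/f trend by one residual
    SD) is a value, not an error.
    """
    signal = np.asarray(signal)
    if len(signal) < 4 * fs:
        raise ValueError("need at least 4 s of signal for peak detection")
    band = DEFAULT_BANDS[band_name] if band is None else band
    nperseg = int(min(len(signal), 2 * fs))
    freqs, psd = scipy.signal.welch(signal, fs=fs, nperseg=nperseg)
    return _find_peak_in_spectrum(freqs, psd, band, PHASE_BANDWIDTHS[band_name], channel, band_name)


def find_spectral_peak_epochs(
    *data: np.ndarray, fs: float, band_name: str, band: tuple[float, float] | None = None,
    channel: str = "", nperseg: int | None = None,
) -> SpectralPeak:
    """Peak detection from one or more epoch sets (periodograms averaged).

    Epoch sets of different lengths (e.g. task and baseline windows) share a
    common Welch segment length so their spectra average on one grid.
    """
    arrays = [np.atleast_2d(np.asarray(d)) for d in data]
    band = DEFAULT_BANDS[band_name] if band is None else band
    if nperseg is None:
        nperseg = min(a.shape[-1] for a in arrays)
    psds, weights = [], []
    for a in arrays:
        freqs, psd = scipy.signal.welch(a, fs=fs, nperseg=nperseg, axis=-1)
        psds.append(psd.mean(axis=0))
        weights.append(a.shape[0])
    psd = np.average(psds, axis=0, weights=weights)
    mask = freqs > 0
    return _find_peak_in_spectrum(
        freqs[mask], psd[mask], band, PHASE_BANDWIDTHS[band_name], channel, band_name
    )


# ---------------------------------------------------------------------------
# phase / amplitude extraction


def widen_carrier_band(
    amp_band: tuple[float, float], phase_band_high: float, fs: float
) -> tuple[tuple[float, float], bool]:
    """Carrier band wide enough to contain the modulation sidebands.

    A carrier modulated at frequency fp carries sidebands at +-fp around each
    carrier component, so the carrier bandwidth must reach 2*fp; when the
    nominal band is too narrow it is widened symmetrically about its center
    (clipped below Nyquist) and flagged as bandwidth-limited.
    """
    lo, hi = amp_band
    needed = 2.0 * phase_band_high
    limited = (hi - lo) < needed
    if limited:
        center = 0.5 * (lo + hi)
        lo = center - needed / 2.0
        hi = center + needed / 2.0
    hi = min(hi, 0.95 * fs / 2.0)
    lo = max(lo, 1.0)
    return (lo, hi), limited


def phase_amp_series(
    signal: np.ndarray,
    fs: float,
    peak: SpectralPeak,
    amp_band: tuple[float, float],
    phase_band_high: float | None = None,
    order: int = 6,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float], bool]:
    """Instantaneous phase of the peak band and amplitude of the carrier band.

    Both come from the Hilbert transform of centered, zero-phase band-pass
    filtered signals.  Returns (phase, amplitude, carrier band used, limited).
    """
    if peak.peak_freq is None or peak.passband is None:
        raise ValueError("spectral peak absent; coupling cannot be estimated")
    signal = np.asarray(signal, dtype=float)
    if phase_band_high is None:
        phase_band_high = DEFAULT_BANDS[peak.band][1] if peak.band in DEFAULT_BANDS else peak.passband[1]
    lo_p = max(peak.passband[0], 0.1)
    sos_p = _sos("bandpass", (lo_p, peak.passband[1]), order, fs)
    narrow = _filtfilt(sos_p, signal)
    narrow = narrow - narrow.mean(axis=-1, keepdims=True)
    phase = np.angle(scipy.signal.hilbert(narrow, axis=-1))
    band, limited = widen_carrier_band(amp_band, phase_band_high, fs)
    sos_a = _sos("bandpass", band, order, fs)
    wide = _filtfilt(sos_a, signal)
    wide = wide - wide.mean(axis=-1, keepdims=True)
    amplitude = np.abs(scipy.signal.hilbert(wide, axis=-1))
    return phase, amplitude, band, limited


# ---------------------------------------------------------------------------
# modulation index


def phase_bin_profile(phases: np.ndarray, amplitudes: np.ndarray, n_bins: int = 18) -> np.ndarray:
    """Mean amplitude per phase bin over [-pi, pi); empty bins yield 0."""
    phases = np.asarray(phases).ravel()
    amplitudes = np.asarray(amplitudes).ravel()
    if phases.size == 0:
        raise ValueError("need at least one sample")
    idx = np.floor((phases + np.pi) / (2 * np.pi) * n_bins).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amplitudes, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    profile = np.zeros(n_bins)
    nz = counts > 0
    profile[nz] = sums[nz] / counts[nz]
    return profile


def mi_from_profile(profile: np.ndarray) -> float:
    """MI = KL(P || uniform) / log(n_bins) of a normalized amplitude profile."""
    profile = np.asarray(profile, dtype=float)
    n_bins = len(profile)
    if np.any(profile < 0):
        raise ValueError("amplitude profile must be non-negative")
    total = profile.sum()
    if total <= 0:
        return 0.0
    p = profile / total
    # bins below the epsilon floor contribute exactly 0 (the p log p limit)
    entropy_terms = scipy.special.xlogy(np.where(p > EPS_FLOOR, p, 0.0), p)
    mi = (np.log(n_bins) + entropy_terms.sum()) / np.log(n_bins)
    return float(np.clip(mi, 0.0, 1.0))


def modulation_index(phases: np.ndarray, amplitudes: np.ndarray, n_bins: int = 18) -> float:
    """MI of the trial-averaged 18-bin phase-amplitude histogram.

    2-D inputs are treated as (epochs, samples): the per-epoch histograms
    are averaged across epochs before the KL divergence is taken.
    """
    phases = np.asarray(phases)
    amplitudes = np.asarray(amplitudes)
    if phases.ndim == 2:
        profiles = np.stack(
            [phase_bin_profile(ph, am, n_bins) for ph, am in zip(phases, amplitudes)]
        )
        return mi_from_profile(profiles.mean(axis=0))
    return mi_from_profile(phase_bin_profile(phases, amplitudes, n_bins))


# ---------------------------------------------------------------------------
# surrogate contrast


def mi_contrast_from_profiles(
    task_profiles: np.ndarray,
    baseline_profiles: np.ndarray,
    n_surrogates: int = 200,
    rng: np.random.Generator | None = None,
) -> dict:
    """MI difference with a label-permutation surrogate null.

    Inputs are per-epoch phase-bin profiles.  The observed statistic is
    ``x_d = MI(task) - MI(baseline)`` from the pool-averaged profiles; each
    surrogate permutes the epoch-to-condition assignment between the task and
    baseline pools and recomputes the difference.  z-scores x_d against the
    surrogate distribution; the one-tailed p comes from the normal CDF.
    """
    rng = np.random.default_rng() if rng is None else rng
    task_profiles = np.atleast_2d(task_profiles)
    baseline_profiles = np.atleast_2d(baseline_profiles)
    n_task = task_profiles.shape[0]
    pool = np.concatenate([task_profiles, baseline_profiles], axis=0)
    mi_task = mi_from_profile(task_profiles.mean(axis=0))
    mi_base = mi_from_profile(baseline_profiles.mean(axis=0))
    x_d = mi_task - mi_base
    surr = np.empty(n_surrogates)
    for s in range(n_surrogates):
        perm = rng.permutation(pool.shape[0])
        a = pool[perm[:n_task]]
        b = pool[perm[n_task:]]
        surr[s] = mi_from_profile(a.mean(axis=0)) - mi_from_profile(b.mean(axis=0))
    s_sd = surr.std(ddof=1)
    if s_sd == 0:
        return dict(mi_task=mi_task, mi_baseline=mi_base, x_d=x_d,
                    surrogate_mean=float(surr.mean()), surrogate_sd=0.0,
                    z=np.nan, p=np.nan, valid=False)
    z = (x_d - surr.mean()) / s_sd
    p = float(scipy.stats.norm.sf(z))
    return dict(mi_task=mi_task, mi_baseline=mi_base, x_d=float(x_d),
                surrogate_mean=float(surr.mean()), surrogate_sd=float(s_sd),
                z=float(z), p=p, valid=True)


def _epoch_profiles(
    data: np.ndarray,
    fs: float,
    peak: SpectralPeak,
    amp_band: tuple[float, float],
    phase_band_high: float,
    n_bins: int = 18,
) -> tuple[np.ndarray, bool]:
    phase, amp, _, limited = phase_amp_series(
        data, fs, peak, amp_band, phase_band_high=phase_band_high
    )
    profiles = np.stack(
        [phase_bin_profile(ph, am, n_bins) for ph, am in zip(np.atleast_2d(phase), np.atleast_2d(amp))]
    )
    return profiles, limited


def mi_contrast_zscore(
    task: Epochs,
    baseline: Epochs,
    channel: str,
    phase_band: str,
    amp_band_name: str,
    n_surrogates: int = 200,
    n_bins: int = 18,
    rng: np.random.Generator | None = None,
    phase_bands: dict | None = None,
    amp_bands: dict | None = None,
) -> CFCEstimate:
    """Surrogate-referenced MI contrast for one channel and band pair.

    The spectral peak is detected on the pooled task+baseline epochs; if no
    peak exists, the estimate is returned marked missing.
    """
    if task.n_trials < 5 or baseline.n_trials < 5:
        raise ValueError("need at least 5 epochs per condition")
    phase_bands = dict(DEFAULT_BANDS) if phase_bands is None else phase_bands
    amp_bands = dict(DEFAULT_CARRIERS) if amp_bands is None else amp_bands
    ci = [c.name for c in task.channels].index(channel)
    peak = find_spectral_peak_epochs(
        task.data[:, ci, :], baseline.data[:, ci, :], fs=task.fs, band_name=phase_band,
        band=phase_bands[phase_band], channel=channel,
    )
    if peak.peak_freq is None:
        return CFCEstimate(channel=channel, phase_band=phase_band, amp_band=amp_band_name,
                           mi_task=np.nan, mi_baseline=np.nan, x_d=np.nan,
                           surrogate_mean=np.nan, surrogate_sd=np.nan, z=np.nan, p=np.nan,
                           peak_freq=None, bandwidth_limited=False, valid=False,
                           n_bins=n_bins, n_surrogates=n_surrogates)
    ph_hi = phase_bands[phase_band][1]
    task_profiles, limited = _epoch_profiles(
        task.data[:, ci, :], task.fs, peak, amp_bands[amp_band_name], ph_hi, n_bins
    )
    base_profiles, _ = _epoch_profiles(
        baseline.data[:, ci, :], baseline.fs, peak, amp_bands[amp_band_name], ph_hi, n_bins
    )
    res = mi_contrast_from_profiles(task_profiles, base_profiles, n_surrogates, rng)
    return CFCEstimate(channel=channel, phase_band=phase_band, amp_band=amp_band_name,
                       peak_freq=peak.peak_freq, bandwidth_limited=limited,
                       n_bins=n_bins, n_surrogates=n_surrogates, **res)


def cfc_map(
    task: Epochs,
    baseline: Epochs,
    pairs=DEFAULT_PAIRS,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """MI contrast z-scores for every channel and band pair, BH-corrected."""
    from .spectral import bh_fdr

    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for ch in task.channels:
        for pband, aband in pairs:
            est = mi_contrast_zscore(
                task, baseline, ch.name, pband, aband, n_surrogates=n_surrogates, rng=rng
            )
            rows.append(est.__dict__.copy())
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    df["significant"] = False
    valid = df["valid"].to_numpy()
    if valid.any():
        q, rej = bh_fdr(df.loc[valid, "p"].to_numpy(), alpha=alpha)
        df.loc[valid, "q"] = q
        df.loc[valid, "significant"] = rej
    return df


def single_trial_mi(
    epochs: Epochs,
    channel: str,
    phase_band: str,
    amp_band_name: str,
    n_bins: int = 18,
    peak: SpectralPeak | None = None,
) -> FeatureTable:
    """Per-trial MI from each trial's own 18-bin histogram (same formula)."""
    ci = [c.name for c in epochs.channels].index(channel)
    if peak is None:
        peak = find_spectral_peak_epochs(
            epochs.data[:, ci, :], fs=epochs.fs, band_name=phase_band, channel=channel
        )
    if peak.peak_freq is None:
        raise ValueError(f"no spectral peak in {phase_band} for channel {channel}")
    profiles, _ = _epoch_profiles(
        epochs.data[:, ci, :], epochs.fs, peak, DEFAULT_CARRIERS[amp_band_name],
        DEFAULT_BANDS[phase_band][1], n_bins,
    )
    mis = np.array([[mi_from_profile(pr) for pr in profiles]]).T
    desc = pd.DataFrame({"channel": [channel], "pair": [f"{phase_band}->{amp_band_name}"]})
    trials = pd.DataFrame(
        {
            "trial_id": epochs.trial_ids,
            "condition": epochs.conditions.astype(str),
            "item": epochs.items.astype(str),
        }
    )
    return FeatureTable(values=mis, descriptors=desc, trials=trials)
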