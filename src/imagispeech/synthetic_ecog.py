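"""Synthetic ECoG with known band-power effects and phase-amplitude coupling.

The generator emulates the study conditions every downstream stage is tested
against: short trials (a 0.5 s baseline preceding each ~1 s task window) at a
400-512 Hz sampling rate, a 1/f background plus line noise, condition-dependent
band-power shifts of a specified Cohen's d, and slow-phase-modulated fast
amplitude of a specified depth m.

Band oscillations are injected at the band's center frequency in *both*
baseline and task segments with per-trial amplitudes drawn from a normal
distribution; a task effect of Cohen's d shifts the task-segment amplitude
mean by ``d`` standard deviations, so the realized amplitudes themselves carry
the target effect size and the spectral stage can be checked for unbiased
recovery.  Item discriminability is injected the same way, as per-item
band-amplitude offsets (in units of the per-trial amplitude SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_BANDS,
    ChannelInfo,
    Recording,
    validate_events,
)

#: Base oscillation amplitude and its per-trial SD (microvolts).  Chosen so
#: the oscillatory component dominates the in-band background: injected
#: effect sizes are then identifiable at the trial counts used in the studies.
OSC_BASE_AMP_UV = 20.0
OSC_AMP_SD_UV = 4.0
#: Background root-mean-square amplitude (microvolts) and spectral exponent.
BACKGROUND_RMS_UV = 5.0
BACKGROUND_EXPONENT = 1.0
LINE_FREQ_HZ = 60.0
LINE_AMP_UV = 2.0
#: Transition time between segment amplitudes (seconds).  Oscillators run
#: continuously (constant phase evolution) with a piecewise-constant
#: amplitude envelope smoothed over this window, so no segment edge drops to
#: zero and short epochs are not attenuated relative to long ones.
AMP_TRANSITION_S = 0.05


@dataclass
class EffectSpec:
    """Injected effects: band-power shifts, coupling depths, item offsets.

    ``band_d``  maps (channel, band) -> target Cohen's d of task vs baseline.
    ``pac_m``   maps (channel, phase_band, amp_band) -> modulation depth m.
    ``item_band_offset`` maps item -> {band: offset}, in units of the
    per-trial amplitude SD, applied to task segments only.
    """

    band_d: dict = field(default_factory=dict)
    pac_m: dict = field(default_factory=dict)
    item_band_offset: dict = field(default_factory=dict)

    def validate(self, channel_names, bands, items) -> None:
        for (ch, band), d in self.band_d.items():
            if ch not in channel_names or band not in bands:
                raise ValueError(f"effect references unknown channel/band ({ch}, {band})")
            if not np.isfinite(d):
                raise ValueError("Cohen's d must be finite")
        for (ch, pband, aband), m in self.pac_m.items():
            if ch not in channel_names or pband not in bands or aband not in bands:
                raise ValueError(f"coupling references unknown channel/band ({ch}, {pband}, {aband})")
            if not 0.0 <= m <= 1.0:
                raise ValueError("modulation depth m must lie in [0, 1]")
        for item, offsets in self.item_band_offset.items():
            if item not in items:
                raise ValueError(f"effect references unknown item {item!r}")
            for band in offsets:
                if band not in bands:
                    raise ValueError(f"item offset references unknown band {band!r}")


@dataclass
class GroundTruth:
    """Realized per-trial band amplitudes and injected coupling depths."""

    trials: pd.DataFrame
    pac_m: dict
    seed: int | None = None


def generate_background(
    duration_s: float,
    fs: float,
    one_over_f_exponent: float = BACKGROUND_EXPONENT,
    line_freq: float | None = LINE_FREQ_HZ,
    line_amp: float = LINE_AMP_UV,
    rms: float = BACKGROUND_RMS_UV,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean 1/f^exponent background plus an optional line component.

    The 1/f shape is produced by spectral shaping of white noise, so the
    log-spectrum slope equals ``-one_over_f_exponent`` in expectation.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if line_freq is not None and line_amp > 0 and line_freq >= fs / 2:
        raise ValueError("line frequency must be below Nyquist")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-one_over_f_exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    x -= x.mean()
    std = x.std()
    if std > 0:
        x *= rms / std
    if line_freq is not None and line_amp > 0:
        t = np.arange(n) / fs
        x += line_amp * np.sin(2 * np.pi * line_freq * t + rng.uniform(0, 2 * np.pi))
    return x


def generate_pac_signal(
    f_phase: float,
    f_amp: float,
    m: float,
    duration_s: float,
    fs: float,
    snr: float = 5.0,
    amp: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Slow oscillation plus a carrier whose amplitude follows the slow phase.

    The carrier is ``amp * (1 + m cos phi(t)) * cos(2 pi f_amp t)`` with
    ``phi`` the phase of the ``f_phase`` oscillation; a 1/f background is
    added at the requested amplitude SNR (RMS of the oscillatory part over
    RMS of the background).  ``snr=inf`` yields a noise-free signal.
    """
    if f_amp <= 2 * f_phase:
        raise ValueError("carrier frequency must exceed twice the phase frequency")
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation depth m must lie in [0, 1]")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng() if rng is None else rng
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phi0 = rng.uniform(0, 2 * np.pi)
    psi0 = rng.uniform(0, 2 * np.pi)
    phi = 2 * np.pi * f_phase * t + phi0
    slow = amp * np.cos(phi)
    carrier = amp * (1.0 + m * np.cos(phi)) * np.cos(2 * np.pi * f_amp * t + psi0)
    signal = slow + carrier
    if np.isfinite(snr):
        bg = generate_background(duration_s, fs, line_freq=None, rms=1.0, rng=rng)
        sig_rms = signal.std()
        signal = signal + bg * (sig_rms / snr)
    return signal


def _smooth_envelope(env: np.ndarray, fs: float) -> np.ndarray:
    """Smooth a piecewise-constant envelope with a short Hann window."""
    n_win = int(round(AMP_TRANSITION_S * fs))
    if n_win < 2:
        return env
    win = np.hanning(n_win)
    win /= win.sum()
    return np.convolve(env, win, mode="same")


def band_center(band: tuple[float, float]) -> float:
    return 0.5 * (band[0] + band[1])


def generate_dataset(
    items,
    n_trials_per_item: int,
    effects: EffectSpec | None = None,
    channels: list[ChannelInfo] | None = None,
    fs: float = 400.0,
    trial_duration_s: float = 1.0,
    baseline_duration_s: float = 0.5,
    gap_s: float = 0.25,
    condition: str = "imagined",
    bands: dict | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Recording, pd.DataFrame, GroundTruth]:
    """Generate a continuous recording with one baseline segment per trial.

    Returns the Recording, an event table with one baseline row and one task
    row per trial, and the GroundTruth of realized band amplitudes.
    """
    items = list(items)
    if n_trials_per_item < 2:
        raise ValueError("need at least 2 trials per item")
    if rng is None:
        rng = np.random.default_rng(seed)
    if channels is None:
        channels = [ChannelInfo(name=f"ch{i}") for i in range(8)]
    bands = dict(DEFAULT_BANDS) if bands is None else bands
    effects = EffectSpec() if effects is None else effects
    names = [c.name for c in channels]
    effects.validate(names, bands, items)

    order = np.repeat(np.arange(len(items)), n_trials_per_item)
    rng.shuffle(order)
    trial_items = [items[i] for i in order]
    n_trials = len(trial_items)

    seg = baseline_duration_s + trial_duration_s + gap_s
    total_s = n_trials * seg + gap_s
    n_total = int(round(total_s * fs))
    t = np.arange(n_total) / fs
    data = np.empty((len(channels), n_total))
    for ci in range(len(channels)):
        data[ci] = generate_background(total_s, fs, rng=rng)

    n_base = int(round(baseline_duration_s * fs))
    n_task = int(round(trial_duration_s * fs))
    events, records, seg_idx = [], [], []
    for k, item in enumerate(trial_items):
        base_on = gap_s + k * seg
        task_on = base_on + baseline_duration_s
        seg_idx.append((int(round(base_on * fs)), int(round(task_on * fs))))
        events.append(
            dict(trial_id=k, condition="baseline", item=item, onset_s=base_on,
                 offset_s=base_on + baseline_duration_s, expected_onset_s=np.nan,
                 expected_offset_s=np.nan)
        )
        events.append(
            dict(trial_id=k, condition=condition, item=item, onset_s=task_on,
                 offset_s=task_on + trial_duration_s, expected_onset_s=task_on,
                 expected_offset_s=task_on + trial_duration_s)
        )
        records.append({"trial_id": k, "condition": "baseline", "item": item})
        records.append({"trial_id": k, "condition": condition, "item": item})

    # smoothed indicator of task segments, for gating coupling envelopes
    task_gate = np.zeros(n_total)
    for i_b, i_t in seg_idx:
        task_gate[i_t : i_t + n_task] = 1.0
    task_gate = _smooth_envelope(task_gate, fs)

    for ci, ch in enumerate(names):
        phases = {}
        for band, band_range in bands.items():
            fc = band_center(band_range)
            phases[band] = 2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi)
        for band in bands:
            env = np.full(n_total, OSC_BASE_AMP_UV)
            for k, item in enumerate(trial_items):
                i_b, i_t = seg_idx[k]
                a_base = max(OSC_BASE_AMP_UV + OSC_AMP_SD_UV * rng.standard_normal(), 0.0)
                shift = effects.band_d.get((ch, band), 0.0) + effects.item_band_offset.get(
                    item, {}
                ).get(band, 0.0)
                a_task = max(
                    OSC_BASE_AMP_UV + OSC_AMP_SD_UV * (rng.standard_normal() + shift), 0.0
                )
                env[i_b : i_b + n_base] = a_base
                env[i_t : i_t + n_task] = a_task
                records[2 * k][f"amp_{ch}_{band}"] = a_base
                records[2 * k + 1][f"amp_{ch}_{band}"] = a_task
            env = _smooth_envelope(env, fs)
            modulator = np.ones(n_total)
            for (c, pband, aband), m in effects.pac_m.items():
                if c == ch and aband == band:
                    modulator = modulator * (1.0 + m * np.cos(phases[pband]) * task_gate)
            data[ci] += env * modulator * np.cos(phases[band])

    recording = Recording(data=data, fs=fs, channels=channels)
    event_df = validate_events(pd.DataFrame(events))
    truth = GroundTruth(trials=pd.DataFrame(records), pac_m=dict(effects.pac_m), seed=seed)
    return recording, event_df, truth
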