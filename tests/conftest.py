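"""Shared fixtures: deterministic RNGs, small synthetic inputs, EDF writing."""

from __future__ import annotations


import numpy as np
import pandas as pd
import pytest

from imagispeech.core_io import ChannelInfo, Epochs, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def channels3():
    return [
        ChannelInfo(name="ch0", roi="sensorimotor", hemisphere="L"),
        ChannelInfo(name="ch1", roi="sensorimotor", hemisphere="L"),
        ChannelInfo(name="ch2", roi="superior_temporal", hemisphere="L"),
    ]


def make_recording(data: np.ndarray, fs: float = 400.0) -> Recording:
    chans = [ChannelInfo(name=f"ch{i}") for i in range(data.shape[0])]
    return Recording(data=np.asarray(data, dtype=float), fs=fs, channels=chans)


def sinusoid_recording(freq: float, fs: float = 400.0, duration: float = 10.0,
                       amp: float = 1.0, n_channels: int = 1) -> Recording:
    t = np.arange(int(round(duration * fs))) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return make_recording(np.tile(x, (n_channels, 1)), fs)


def make_epochs(data: np.ndarray, fs: float = 400.0, items=None, conditions=None) -> Epochs:
    n_trials, n_ch, _ = data.shape
    items = ["w"] * n_trials if items is None else list(items)
    conditions = ["imagined"] * n_trials if conditions is None else list(conditions)
    return Epochs(
        data=data,
        fs=fs,
        conditions=np.array(conditions, dtype=object),
        items=np.array(items, dtype=object),
        trial_ids=np.arange(n_trials),
        channels=[ChannelInfo(name=f"ch{i}") for i in range(n_ch)],
    )


def write_minimal_edf(path, data: np.ndarray, fs: float, names: list[str]) -> None:
    """Write a standard 16-bit EDF file (1 s data records, microvolt units)."""
    data = np.asarray(data, dtype=float)
    ns, n_samples = data.shape
    spr = int(fs)  # samples per 1 s record
    n_rec = n_samples // spr
    assert n_rec * spr == n_samples, "duration must be an integer number of seconds"

    def pad(s, width):
        return s.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2020 X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8), pad(str(256 * (1 + ns)), 8),
        pad("", 44), pad(str(n_rec), 8), pad("1", 8), pad(str(ns), 4),
    ])
    phys_min, phys_max = -3276.8, 3276.7
    dig_min, dig_max = -32768, 32767
    fields = [
        [pad(n, 16) for n in names],
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(str(phys_min), 8)] * ns,
        [pad(str(phys_max), 8)] * ns,
        [pad(str(dig_min), 8)] * ns,
        [pad(str(dig_max), 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(spr), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    sig_header = b"".join(b"".join(f) for f in fields)
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as f:
        f.write(header + sig_header)
        for r in range(n_rec):
            for s in range(ns):
                f.write(digital[s, r * spr : (r + 1) * spr].tobytes())


def write_channel_tsv(path, names, roi="other", hemisphere="unknown"):
    pd.DataFrame({"name": names, "roi": roi, "hemisphere": hemisphere}).to_csv(
        path, sep="\t", index=False
    )
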