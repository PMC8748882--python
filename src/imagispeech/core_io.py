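"""Data model, file readers/writers, configuration and seeded randomness.

All on-disk metadata uses one TSV dialect: tab separator, ``.`` decimal,
UTF-8, with a header row.  Times in metadata files are seconds (floats);
sample indices are 0-based; epoch windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("imagispeech")

#: Regions of interest used throughout: sensory/motor, superior temporal,
#: middle and inferior temporal, inferior frontal cortex, or anything else.
ROIS = (
    "sensorimotor",
    "superior_temporal",
    "middle_inferior_temporal",
    "inferior_frontal",
    "other",
)
HEMISPHERES = ("L", "R", "unknown")
CONDITIONS = ("baseline", "listen", "overt", "imagined")

#: Default frequency bands (Hz): theta, low-beta, low-gamma and broadband
#: high-frequency activity.
DEFAULT_BANDS = {
    "theta": (4.0, 8.0),
    "low_beta": (12.0, 18.0),
    "low_gamma": (25.0, 35.0),
    "bha": (80.0, 150.0),
}

#: Carrier (modulated) bands for phase-amplitude coupling.
DEFAULT_CARRIERS = {
    "beta": (12.0, 25.0),
    "gamma": (25.0, 50.0),
    "bha": (80.0, 150.0),
}

#: Band-pass width (Hz) used around a detected spectral peak when extracting
#: the modulating phase: half the width of the band the peak lies in.
PHASE_BANDWIDTHS = {"theta": 2.0, "low_beta": 3.0, "low_gamma": 5.0}


@dataclass
class ChannelInfo:
    """One electrode: name, region-of-interest label, hemisphere, exclusion flag."""

    name: str
    roi: str = "other"
    hemisphere: str = "unknown"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.roi not in ROIS:
            raise ValueError(f"unknown roi {self.roi!r}; expected one of {ROIS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"unknown hemisphere {self.hemisphere!r}; expected one of {HEMISPHERES}"
            )


@dataclass
class Recording:
    """Multichannel time series in microvolts, ``data[channel, sample]``."""

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D [n_channels x n_samples]")
        if self.data.shape[0] < 1:
            raise ValueError("Recording must contain at least one channel")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata length does not match data rows")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "Recording":
        return Recording(data=data, fs=self.fs if fs is None else fs, channels=list(self.channels))


@dataclass
class Epochs:
    """Equal-length trials: ``data[trial, channel, sample]`` plus labels.

    ``window`` is the (start, end) of each epoch in seconds relative to the
    anchor; the window is half-open.  Zero-padding is forbidden: all trials
    must have exactly the same number of samples.
    """

    data: np.ndarray
    fs: float
    conditions: np.ndarray
    items: np.ndarray
    trial_ids: np.ndarray
    channels: list[ChannelInfo]
    window: tuple[float, float] = (0.0, 0.0)
    anchor: str = "cue"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Epochs data must be 3-D [trials x channels x samples]")
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.items = np.asarray(self.items, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids)
        n = self.data.shape[0]
        if not (len(self.conditions) == len(self.items) == len(self.trial_ids) == n):
            raise ValueError("label arrays must have one entry per trial")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel metadata does not match epoch channel axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask: np.ndarray) -> "Epochs":
        mask = np.asarray(mask)
        return Epochs(
            data=self.data[mask],
            fs=self.fs,
            conditions=self.conditions[mask],
            items=self.items[mask],
            trial_ids=self.trial_ids[mask],
            channels=list(self.channels),
            window=self.window,
            anchor=self.anchor,
        )


@dataclass
class FeatureTable:
    """Per-trial feature matrix with one descriptor row per feature column.

    ``descriptors`` holds at least a ``channel`` column and whatever else
    identifies the feature (``band``, ``pair`` ...); ``trials`` holds
    ``trial_id``, ``condition`` and ``item`` per row of ``values``.
    """

    values: np.ndarray
    descriptors: pd.DataFrame
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("FeatureTable values must be 2-D [trials x features]")
        if len(self.descriptors) != self.values.shape[1]:
            raise ValueError("descriptor rows must match feature columns")
        if len(self.trials) != self.values.shape[0]:
            raise ValueError("trial rows must match value rows")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with study defaults."""

    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    carriers: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CARRIERS.items()}
    )
    highpass_cutoff_hz: float = 0.5
    filter_order: int = 6
    notch_scheme: str = "us_60"
    target_fs_hz: float = 400.0
    lowfreq_cutoff_hz: float = 20.0
    lowfreq_order: int = 8
    wavelet_cycles: int = 7
    freq_step_hz: float = 1.0
    bha_freq_step_hz: float = 2.0
    n_bins: int = 18
    n_surrogates: int = 200
    n_permutations: int = 1000
    fdr_alpha: float = 0.05
    pca_variance_fraction: float = 0.95
    cv_folds: int = 10
    inner_cv_folds: int = 5
    rfe_step: float = 0.1
    svm_c: float = 1.0
    fisher_mode: str = "max"
    artifact_sd_threshold: float = 8.0
    contamination_window_s: float = 0.25
    rng_seed: int = 0
    # synthetic generator conditions
    sim_fs_hz: float = 400.0
    sim_n_channels: int = 8
    sim_n_trials_per_item: int = 20
    sim_trial_duration_s: float = 1.0
    sim_baseline_duration_s: float = 0.5
    sim_gap_s: float = 0.25
    sim_condition: str = "imagined"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if self.n_surrogates < 2 or self.n_permutations < 2:
            raise ValueError("surrogate/permutation counts must be >= 2")
        if self.fisher_mode not in ("max", "sum"):
            raise ValueError("fisher_mode must be 'max' or 'sum'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independently reproducible random substream of a global seed.

    Each stochastic stage draws from its own substream so rerunning a single
    stage reproduces its randomness regardless of what ran before.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# readers / writers


def read_channel_table(path: str | Path) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "roi", "hemisphere"}
    if not required.issubset(df.columns):
        raise ValueError(f"channel table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        excluded = str(row.get("excluded", "0")).strip().lower() in ("1", "true", "yes")
        out.append(
            ChannelInfo(
                name=str(row["name"]),
                roi=str(row["roi"]),
                hemisphere=str(row["hemisphere"]),
                excluded=excluded,
            )
        )
    return out


def write_channel_table(channels: Sequence[ChannelInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": [c.name for c in channels],
            "roi": [c.roi for c in channels],
            "hemisphere": [c.hemisphere for c in channels],
            "excluded": [int(c.excluded) for c in channels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_recording(path: str | Path, channel_table: str | Path) -> Recording:
    """Read an EDF file or a delimited matrix (+ JSON sidecar stating fs).

    Channel metadata comes from a tab-separated table with columns
    ``name/roi/hemisphere``; every recorded channel must appear in the table
    (order is preserved from the file).  EDF voltages are converted to
    microvolts.
    """
    path = Path(path)
    table = read_channel_table(channel_table)
    by_name = {c.name: c for c in table}
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        names = list(raw.ch_names)
    elif path.suffix.lower() in (".tsv", ".txt", ".csv"):
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(f"missing sidecar {sidecar} stating the sampling rate")
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        fs = float(meta["fs"])
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        names = meta.get("channels") or [c.name for c in table][: data.shape[0]]
    else:
        raise ValueError(f"unknown recording format {path.suffix!r}")
    missing = [n for n in names if n not in by_name]
    if missing or len(names) != data.shape[0]:
        raise ValueError(f"channel-name mismatch: {missing or 'count differs'}")
    if not np.all(np.isfinite(data)):
        raise ValueError("Recording contains non-finite samples")
    return Recording(data=data, fs=fs, channels=[by_name[n] for n in names])


def write_recording_matrix(rec: Recording, path: str | Path) -> None:
    """Write a recording as a tab-delimited matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.8g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"fs": rec.fs, "channels": rec.channel_names(), "units": "uV"}, indent=0),
        encoding="utf-8",
    )


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an event table (TSV, seconds), sorted by onset."""
    df = pd.read_csv(path, sep="\t")
    required = {"trial_id", "condition", "item", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    if "expected_onset_s" not in df.columns:
        df["expected_onset_s"] = np.nan
    if "expected_offset_s" not in df.columns:
        df["expected_offset_s"] = np.nan
    df = df.astype(
        {
            "trial_id": int,
            "condition": str,
            "item": str,
            "onset_s": float,
            "offset_s": float,
            "expected_onset_s": float,
            "expected_offset_s": float,
        }
    )
    return validate_events(df)


def validate_events(df: pd.DataFrame, lexicon_items: Sequence[str] | None = None) -> pd.DataFrame:
    bad = df["condition"][~df["condition"].isin(CONDITIONS)]
    if len(bad):
        raise ValueError(f"unknown condition token(s): {sorted(set(bad))}")
    late = df[df["offset_s"] <= df["onset_s"]]
    if len(late):
        raise ValueError(f"offset <= onset for trial_id(s) {late['trial_id'].tolist()}")
    if lexicon_items is not None:
        unknown = sorted(set(df["item"]) - set(lexicon_items))
        if unknown:
            raise ValueError(f"items not in lexicon: {unknown}")
    dup = df.duplicated(subset=["trial_id", "condition"])
    if dup.any():
        raise ValueError("duplicate (trial_id, condition) rows")
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_results_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV output for result tables."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# hierarchical feature container (HDF5)


def _df_to_json(df: pd.DataFrame) -> str:
    return df.to_json(orient="table", index=False)


def _df_from_json(s: str) -> pd.DataFrame:
    return pd.read_json(__import__("io").StringIO(s), orient="table")


def write_feature_table(ft: FeatureTable, path: str | Path, group: str = "features") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("values", data=ft.values, track_times=False)
        g.create_dataset("descriptors", data=_df_to_json(ft.descriptors), track_times=False)
        g.create_dataset("trials", data=_df_to_json(ft.trials), track_times=False)


def read_feature_table(path: str | Path, group: str = "features") -> FeatureTable:
    with h5py.File(path, "r") as f:
        g = f[group]
        values = np.asarray(g["values"])
        descriptors = _df_from_json(g["descriptors"][()].decode())
        trials = _df_from_json(g["trials"][()].decode())
    return FeatureTable(values=values, descriptors=descriptors, trials=trials)


def write_epochs(ep: Epochs, path: str | Path, group: str = "epochs") -> None:
    labels = pd.DataFrame(
        {
            "trial_id": ep.trial_ids,
            "condition": ep.conditions.astype(str),
            "item": ep.items.astype(str),
        }
    )
    chans = pd.DataFrame(
        {
            "name": [c.name for c in ep.channels],
            "roi": [c.roi for c in ep.channels],
            "hemisphere": [c.hemisphere for c in ep.channels],
            "excluded": [int(c.excluded) for c in ep.channels],
        }
    )
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=ep.data, track_times=False)
        g.create_dataset("labels", data=_df_to_json(labels), track_times=False)
        g.create_dataset("channels", data=_df_to_json(chans), track_times=False)
        g.attrs["fs"] = ep.fs
        g.attrs["window"] = list(ep.window)
        g.attrs["anchor"] = ep.anchor


def read_epochs(path: str | Path, group: str = "epochs") -> Epochs:
    with h5py.File(path, "r") as f:
        g = f[group]
        data = np.asarray(g["data"])
        labels = _df_from_json(g["labels"][()].decode())
        chans = _df_from_json(g["channels"][()].decode())
        fs = float(g.attrs["fs"])
        window = tuple(g.attrs["window"])
        anchor = str(g.attrs["anchor"])
    channels = [
        ChannelInfo(name=str(r["name"]), roi=str(r["roi"]), hemisphere=str(r["hemisphere"]),
                    excluded=bool(r["excluded"]))
        for _, r in chans.iterrows()
    ]
    return Epochs(
        data=data,
        fs=fs,
        conditions=labels["condition"].to_numpy(dtype=object),
        items=labels["item"].to_numpy(dtype=object),
        trial_ids=labels["trial_id"].to_numpy(),
        channels=channels,
        window=window,
        anchor=anchor,
    )
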