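"""Stage runner: simulate -> preprocess -> power / cfc / correlate / fisher
-> decode -> report, with file artifacts between stages.

Each stage reads only the artifacts of its upstream stages from the output
directory and fails with a clear error when one is missing.  All randomness
derives from named substreams of the single configured seed, so any stage
rerun with the same config and seed reproduces its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfc as cfc_mod
from . import core_io, decoding, discriminability, lexicon, preprocess, spectral
from .core_io import PipelineConfig, substream
from .synthetic_ecog import EffectSpec, generate_dataset

logger = logging.getLogger("imagispeech")

STAGES = ("simulate", "preprocess", "power", "cfc", "correlate", "fisher", "decode", "report")


def _require(out: Path, *names: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise FileNotFoundError(f"missing upstream artifact {name!r}; run earlier stages first")


def demo_channels(n: int = 8) -> list[core_io.ChannelInfo]:
    """Half sensorimotor, half superior temporal, all left hemisphere."""
    rois = ["sensorimotor"] * (n // 2) + ["superior_temporal"] * (n - n // 2)
    return [core_io.ChannelInfo(name=f"ch{i}", roi=rois[i], hemisphere="L") for i in range(n)]


def demo_effects(items, channels) -> EffectSpec:
    """Default injected effects: one strong high-frequency task effect, one
    low-beta suppression, and item-discriminating offsets on two channels."""
    names = [c.name for c in channels]
    offsets = {
        item: {"bha": (i - (len(items) - 1) / 2.0), "theta": ((len(items) - 1) / 2.0 - i) / 2.0}
        for i, item in enumerate(items)
    }
    return EffectSpec(
        band_d={(names[0], "bha"): 1.0, (names[1], "low_beta"): -0.8},
        pac_m={(names[2], "theta", "bha"): 0.8},
        item_band_offset=offsets,
    )


def run_pipeline(
    config: PipelineConfig, stage: str, out_dir: str | Path, seed: int | None = None
) -> None:
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    logger.info("stage=%s config_hash=%s rng_seed=%d", stage, config.config_hash(), seed)
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": config.config_hash(), "rng_seed": seed, "last_stage": stage}),
        encoding="utf-8",
    )
    globals()[f"_stage_{stage}"](config, out, seed)


def _stage_simulate(config: PipelineConfig, out: Path, seed: int) -> None:
    entries = lexicon.packaged_lexicon("study1")
    items = [e.item for e in entries]
    channels = demo_channels(config.sim_n_channels)
    effects = demo_effects(items, channels)
    rec, events, truth = generate_dataset(
        items,
        config.sim_n_trials_per_item,
        effects=effects,
        channels=channels,
        fs=config.sim_fs_hz,
        trial_duration_s=config.sim_trial_duration_s,
        baseline_duration_s=config.sim_baseline_duration_s,
        gap_s=config.sim_gap_s,
        condition=config.sim_condition,
        rng=substream(seed, "simulate"),
    )
    core_io.write_recording_matrix(rec, out / "recording.tsv")
    core_io.write_channel_table(rec.channels, out / "channels.tsv")
    core_io.write_events(events, out / "events.tsv")
    core_io.write_results_tsv(truth.trials, out / "ground_truth.tsv")


def _stage_preprocess(config: PipelineConfig, out: Path, seed: int) -> None:
    _require(out, "recording.tsv", "channels.tsv", "events.tsv")
    rec = core_io.read_recording(out / "recording.tsv", out / "channels.tsv")
    events = core_io.read_events(out / "events.tsv")
    rec = preprocess.preprocess_chain(
        rec,
        notch_scheme=config.notch_scheme,
        target_fs=config.target_fs_hz,
        highpass_cutoff=config.highpass_cutoff_hz,
        order=config.filter_order,
    )
    core_io.write_recording_matrix(rec, out / "clean_recording.tsv")
    task_conditions = [c for c in events["condition"].unique() if c != "baseline"]
    task = preprocess.extract_epochs(rec, events, "cue_window", conditions=task_conditions)
    base = preprocess.extract_epochs(rec, events, "cue_window", conditions=["baseline"])
    path = out / "epochs.h5"
    if path.exists():
        path.unlink()
    core_io.write_epochs(task, path, group="task")
    core_io.write_epochs(base, path, group="baseline")


def _read_epochs_pair(out: Path):
    _require(out, "epochs.h5")
    return core_io.read_epochs(out / "epochs.h5", "task"), core_io.read_epochs(
        out / "epochs.h5", "baseline"
    )


def _bands(config: PipelineConfig) -> dict:
    return {k: tuple(v) for k, v in config.bands.items()}


def _stage_power(config: PipelineConfig, out: Path, seed: int) -> None:
    _require(out, "clean_recording.tsv", "channels.tsv", "events.tsv")
    rec = core_io.read_recording(out / "clean_recording.tsv", out / "channels.tsv")
    events = core_io.read_events(out / "events.tsv")
    task_conditions = [c for c in events["condition"].unique() if c != "baseline"]
    kw = dict(bands=_bands(config), cycles=config.wavelet_cycles,
              freq_step=config.freq_step_hz, bha_freq_step=config.bha_freq_step_hz)
    bpt_task = spectral.wavelet_band_power_windows(rec, events, conditions=task_conditions, **kw)
    bpt_base = spectral.wavelet_band_power_windows(rec, events, conditions=["baseline"], **kw)
    path = out / "band_power.h5"
    if path.exists():
        path.unlink()
    core_io.write_feature_table(bpt_task.to_feature_table(), path, group="task")
    core_io.write_feature_table(bpt_base.to_feature_table(), path, group="baseline")
    core_io.write_results_tsv(
        spectral.cohens_d_map(bpt_task, bpt_base, alpha=config.fdr_alpha),
        out / "effect_sizes.tsv",
    )


def _stage_cfc(config: PipelineConfig, out: Path, seed: int) -> None:
    task, base = _read_epochs_pair(out)
    df = cfc_mod.cfc_map(
        task, base, n_surrogates=config.n_surrogates, alpha=config.fdr_alpha,
        rng=substream(seed, "cfc"),
    )
    core_io.write_results_tsv(df.drop(columns=["valid"]), out / "cfc_map.tsv")


def _stage_correlate(config: PipelineConfig, out: Path, seed: int) -> None:
    _require(out, "band_power.h5")
    features = core_io.read_feature_table(out / "band_power.h5", group="task")
    df = discriminability.pairwise_label_correlation(
        features, n_perm=config.n_permutations, alpha=config.fdr_alpha,
        rng=substream(seed, "correlate"),
    )
    core_io.write_results_tsv(df, out / "correlation_map.tsv")


def _stage_fisher(config: PipelineConfig, out: Path, seed: int) -> None:
    _require(out, "band_power.h5", "channels.tsv")
    features = core_io.read_feature_table(out / "band_power.h5", group="task")
    channels = core_io.read_channel_table(out / "channels.tsv")
    entries = lexicon.packaged_lexicon("study1")
    df = discriminability.group_assigned_fisher(
        features, entries, channels,
        n_perm=config.n_permutations,
        variance_fraction=config.pca_variance_fraction,
        mode=config.fisher_mode,
        alpha=config.fdr_alpha,
        rng=substream(seed, "fisher"),
    )
    core_io.write_results_tsv(df, out / "fisher_distances.tsv")


def _stage_decode(config: PipelineConfig, out: Path, seed: int) -> None:
    _require(out, "band_power.h5")
    features = core_io.read_feature_table(out / "band_power.h5", group="task")
    entries = lexicon.packaged_lexicon("study1")
    rng = substream(seed, "decode")
    rows = []
    for rep in ("articulatory", "phonetic", "vocalic"):
        dist = lexicon.representation_distance_matrix(entries, rep)
        split = decoding.build_binary_classes(dist, representation=rep)
        for band in sorted(features.descriptors["band"].unique()):
            cols = features.descriptors["band"] == band
            sub = core_io.FeatureTable(
                values=features.values[:, cols.to_numpy()],
                descriptors=features.descriptors[cols].reset_index(drop=True),
                trials=features.trials,
            )
            res = decoding.svm_rfe_decode(
                sub, split, folds=config.cv_folds, inner_folds=config.inner_cv_folds,
                c=config.svm_c, rfe_step=config.rfe_step, alpha=config.fdr_alpha, rng=rng,
            )
            rows.append(dict(representation=rep, band=band,
                             class_a="|".join(sorted(split.class_a)),
                             class_b="|".join(sorted(split.class_b)),
                             balanced_accuracy=res.balanced_accuracy,
                             n_trials=res.n_trials, threshold=res.threshold,
                             significant=res.significant))
    core_io.write_results_tsv(pd.DataFrame(rows), out / "decoding.tsv")


def _stage_report(config: PipelineConfig, out: Path, seed: int) -> None:
    rows = []
    specs = [
        ("power", "effect_sizes.tsv", "significant"),
        ("cfc", "cfc_map.tsv", "significant"),
        ("correlation", "correlation_map.tsv", "significant"),
        ("fisher", "fisher_distances.tsv", "significant"),
        ("decoding", "decoding.tsv", "significant"),
    ]
    found = False
    for name, fname, col in specs:
        path = out / fname
        if not path.exists():
            continue
        found = True
        df = pd.read_csv(path, sep="\t")
        rows.append(dict(analysis=name, n_significant=int(df[col].sum()), n_total=len(df)))
    if not found:
        raise FileNotFoundError("missing upstream artifact: no analysis outputs to report on")
    core_io.write_results_tsv(pd.DataFrame(rows), out / "report.tsv")
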