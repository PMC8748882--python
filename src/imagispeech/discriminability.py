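"""Item-level information maps: label correlations and Fisher distances.

Two complementary statistics quantify how much item-specific information a
feature carries.  The pairwise label correlation assigns each speech-item
pair labels +1/-1 and averages the Pearson correlation between a scalar
feature and the labels across all pairs, with a label-permutation null.  The
Fisher distance works in a PCA-reduced region-of-interest feature space and
takes, for each item pair, the maximum over retained principal components of
``(mu_i - mu_j)^2 / (sigma_i^2 + sigma_j^2)``; each pair's distance is
attributed to the representation groups that discriminate the pair, and
group values are the means over contributing pairs.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core_io import ChannelInfo, FeatureTable
from .lexicon import LexiconEntry, discriminant_groups
from .spectral import bh_fdr

logger = logging.getLogger("imagispeech")


# ---------------------------------------------------------------------------
# pairwise label correlation


def _pair_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each feature column of x and the label vector y.

    Zero-variance features yield r = 0 by policy (degenerate input).
    """
    xc = x - x.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.nan_to_num(r)


def pairwise_label_correlation(
    features: FeatureTable,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean pairwise item-label correlation per feature, with permutation p.

    For each (unordered) item pair, trials of the first item get label +1 and
    of the second -1; per-feature correlations are averaged (signed) across
    pairs.  The null shuffles the whole item-label vector across trials and
    repeats the pair averaging, which preserves the dependence between pairs
    sharing trials (permuting each pair independently under-disperses the
    null).  The reported p is two-sided on the signed mean and deliberately
    uncorrected across features.
    """
    rng = np.random.default_rng() if rng is None else rng
    items = features.trials["item"].to_numpy()
    uniq = sorted(set(items))
    if len(uniq) < 2:
        raise ValueError("need at least 2 items")
    counts = pd.Series(items).value_counts()
    if counts.min() < 3:
        raise ValueError("need at least 3 trials per item")
    pairs = list(combinations(uniq, 2))
    n_feat = features.values.shape[1]

    def mean_pair_corr(labels: np.ndarray) -> np.ndarray:
        total = np.zeros(n_feat)
        for a, b in pairs:
            mask = (labels == a) | (labels == b)
            x = features.values[mask]
            y = np.where(labels[mask] == a, 1.0, -1.0)
            total += _pair_correlations(x, y)
        return total / len(pairs)

    obs = mean_pair_corr(items)
    null = np.stack([mean_pair_corr(rng.permutation(items)) for _ in range(n_perm)])
    p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)) / (n_perm + 1.0)
    out = features.descriptors.copy()
    out["r_mean"] = obs
    out["p"] = p
    out["significant"] = p < alpha
    return out


# ---------------------------------------------------------------------------
# ROI PCA space and Fisher distances


def roi_pca_space(
    features: FeatureTable,
    channels: list[ChannelInfo],
    roi: str,
    hemisphere: str | None = None,
    variance_fraction: float = 0.95,
    band: str | None = None,
) -> tuple[np.ndarray, PCA]:
    """PCA component scores of the ROI's channel-feature matrix.

    Fitted on all trials; retains the smallest component count reaching the
    requested explained-variance fraction.
    """
    info = {c.name: c for c in channels}
    keep = []
    for fi, row in features.descriptors.iterrows():
        c = info.get(row["channel"])
        if c is None or c.roi != roi:
            continue
        if hemisphere is not None and c.hemisphere != hemisphere:
            continue
        if band is not None and row.get("band") != band:
            continue
        keep.append(fi)
    if len({features.descriptors.loc[fi, "channel"] for fi in keep}) < 2:
        raise ValueError(f"fewer than 2 channels in ROI {roi!r}")
    x = features.values[:, keep]
    if x.shape[0] < 2:
        raise ValueError("need more trials than components")
    pca = PCA()
    scores = pca.fit_transform(x)
    if variance_fraction >= 1.0:
        k = scores.shape[1]
    else:
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_fraction) + 1)
    return scores[:, :k], pca


def fisher_distance(
    a: np.ndarray, b: np.ndarray, mode: str = "max"
) -> tuple[float, np.ndarray]:
    """Fisher criterion per component and its max (or sum) across components.

    Components where both groups have zero variance are skipped; if every
    component is skipped the distance is undefined (NaN).
    """
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per item")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    denom = va + vb
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (mu_a - mu_b) ** 2 / denom
    terms = np.where(denom == 0, np.nan, terms)
    if np.all(np.isnan(terms)):
        return float("nan"), terms
    if mode == "max":
        return float(np.nanmax(terms)), terms
    if mode == "sum":
        return float(np.nansum(terms)), terms
    raise ValueError(f"unknown mode {mode!r}")


def _group_means(
    scores: np.ndarray,
    items: np.ndarray,
    entries: dict,
    representation: str,
    mode: str,
) -> dict:
    """Mean Fisher distance per discriminant group over contributing pairs."""
    uniq = sorted(set(items))
    sums: dict = {}
    counts: dict = {}
    for a, b in combinations(uniq, 2):
        groups = discriminant_groups(entries[a], entries[b], representation)
        if not groups:
            continue
        d, _ = fisher_distance(scores[items == a], scores[items == b], mode)
        if np.isnan(d):
            continue
        for g in groups:
            sums[g] = sums.get(g, 0.0) + d
            counts[g] = counts.get(g, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}


def group_assigned_fisher(
    features: FeatureTable,
    entries: list[LexiconEntry],
    channels: list[ChannelInfo],
    representations=("articulatory", "phonetic", "vocalic"),
    rois=None,
    n_perm: int = 1000,
    variance_fraction: float = 0.95,
    mode: str = "max",
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Group-attributed Fisher distances per (ROI, hemisphere, band, representation).

    Item-pair distances are computed in the PCA space of each ROI x band
    feature block and assigned to the pair's discriminant groups.  The
    permutation null shuffles item labels across trials and repeats the
    group averaging (PCA is label-free, so the component space is shared);
    BH-FDR runs across all result rows.
    """
    rng = np.random.default_rng() if rng is None else rng
    entry_map = {e.item: e for e in entries}
    items = features.trials["item"].to_numpy()
    unknown = sorted(set(items) - set(entry_map))
    if unknown:
        raise ValueError(f"items without lexicon entries: {unknown}")
    info = {c.name: c for c in channels}
    desc = features.descriptors
    bands = sorted(desc["band"].unique()) if "band" in desc.columns else [None]
    combos = sorted(
        {(info[r["channel"]].roi, info[r["channel"]].hemisphere) for _, r in desc.iterrows()}
    )
    if rois is not None:
        combos = [c for c in combos if c[0] in rois]
    rows = []
    for roi, hemi in combos:
        for band in bands:
            try:
                scores, _ = roi_pca_space(
                    features, channels, roi, hemisphere=hemi,
                    variance_fraction=variance_fraction, band=band,
                )
            except ValueError:
                logger.info("skipping ROI %s/%s band %s: too few channels", roi, hemi, band)
                continue
            for rep in representations:
                obs = _group_means(scores, items, entry_map, rep, mode)
                if not obs:
                    continue
                null = {g: np.empty(n_perm) for g in obs}
                for s in range(n_perm):
                    perm_items = rng.permutation(items)
                    nm = _group_means(scores, perm_items, entry_map, rep, mode)
                    for g in null:
                        null[g][s] = nm.get(g, 0.0)
                for g, d in sorted(obs.items()):
                    p = (1.0 + np.sum(null[g] >= d)) / (n_perm + 1.0)
                    rows.append(dict(roi=roi, hemisphere=hemi, band=band,
                                     representation=rep, group=g, D=d, p=p))
    df = pd.DataFrame(rows)
    if len(df):
        q, rej = bh_fdr(df["p"].to_numpy(), alpha=alpha)
        df["q"] = q
        df["significant"] = rej
    return df
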