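"""Feature-space reconstruction metrics and statistical comparisons.

Per test frame, reconstruction quality is the Pearson correlation and the
Euclidean distance between extractor features of the reconstruction and of
the ground-truth frame, for each of six extractor-layer combinations (two
extractors x pool2/pool5/fc6), then averaged over frames. Two tests mirror
standard practice: a one-sided one-sample t-test of the per-frame metric
against a chance level, and a one-sided binomial test counting, across all
frames and all 12 metric columns, how often one model beats another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import default_extractors

__all__ = [
    "feature_metrics", "metrics_table", "above_chance_ttest",
    "binomial_vs_baseline", "shuffled_pair_chance",
]

LAYERS = ("pool2", "pool5", "fc6")


def _per_frame_metrics(feat_recon: np.ndarray, feat_target: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    rs = np.empty(len(feat_recon))
    ds = np.empty(len(feat_recon))
    for i, (fr, ft) in enumerate(zip(feat_recon, feat_target)):
        if fr.std() == 0 or ft.std() == 0:
            warnings.warn("constant feature vector; correlation recorded as 0")
            rs[i] = 0.0
        else:
            rs[i] = np.corrcoef(fr, ft)[0, 1]
        ds[i] = np.linalg.norm(fr - ft)
    return rs, ds


def feature_metrics(recon_frames: np.ndarray, target_frames: np.ndarray,
                    extractor, layer: str) -> pd.DataFrame:
    """Per-frame Pearson r and Euclidean distance at one extractor layer."""
    recon_frames = np.asarray(recon_frames, dtype=float)
    target_frames = np.asarray(target_frames, dtype=float)
    if recon_frames.shape != target_frames.shape:
        raise ValueError("frame counts/shapes differ")
    fr = extractor.features(recon_frames, layer=layer)
    ft = extractor.features(target_frames, layer=layer)
    rs, ds = _per_frame_metrics(fr, ft)
    return pd.DataFrame({
        "frame": np.arange(len(rs)),
        "extractor": getattr(extractor, "name", "extractor"),
        "layer": layer,
        "pearson_r": rs,
        "euclidean_distance": ds,
    })


def metrics_table(recon_frames: np.ndarray, target_frames: np.ndarray,
                  extractors: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """Full table over all 6 extractor-layer combinations (long format)."""
    extractors = extractors or default_extractors(seed)
    parts = [feature_metrics(recon_frames, target_frames, ext, layer)
             for ext in extractors.values() for layer in LAYERS]
    return pd.concat(parts, ignore_index=True)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean metric per extractor-layer, mirroring the published table layout."""
    return (table.groupby(["extractor", "layer"])
            [["pearson_r", "euclidean_distance"]].mean().reset_index())


def above_chance_ttest(per_frame_metric: np.ndarray, chance_level: float
                       ) -> tuple[float, float]:
    """One-sample, one-sided t-test that the metric exceeds chance."""
    vals = np.asarray(per_frame_metric, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two frames")
    if vals.std(ddof=1) == 0:
        raise ValueError("zero variance in the metric; t-test undefined")
    res = stats.ttest_1samp(vals, chance_level, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def shuffled_pair_chance(recon_frames: np.ndarray, target_frames: np.ndarray,
                         extractor, layer: str, seed: int = 0) -> float:
    """Chance level by pairing each reconstruction with a mismatched target
    (a cyclic shift of the target order)."""
    shift = np.roll(np.arange(len(target_frames)), 1)
    tab = feature_metrics(recon_frames, np.asarray(target_frames)[shift],
                          extractor, layer)
    return float(tab["pearson_r"].mean())


def binomial_vs_baseline(model_metrics: pd.DataFrame,
                         baseline_metrics: pd.DataFrame
                         ) -> tuple[int, int, float]:
    """One-sided binomial test on per-frame, per-metric wins against p = 0.5.

    A win is model r > baseline r, or model distance < baseline distance
    (lower distance is better); ties count as failures. Tables must be
    aligned long-format outputs of :func:`metrics_table`.
    """
    key = ["frame", "extractor", "layer"]
    m = model_metrics.sort_values(key).reset_index(drop=True)
    b = baseline_metrics.sort_values(key).reset_index(drop=True)
    if len(m) != len(b) or not (m[key].values == b[key].values).all():
        raise ValueError("metric tables are not aligned")
    wins_r = (m["pearson_r"].values > b["pearson_r"].values).sum()
    wins_d = (m["euclidean_distance"].values < b["euclidean_distance"].values).sum()
    successes = int(wins_r + wins_d)
    n = 2 * len(m)
    p = stats.binomtest(successes, n, p=0.5, alternative="greater").pvalue
    return successes, n, float(p)
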