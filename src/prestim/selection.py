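"""Feature reduction by squared point-biserial correlation.

Each feature is scored by the squared Pearson correlation between its
values and the binary class label (the point-biserial identity). Features
are then kept greedily, best first, until the retained scores account for a
fraction (default 90%) of the total score. For scalp maps, per-feature
scores are averaged within each channel and normalised to percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionResult",
    "point_biserial_r2",
    "biserial_r2_scores",
    "select_by_cumulative_score",
    "channel_scalp_scores",
    "score_and_select",
]

DEFAULT_THRESHOLD = 0.90


@dataclass
class SelectionResult:
    """Per-feature scores, the retained subset and per-channel aggregates."""

    r2: np.ndarray
    selected: np.ndarray
    threshold_frac: float
    channel_percent: np.ndarray


def point_biserial_r2(feature: np.ndarray, labels: np.ndarray) -> float:
    """Squared point-biserial correlation of one feature with binary labels.

    Identical to the squared Pearson correlation computed with the labels
    treated as 0/1 numbers; lies in [0, 1]. Degenerate inputs (a constant
    feature, or a single class) are rejected.
    """
    feature = np.asarray(feature, dtype=float)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if np.ptp(feature) == 0:
        raise ValueError("feature is constant; correlation undefined")
    r = np.corrcoef(feature, labels.astype(float))[0, 1]
    return float(r * r)


def biserial_r2_scores(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised r² over the columns of an instances-by-features matrix.

    Columns that are constant within the given instances carry no class
    information and are assigned a score of 0 (rather than raising), which
    is the behaviour the cross-validation harness relies on: a fold's
    training portion may flatten a feature by chance.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    yc = y - y.mean()
    xc = values - values.mean(axis=0)
    cov = xc.T @ yc
    var_x = (xc * xc).sum(axis=0)
    var_y = (yc * yc).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (cov * cov) / (var_x * var_y)
    r2 = np.where(var_x == 0, 0.0, r2)
    return np.clip(r2, 0.0, 1.0)


def select_by_cumulative_score(r2: np.ndarray,
                               threshold_frac: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Smallest prefix of descending-score features reaching the threshold.

    Features are sorted by descending score (stable: ties keep ascending
    original index); the shortest prefix whose cumulative score reaches
    ``threshold_frac`` of the total is returned, in descending-score order.
    """
    r2 = np.asarray(r2, dtype=float)
    if (r2 < 0).any():
        raise ValueError("scores must be non-negative")
    total = r2.sum()
    if total == 0:
        raise ValueError("all scores are zero; nothing to select")
    if not 0 < threshold_frac <= 1:
        raise ValueError(f"threshold_frac={threshold_frac} must lie in (0, 1]")
    order = np.argsort(-r2, kind="stable")
    csum = np.cumsum(r2[order])
    k = int(np.searchsorted(csum, threshold_frac * total - 1e-12)) + 1
    selected = order[:k]
    if threshold_frac == 1.0:
        selected = order[r2[order] > 0]
    return selected


def channel_scalp_scores(r2: np.ndarray, feature_channel_map: np.ndarray) -> np.ndarray:
    """Mean score per channel, normalised to percentages summing to 100."""
    r2 = np.asarray(r2, dtype=float)
    fmap = np.asarray(feature_channel_map, dtype=int)
    if r2.shape != fmap.shape:
        raise ValueError("every feature must be mapped to a channel")
    n_channels = fmap.max() + 1
    sums = np.bincount(fmap, weights=r2, minlength=n_channels)
    counts = np.bincount(fmap, minlength=n_channels)
    if (counts == 0).any():
        raise ValueError("some channels have no mapped features")
    means = sums / counts
    return means / means.sum() * 100.0


def score_and_select(values: np.ndarray, labels: np.ndarray,
                     feature_channel_map: np.ndarray,
                     threshold_frac: float = DEFAULT_THRESHOLD) -> SelectionResult:
    """Score all features, select by cumulative threshold, aggregate by channel."""
    r2 = biserial_r2_scores(values, labels)
    selected = select_by_cumulative_score(r2, threshold_frac)
    percent = channel_scalp_scores(r2, feature_channel_map)
    return SelectionResult(r2=r2, selected=selected, threshold_frac=threshold_frac,
                           channel_percent=percent)
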