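"""Feature extraction: the four feature families of the decoding pipeline.

Two feature families describe a whole 1000 ms pre-stimulus epoch (*static*
classification) and the same two families are recomputed inside a sliding
500 ms window (*dynamic*, i.e. time-resolved, classification):

* **spectral** — per channel, the ratio of beta to alpha total log-power
  (emotional arousal) and of theta to beta total log-power (cognitive
  arousal), giving ``2 x n_channels`` features per instance;
* **temporal** — per channel, the band-limited (0.05–10 Hz), 20 Hz-decimated
  and epoch-wise z-scored trace, giving ``n_points x n_channels`` features
  (20 points per channel for the full epoch, 10 for a 500 ms window).

Every feature maps to exactly one channel, which is what lets the selection
stage aggregate discriminability back onto the scalp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .signal import EpochSet, Psd, bandpass_butter_zerophase, decimate_to, welch_psd

__all__ = [
    "BandDefinition",
    "FeatureMatrix",
    "band_totals",
    "static_spectral_features",
    "static_temporal_features",
    "segment_epoch",
    "segment_times",
    "dynamic_spectral_features",
    "dynamic_temporal_features",
]

#: Welch settings for whole-epoch spectra: one 250-sample Hamming window.
STATIC_WELCH_WINDOW = 250
#: Welch settings for 500 ms windows: 16-sample Hamming, zero-padded to 250.
DYNAMIC_WELCH_WINDOW = 16
DYNAMIC_WELCH_NFFT = 250
#: Sliding-window length for the dynamic approach, milliseconds.
DYNAMIC_WINDOW_MS = 500.0
#: Target rate of the temporal feature family, Hz.
TEMPORAL_FS_OUT = 20.0
#: Band edges of the temporal band-pass, Hz.
TEMPORAL_BAND = (0.05, 10.0)


class FeatureError(ValueError):
    """Raised when a degenerate input makes a feature undefined."""


@dataclass
class BandDefinition:
    """Frequency bands for the spectral features, in Hz.

    Defaults: theta 4–6, alpha 6–13, beta 13–30. Under the default
    ``half-open`` convention a band covers ``[low, high)`` so the shared
    edges at 6 and 13 Hz are not double counted; ``closed`` includes both
    edges.
    """

    theta: tuple[float, float] = (4.0, 6.0)
    alpha: tuple[float, float] = (6.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)
    edge_convention: Literal["half-open", "closed"] = "half-open"

    def __post_init__(self) -> None:
        for name in ("theta", "alpha", "beta"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} band ({lo}, {hi}) must have low < high")
        if self.edge_convention not in ("half-open", "closed"):
            raise ValueError(f"unknown edge convention {self.edge_convention!r}")

    def mask(self, freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if self.edge_convention == "half-open":
            return (freqs >= lo) & (freqs < hi)
        return (freqs >= lo) & (freqs <= hi)


@dataclass
class FeatureMatrix:
    """Instances-by-features matrix with per-feature channel provenance."""

    values: np.ndarray
    labels: np.ndarray
    feature_channel_map: np.ndarray
    feature_kind: Literal["spectral", "temporal"]
    channel_ids: list[str] = field(default_factory=list)
    segment_index: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_channel_map = np.asarray(self.feature_channel_map, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (instances x features)")
        if self.labels.shape[0] != self.values.shape[0]:
            raise ValueError("labels do not match the number of instances")
        if self.feature_channel_map.shape[0] != self.values.shape[1]:
            raise ValueError("feature_channel_map must give one channel per feature")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def band_totals(psd: Psd, bands: BandDefinition | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum natural-log-transformed PSD bins per band.

    The log transform compensates the right skew of raw power; the totals
    are then ``theta_tot``, ``alpha_tot`` and ``beta_tot`` per channel
    (arrays shaped like ``psd.values`` without the frequency axis).
    """
    bands = bands or BandDefinition()
    totals = []
    for name in ("theta", "alpha", "beta"):
        m = bands.mask(psd.freqs, getattr(bands, name))
        vals = psd.values[..., m]
        if not (vals > 0).all():
            raise FeatureError(
                f"non-positive PSD bin inside the {name} band; log-power undefined"
            )
        totals.append(np.log(vals).sum(axis=-1))
    return totals[0], totals[1], totals[2]


def _spectral_from_psd(psd: Psd, epochs: EpochSet, bands: BandDefinition,
                       invert_theta_beta: bool, segment_index: int | None
                       ) -> FeatureMatrix:
    theta, alpha, beta = band_totals(psd, bands)  # each (n_epochs, n_channels)
    bad_alpha = np.argwhere(alpha == 0)
    bad_beta = np.argwhere(beta == 0)
    if bad_alpha.size or bad_beta.size:
        ep, ch = (bad_alpha if bad_alpha.size else bad_beta)[0]
        raise FeatureError(
            f"zero band total in epoch {ep}, channel {epochs.channel_ids[ch]}: "
            "band-ratio feature undefined"
        )
    beta_alpha = beta / alpha
    second = beta / theta if invert_theta_beta else theta / beta
    # interleave per channel: [b/a(ch1), t/b(ch1), b/a(ch2), ...]
    n_epochs, n_channels = beta_alpha.shape
    values = np.empty((n_epochs, 2 * n_channels))
    values[:, 0::2] = beta_alpha
    values[:, 1::2] = second
    fmap = np.repeat(np.arange(n_channels), 2)
    return FeatureMatrix(values=values, labels=epochs.labels, feature_channel_map=fmap,
                         feature_kind="spectral", channel_ids=list(epochs.channel_ids),
                         segment_index=segment_index)


def static_spectral_features(epochs: EpochSet, bands: BandDefinition | None = None,
                             window_len: int = STATIC_WELCH_WINDOW,
                             nfft: int | None = None,
                             invert_theta_beta: bool = False) -> FeatureMatrix:
    """Whole-epoch band-ratio features: ``2 x n_channels`` per epoch.

    Per channel the pair is ``(beta/alpha, theta/beta)`` of the log-power
    band totals; ``invert_theta_beta=True`` swaps the second ratio to
    ``beta/theta``.
    """
    bands = bands or BandDefinition()
    psd = welch_psd(epochs.data, epochs.fs, window_len=window_len, nfft=nfft)
    return _spectral_from_psd(psd, epochs, bands, invert_theta_beta, None)


def _temporal_block(data: np.ndarray, fs: float, channel_ids: list[str]) -> np.ndarray:
    """Filter, decimate and z-score (n_epochs, n_channels, n_samples) data.

    Returns the concatenated (n_epochs, n_points * n_channels) block in
    channel-major order. The z-score uses each epoch-channel's own temporal
    mean and sample standard deviation (ddof=1).
    """
    filtered = bandpass_butter_zerophase(data, fs, *TEMPORAL_BAND, order=2)
    dec = decimate_to(filtered, fs, TEMPORAL_FS_OUT)
    mean = dec.mean(axis=-1, keepdims=True)
    sd = dec.std(axis=-1, ddof=1, keepdims=True)
    flat = np.argwhere(sd[..., 0] == 0)
    if flat.size:
        ep, ch = flat[0]
        raise FeatureError(
            f"flat trace in epoch {ep}, channel {channel_ids[ch]}: z-score undefined"
        )
    z = (dec - mean) / sd
    n_epochs = z.shape[0]
    return z.reshape(n_epochs, -1)


def static_temporal_features(epochs: EpochSet) -> FeatureMatrix:
    """Whole-epoch temporal features: the CNV-style slow-wave shape.

    Each channel is band-passed to 0.05–10 Hz (zero-phase Butterworth,
    order 2), decimated to 20 Hz and z-scored over time within the epoch;
    channels are concatenated, giving ``20 x n_channels`` features for a
    1000 ms epoch.
    """
    values = _temporal_block(epochs.data, epochs.fs, list(epochs.channel_ids))
    n_points = values.shape[1] // epochs.n_channels
    fmap = np.repeat(np.arange(epochs.n_channels), n_points)
    return FeatureMatrix(values=values, labels=epochs.labels, feature_channel_map=fmap,
                         feature_kind="temporal", channel_ids=list(epochs.channel_ids))


def segment_epoch(epochs: EpochSet, window_ms: float = DYNAMIC_WINDOW_MS,
                  shift_samples: int = 1) -> list[EpochSet]:
    """Slice each epoch into sliding windows (stride ``shift_samples``).

    Window starts run from sample 0 up to ``n_samples - window - 1``; the
    final start position (which would end exactly at the epoch edge) is
    dropped, so a 1000 ms epoch at 250 Hz with a 500 ms window yields
    exactly 125 segments. Segment ``i`` (0-based) is assigned the time of
    its left extreme, ``i * shift / fs`` seconds.
    """
    window = int(round(window_ms / 1000.0 * epochs.fs))
    if window > epochs.n_samples:
        raise ValueError(
            f"window of {window} samples exceeds epoch length {epochs.n_samples}"
        )
    if shift_samples < 1:
        raise ValueError("shift_samples must be >= 1")
    n_segments = (epochs.n_samples - window) // shift_samples
    if n_segments < 1:
        raise ValueError("epoch too short for even one sliding window")
    out = []
    for i in range(n_segments):
        start = i * shift_samples
        out.append(epochs.with_data(epochs.data[:, :, start:start + window]))
    return out


def segment_times(n_segments: int, fs: float, shift_samples: int = 1) -> np.ndarray:
    """Left-extreme time (seconds) of each sliding window."""
    return np.arange(n_segments) * shift_samples / fs


def dynamic_spectral_features(epochs: EpochSet, bands: BandDefinition | None = None,
                              window_ms: float = DYNAMIC_WINDOW_MS,
                              shift_samples: int = 1,
                              invert_theta_beta: bool = False) -> list[FeatureMatrix]:
    """Band-ratio features per sliding window.

    Within each 500 ms window the PSD comes from a 16-sample Hamming Welch
    window zero-padded to 250 points (so the frequency grid matches the
    static analysis); features have the same ``2 x n_channels`` layout.
    """
    bands = bands or BandDefinition()
    segments = segment_epoch(epochs, window_ms=window_ms, shift_samples=shift_samples)
    out = []
    for i, seg in enumerate(segments):
        psd = welch_psd(seg.data, seg.fs, window_len=DYNAMIC_WELCH_WINDOW,
                        nfft=DYNAMIC_WELCH_NFFT)
        out.append(_spectral_from_psd(psd, seg, bands, invert_theta_beta, i))
    return out


def dynamic_temporal_features(epochs: EpochSet, window_ms: float = DYNAMIC_WINDOW_MS,
                              shift_samples: int = 1) -> list[FeatureMatrix]:
    """Temporal features per sliding window: ``10 x n_channels`` each.

    Each 500 ms window is band-passed (0.05–10 Hz, zero-phase), decimated
    to 20 Hz (10 points) and z-scored *within the window*. Filtering is
    per-window rather than over the full epoch: the non-causal 0.05 Hz
    high-pass has a time constant far longer than the epoch, so filtering
    the whole epoch first would smear a late slow deflection across every
    window and defeat the temporal localisation this analysis is for.
    Reflection padding keeps the short-window filter transients mild.
    """
    segments = segment_epoch(epochs, window_ms=window_ms, shift_samples=shift_samples)
    out = []
    for i, seg in enumerate(segments):
        filt = bandpass_butter_zerophase(seg.data, seg.fs, *TEMPORAL_BAND, order=2)
        dec = decimate_to(filt, seg.fs, TEMPORAL_FS_OUT)
        mean = dec.mean(axis=-1, keepdims=True)
        sd = dec.std(axis=-1, ddof=1, keepdims=True)
        flat = np.argwhere(sd[..., 0] == 0)
        if flat.size:
            ep, ch = flat[0]
            raise FeatureError(
                f"flat trace in segment {i}, epoch {ep}, "
                f"channel {seg.channel_ids[ch]}: z-score undefined"
            )
        z = ((dec - mean) / sd).reshape(seg.n_epochs, -1)
        n_points = z.shape[1] // seg.n_channels
        fmap = np.repeat(np.arange(seg.n_channels), n_points)
        out.append(FeatureMatrix(values=z, labels=seg.labels, feature_channel_map=fmap,
                                 feature_kind="temporal",
                                 channel_ids=list(seg.channel_ids), segment_index=i))
    return out
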