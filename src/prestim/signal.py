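"""Deterministic signal-conditioning primitives for epoched EEG.

This module defines the pipeline's universal container (:class:`EpochSet`)
and the conditioning operations every later stage builds on: zero-phase
Butterworth band-pass filtering, linear-phase FIR filtering for continuous
raw data, common-average re-referencing, baseline correction, rational-ratio
decimation and the Welch periodogram.

All operations are pure functions: they never mutate their input and are
deterministic for a given input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import scipy.signal as sps

__all__ = [
    "EpochSet",
    "Psd",
    "bandpass_butter_zerophase",
    "fir_bandpass",
    "common_average_reference",
    "baseline_correct",
    "decimate_to",
    "welch_psd",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates a documented constraint."""


@dataclass
class EpochSet:
    """Labelled epoched multichannel EEG.

    Parameters
    ----------
    data:
        Array of shape ``(n_epochs, n_channels, n_samples)``; microvolts, or
        z-units after normalisation.
    fs:
        Sampling rate in Hz.
    labels:
        Binary array of shape ``(n_epochs,)``: 1 for the high-arousal class,
        0 for the low-arousal class.
    channel_ids:
        Ordered channel identifiers, one per channel.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_epochs, n_channels, n_samples); got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels shape {self.labels.shape} does not match n_epochs {self.data.shape[0]}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = low arousal, 1 = high arousal)")
        self.labels = self.labels.astype(int)
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i}" for i in range(self.data.shape[1])]
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError("channel_ids length does not match n_channels")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Return a copy of this set carrying new sample data."""
        return EpochSet(data=data, fs=self.fs, labels=self.labels.copy(),
                        channel_ids=list(self.channel_ids))


@dataclass
class Psd:
    """One-sided power spectral density, per channel.

    ``values`` has shape ``(..., n_freqs)`` with the frequency axis last;
    ``freqs`` runs uniformly from 0 to the Nyquist frequency.
    """

    freqs: np.ndarray
    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[-1] != self.freqs.shape[0]:
            raise ValueError("last axis of values must match freqs")
        if self.freqs[0] != 0:
            raise ValueError("freqs must start at 0")


def bandpass_butter_zerophase(x: np.ndarray, fs: float, low: float, high: float,
                              order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The filter is applied forward and backward, which cancels the phase
    response and squares the magnitude response. Edge transients are
    handled with Gustafsson's minimum-transient initial conditions rather
    than signal padding: with a high-pass corner far below 1/epoch-length
    (0.05 Hz on 1 s epochs) the impulse response dwarfs the signal, and
    padding-based initialisation leaks large slow artefacts into the
    interior.
    """
    if not 0 <= low < high:
        raise ValueError(f"need 0 <= low < high, got low={low}, high={high}")
    if high >= fs / 2:
        raise ValueError(f"high={high} Hz must lie below the Nyquist frequency {fs / 2} Hz")
    if low == 0:
        b, a = sps.butter(order, high, btype="lowpass", fs=fs)
    else:
        b, a = sps.butter(order, [low, high], btype="bandpass", fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1, method="gust")


def fir_bandpass(x: np.ndarray, fs: float, low: float, high: float,
                 order: int = 16500) -> np.ndarray:
    """Linear-phase Hamming windowed-sinc band-pass, group delay compensated.

    Intended for continuous raw recordings prior to epoching; the default
    order matches a very sharp 0.1–45 Hz selection at typical EEG rates.
    The constant group delay of ``order/2`` samples is removed so the output
    is time-aligned with the input.
    """
    x = np.asarray(x, dtype=float)
    if order % 2 != 0:
        raise ValueError(f"order must be even, got {order}")
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {fs / 2}) Hz")
    if x.shape[-1] <= order:
        raise ValueError(
            f"series length {x.shape[-1]} must exceed the filter order {order}"
        )
    taps = sps.firwin(order + 1, [low, high], pass_zero=False, window="hamming", fs=fs)
    delay = order // 2
    padded = np.concatenate(
        [x, np.zeros(x.shape[:-1] + (delay,), dtype=float)], axis=-1
    )
    y = sps.lfilter(taps, 1.0, padded, axis=-1)
    return y[..., delay:]


def fir_kernel(fs: float, low: float, high: float, order: int) -> np.ndarray:
    """The windowed-sinc impulse response used by :func:`fir_bandpass`."""
    return sps.firwin(order + 1, [low, high], pass_zero=False, window="hamming", fs=fs)


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference every sample to the instantaneous mean across channels.

    After CAR the channel mean at every time point is exactly zero; the
    operation is idempotent and linear.
    """
    if epochs.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    mean = epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(epochs.data - mean)


def baseline_correct(epochs: EpochSet, baseline_window: tuple[int, int]) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``baseline_window``.

    ``baseline_window`` is a half-open sample interval ``(start, stop)``
    relative to the epoch start.
    """
    start, stop = baseline_window
    if not (0 <= start < stop <= epochs.n_samples):
        raise ValueError(
            f"baseline window ({start}, {stop}) must be non-empty and inside "
            f"[0, {epochs.n_samples}]"
        )
    mean = epochs.data[:, :, start:stop].mean(axis=2, keepdims=True)
    return epochs.with_data(epochs.data - mean)


def decimate_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Resample the last axis from ``fs_in`` to ``fs_out`` (polyphase FIR).

    The rate ratio may be rational (250 -> 20 Hz is a ratio of 25/2); the
    anti-alias low-pass is the Kaiser-windowed FIR built into the polyphase
    resampler. The resampled length ``ceil(n * fs_out / fs_in)`` must be an
    integer number of output samples covering the same duration.
    """
    x = np.asarray(x, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_out > fs_in:
        raise ValueError(f"fs_out={fs_out} must not exceed fs_in={fs_in}")
    ratio = Fraction(fs_out / fs_in).limit_denominator(10_000)
    if not np.isclose(float(ratio), fs_out / fs_in, rtol=0, atol=1e-12):
        raise ValueError(f"rate ratio {fs_out}/{fs_in} is not a simple rational number")
    up, down = ratio.numerator, ratio.denominator
    if up == down:
        return x.copy()
    n_out = x.shape[-1] * up / down
    if not float(n_out).is_integer():
        raise ValueError(
            f"{x.shape[-1]} samples at {fs_in} Hz do not span an integer number "
            f"of samples at {fs_out} Hz"
        )
    return sps.resample_poly(x, up, down, axis=-1, padtype="line")


def welch_psd(x: np.ndarray, fs: float, window_len: int,
              nfft: int | None = None, overlap_frac: float = 0.5) -> Psd:
    """Welch's averaged modified periodogram with a Hamming window.

    Segments of ``window_len`` samples, overlapping by ``overlap_frac``, are
    Hamming-windowed, (optionally zero-padded to ``nfft``), transformed, and
    their periodograms averaged. One-sided density scaling: the integral of
    the PSD over frequency approximates the signal variance. No detrending
    is applied, so DC power stays in the 0 Hz bin.
    """
    x = np.asarray(x, dtype=float)
    if nfft is None:
        nfft = window_len
    if window_len > x.shape[-1]:
        raise ValueError(
            f"window_len={window_len} exceeds series length {x.shape[-1]}"
        )
    if nfft < window_len:
        raise ValueError(f"nfft={nfft} must be >= window_len={window_len}")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac={overlap_frac} must lie in [0, 1)")
    noverlap = int(round(window_len * overlap_frac))
    freqs, values = sps.welch(
        x, fs=fs, window="hamming", nperseg=window_len, noverlap=noverlap,
        nfft=nfft, detrend=False, return_onesided=True, scaling="density",
        axis=-1,
    )
    return Psd(freqs=freqs, values=values, resolution=fs / nfft)
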