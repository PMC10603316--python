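"""Synthetic labelled EEG epoch sets with injectable class effects.

The generator emulates the statistical structure the decoding pipeline
assumes without claiming biophysical realism: 128 channels sampled at
250 Hz for 1000 ms, a 1/f^a coloured-noise background normalised to unit
variance, narrow-band oscillations with per-epoch random phase, and two
approximately balanced classes. Class effects can be injected into a
configurable channel subset:

* a **spectral effect** multiplies the beta-band (13–30 Hz) amplitude of
  the background noise for high-arousal epochs, shifting the beta/alpha
  power ratio upward on exactly the targeted channels;
* a **temporal effect** adds a slow ramp (an anticipatory, CNV-like
  deflection — use a negative amplitude for the physiological sign) growing
  from an onset time to the epoch end, in units of the background standard
  deviation.

With both effects disabled the two classes are exchangeable by
construction, which is what the pipeline's null-calibration tests rely on.
All randomness flows from the single config seed; an identical config is
guaranteed to reproduce a bit-identical epoch set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .signal import ConfigError, EpochSet

__all__ = [
    "Oscillation",
    "SpectralEffect",
    "TemporalEffect",
    "GeneratorConfig",
    "generate_epochs",
    "load_generator_config",
]

BETA_BAND = (13.0, 30.0)


@dataclass
class Oscillation:
    """A narrow-band sinusoidal component with per-epoch random phase."""

    freq_hz: float
    amplitude: float
    channels: Sequence[int] | None = None  # None = all channels


@dataclass
class SpectralEffect:
    """Beta-amplitude multiplier applied to high-arousal epochs."""

    channels: Sequence[int]
    beta_multiplier: float = 1.0


@dataclass
class TemporalEffect:
    """Slow ramp added to high-arousal epochs on the targeted channels.

    ``amplitude`` is the value reached at the epoch end, in units of the
    (unit) background standard deviation; ``onset_ms`` is where the ramp
    leaves zero; ``shape`` is currently always ``'linear'``.
    """

    channels: Sequence[int]
    amplitude: float = 0.0
    onset_ms: float = 0.0
    shape: str = "linear"


@dataclass
class GeneratorConfig:
    """Study-condition defaults: 128 channels, 250 Hz, 1000 ms epochs,
    1/f background with a 10 Hz alpha rhythm, balanced classes.

    The background and oscillation amplitudes are expressed in units of the
    background standard deviation; the whole epoch is finally scaled to
    ``rms_amplitude_uv`` microvolts of background RMS so spectral log-power
    totals are positive, as they are on recorded EEG.
    """

    n_epochs_per_class: int
    n_channels: int = 128
    fs: float = 250.0
    epoch_ms: float = 1000.0
    noise_exponent: float = 1.0
    osc_components: list[Oscillation] = field(
        default_factory=lambda: [Oscillation(10.0, 1.0)])
    spectral_effect: SpectralEffect | None = None
    temporal_effect: TemporalEffect | None = None
    class_imbalance: float = 0.5
    rms_amplitude_uv: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rms_amplitude_uv <= 0:
            raise ConfigError(f"rms_amplitude_uv must be positive, got {self.rms_amplitude_uv}")
        if self.n_epochs_per_class < 1:
            raise ConfigError(f"n_epochs_per_class must be >= 1, got {self.n_epochs_per_class}")
        if self.n_channels < 2:
            raise ConfigError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        n_samples = self.fs * self.epoch_ms / 1000.0
        if not float(n_samples).is_integer() or n_samples < 2:
            raise ConfigError(
                f"epoch_ms={self.epoch_ms} at fs={self.fs} Hz gives a non-integer "
                f"or degenerate sample count ({n_samples})"
            )
        if not 0.4 <= self.class_imbalance <= 0.6:
            raise ConfigError(
                f"class_imbalance={self.class_imbalance} outside [0.4, 0.6]; "
                "classes must stay approximately balanced"
            )
        for eff, name in ((self.spectral_effect, "spectral_effect"),
                          (self.temporal_effect, "temporal_effect")):
            if eff is not None:
                ch = np.asarray(eff.channels, dtype=int)
                if ch.size and (ch.min() < 0 or ch.max() >= self.n_channels):
                    raise ConfigError(f"{name} channels outside [0, {self.n_channels})")
        if self.temporal_effect is not None and self.temporal_effect.shape != "linear":
            raise ConfigError(
                f"temporal_effect shape {self.temporal_effect.shape!r} not supported"
            )

    @property
    def n_samples(self) -> int:
        return int(self.fs * self.epoch_ms / 1000.0)


def _colored_noise(rng: np.random.Generator, n_epochs: int, n_channels: int,
                   n_samples: int, fs: float, exponent: float,
                   beta_boost_mask: np.ndarray | None,
                   beta_multiplier: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping.

    ``beta_boost_mask`` is a boolean (n_epochs, n_channels) mask whose True
    entries get the beta-band amplitude multiplier applied after the
    unit-variance normalisation, so the boost is not normalised away.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    # Parseval weights: interior rfft bins represent two conjugate bins.
    w = np.full_like(freqs, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    # scale so the expected sample variance is 1
    amp *= n_samples / np.sqrt((w * amp**2).sum())
    nf = freqs.size
    re = rng.standard_normal((n_epochs, n_channels, nf))
    im = rng.standard_normal((n_epochs, n_channels, nf))
    coeff = amp * (re + 1j * im) / np.sqrt(2.0)
    if beta_boost_mask is not None and beta_multiplier != 1.0:
        band = (freqs >= BETA_BAND[0]) & (freqs < BETA_BAND[1])
        boost = np.where(beta_boost_mask[:, :, None] & band[None, None, :],
                         beta_multiplier, 1.0)
        coeff = coeff * boost
    return np.fft.irfft(coeff, n=n_samples, axis=-1)


def generate_epochs(config: GeneratorConfig) -> EpochSet:
    """Draw a labelled epoch set from the configured generative model.

    The class split is ``round(n_total * class_imbalance)`` high-arousal
    epochs out of ``2 * n_epochs_per_class``; epoch order is shuffled
    deterministically by the seed.
    """
    rng = np.random.default_rng(config.seed)
    n_total = 2 * config.n_epochs_per_class
    n_high = int(round(n_total * config.class_imbalance))
    n_low = n_total - n_high
    n_samples = config.n_samples
    c = config.n_channels

    labels = np.concatenate([np.zeros(n_low, dtype=int), np.ones(n_high, dtype=int)])

    boost_mask = None
    multiplier = 1.0
    if config.spectral_effect is not None:
        multiplier = config.spectral_effect.beta_multiplier
        boost_mask = np.zeros((n_total, c), dtype=bool)
        ch = np.asarray(config.spectral_effect.channels, dtype=int)
        boost_mask[np.ix_(labels == 1, ch)] = True

    data = _colored_noise(rng, n_total, c, n_samples, config.fs,
                          config.noise_exponent, boost_mask, multiplier)

    t = np.arange(n_samples) / config.fs
    for osc in config.osc_components:
        ch = (np.arange(c) if osc.channels is None
              else np.asarray(osc.channels, dtype=int))
        phase = rng.uniform(0, 2 * np.pi, size=(n_total, ch.size, 1))
        data[:, ch, :] += osc.amplitude * np.sin(
            2 * np.pi * osc.freq_hz * t[None, None, :] + phase)

    if config.temporal_effect is not None and config.temporal_effect.amplitude != 0:
        eff = config.temporal_effect
        onset = eff.onset_ms / 1000.0
        duration = config.epoch_ms / 1000.0
        ramp = np.clip((t - onset) / max(duration - 1 / config.fs - onset, 1e-12),
                       0.0, 1.0) * eff.amplitude
        ch = np.asarray(eff.channels, dtype=int)
        data[np.ix_(labels == 1, ch)] += ramp[None, None, :]

    # scale from z-like units to microvolts; log-power band totals are then
    # positive (as on real EEG), which fixes the direction of ratio shifts
    data *= config.rms_amplitude_uv

    perm = rng.permutation(n_total)
    channel_ids = [f"ch{i}" for i in range(c)]
    return EpochSet(data=data[perm], fs=config.fs, labels=labels[perm],
                    channel_ids=channel_ids)


# ---------------------------------------------------------------------------
# flat key-value config files
# ---------------------------------------------------------------------------

_SCALAR_KEYS = {
    "n_epochs_per_class": int, "n_channels": int, "fs": float, "epoch_ms": float,
    "noise_exponent": float, "class_imbalance": float, "rms_amplitude_uv": float,
    "seed": int,
}


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a GeneratorConfig from a flat ``key = value`` text file.

    Scalar keys mirror the dataclass fields. Channel subsets are
    comma-separated indices; oscillations are semicolon-separated
    ``freq,amplitude[,ch0|ch1|...]`` triples under the key
    ``osc_components``. Effect keys: ``spectral_channels`` +
    ``spectral_beta_multiplier``; ``temporal_channels`` +
    ``temporal_amplitude`` + ``temporal_onset_ms``. Lines starting with
    ``#`` are comments.
    """
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        raw[key.strip()] = value.strip()

    kwargs: dict = {}
    for key, cast in _SCALAR_KEYS.items():
        if key in raw:
            kwargs[key] = cast(raw[key])
    if "osc_components" in raw:
        oscs = []
        for part in filter(None, (p.strip() for p in raw["osc_components"].split(";"))):
            bits = part.split(",")
            channels = None
            if len(bits) == 3:
                channels = [int(x) for x in bits[2].split("|")]
            oscs.append(Oscillation(float(bits[0]), float(bits[1]), channels))
        kwargs["osc_components"] = oscs
    if "spectral_channels" in raw:
        kwargs["spectral_effect"] = SpectralEffect(
            channels=[int(x) for x in raw["spectral_channels"].split(",")],
            beta_multiplier=float(raw.get("spectral_beta_multiplier", 1.0)))
    if "temporal_channels" in raw:
        kwargs["temporal_effect"] = TemporalEffect(
            channels=[int(x) for x in raw["temporal_channels"].split(",")],
            amplitude=float(raw.get("temporal_amplitude", 0.0)),
            onset_ms=float(raw.get("temporal_onset_ms", 0.0)))
    if "n_epochs_per_class" not in kwargs:
        raise ConfigError(f"{path}: missing required key n_epochs_per_class")
    return GeneratorConfig(**kwargs)
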