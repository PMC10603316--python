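import numpy as np
import pytest

from prestim import EpochSet, GeneratorConfig, generate_epochs


def make_epochs(data, fs=250.0, labels=None, channel_ids=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = np.arange(data.shape[0]) % 2
    return EpochSet(data=data, fs=fs, labels=labels, channel_ids=channel_ids)


@pytest.fixture(scope="session")
def null_epochs():
    """Small label-exchangeable synthetic set (no injected effect)."""
    return generate_epochs(GeneratorConfig(n_epochs_per_class=20, n_channels=6, seed=42))


@pytest.fixture(scope="session")
def effect_epochs():
    """Small set with a slow negative ramp on the first three channels."""
    from prestim import TemporalEffect
    cfg = GeneratorConfig(
        n_epochs_per_class=30, n_channels=6, seed=7,
        temporal_effect=TemporalEffect(channels=[0, 1, 2], amplitude=-3.0, onset_ms=0),
    )
    return generate_epochs(cfg)
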