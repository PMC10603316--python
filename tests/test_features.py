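"""Feature families: dimensionality identities, hand-computed ratios, segmentation."""

import numpy as np
import pytest
import scipy.stats

from prestim import (BandDefinition, GeneratorConfig, Psd, band_totals,
                     dynamic_spectral_features, dynamic_temporal_features,
                     generate_epochs, segment_epoch, segment_times,
                     static_spectral_features, static_temporal_features)
from prestim.features import FeatureError, _spectral_from_psd
from tests.conftest import make_epochs


def flat_psd(value, n_channels=2, n_epochs=1, fmax=125):
    freqs = np.arange(fmax + 1, dtype=float)
    values = np.full((n_epochs, n_channels, freqs.size), float(value))
    return Psd(freqs=freqs, values=values, resolution=1.0)


class TestBandTotals:
    def test_constant_e_gives_bin_counts(self):
        # log(e) = 1 per bin: theta has 2 bins (4,5), alpha 7 (6..12), beta 17 (13..29)
        theta, alpha, beta = band_totals(flat_psd(np.e))
        np.testing.assert_allclose(theta, 2.0)
        np.testing.assert_allclose(alpha, 7.0)
        np.testing.assert_allclose(beta, 17.0)

    def test_constant_one_gives_zero(self):
        for tot in band_totals(flat_psd(1.0)):
            np.testing.assert_allclose(tot, 0.0)

    def test_hand_summed_random_spectrum(self):
        rng = np.random.default_rng(0)
        freqs = np.arange(31, dtype=float)
        values = rng.uniform(0.5, 4.0, size=(1, 1, 31))
        psd = Psd(freqs=freqs, values=values, resolution=1.0)
        theta, alpha, beta = band_totals(psd)
        assert theta[0, 0] == pytest.approx(sum(np.log(values[0, 0, f]) for f in (4, 5)))
        assert alpha[0, 0] == pytest.approx(sum(np.log(values[0, 0, f]) for f in range(6, 13)))
        assert beta[0, 0] == pytest.approx(sum(np.log(values[0, 0, f]) for f in range(13, 30)))

    def test_closed_edges_double_count_boundaries(self):
        bands = BandDefinition(edge_convention="closed")
        theta, alpha, beta = band_totals(flat_psd(np.e), bands)
        assert (theta[0, 0], alpha[0, 0], beta[0, 0]) == (3.0, 8.0, 18.0)

    def test_nonpositive_bin_rejected(self):
        with pytest.raises(FeatureError):
            band_totals(flat_psd(0.0))


class TestStaticSpectral:
    def test_ratio_vector_from_constant_psd(self):
        ep = make_epochs(np.zeros((1, 2, 250)), labels=[0])
        fm = _spectral_from_psd(flat_psd(np.e), ep, BandDefinition(), False, None)
        np.testing.assert_allclose(fm.values[0], [17 / 7, 2 / 17, 17 / 7, 2 / 17])

    def test_inversion_flag(self):
        ep = make_epochs(np.zeros((1, 2, 250)), labels=[0])
        fm = _spectral_from_psd(flat_psd(np.e), ep, BandDefinition(), True, None)
        np.testing.assert_allclose(fm.values[0], [17 / 7, 17 / 2, 17 / 7, 17 / 2])

    @pytest.mark.parametrize("n_channels", [2, 5, 16])
    def test_dimensionality_is_twice_channels(self, n_channels):
        ep = generate_epochs(GeneratorConfig(n_epochs_per_class=2, n_channels=n_channels, seed=0))
        fm = static_spectral_features(ep)
        assert fm.values.shape == (4, 2 * n_channels)
        np.testing.assert_array_equal(fm.feature_channel_map,
                                      np.repeat(np.arange(n_channels), 2))

    def test_identical_epochs_identical_rows(self):
        rng = np.random.default_rng(2)
        trace = rng.standard_normal((1, 3, 250))
        ep = make_epochs(np.repeat(trace, 2, axis=0), labels=[0, 1])
        fm = static_spectral_features(ep)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_channel_permutation_equivariance(self, null_epochs):
        perm = np.array([3, 0, 5, 1, 4, 2])
        fm = static_spectral_features(null_epochs)
        permuted = make_epochs(null_epochs.data[:, perm], labels=null_epochs.labels)
        fm_p = static_spectral_features(permuted)
        # feature block of channel perm[j] in the original appears at block j
        orig_blocks = fm.values.reshape(fm.n_instances, -1, 2)
        perm_blocks = fm_p.values.reshape(fm.n_instances, -1, 2)
        np.testing.assert_allclose(perm_blocks, orig_blocks[:, perm], atol=1e-12)


class TestStaticTemporal:
    @pytest.mark.parametrize("n_channels", [3, 8])
    def test_dimensionality_and_zscore(self, n_channels):
        ep = generate_epochs(GeneratorConfig(n_epochs_per_class=2, n_channels=n_channels, seed=1))
        fm = static_temporal_features(ep)
        assert fm.values.shape == (4, 20 * n_channels)
        blocks = fm.values.reshape(4, n_channels, 20)
        np.testing.assert_allclose(blocks.mean(axis=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(blocks.std(axis=-1, ddof=1), 1.0, atol=1e-12)

    def test_sinusoid_channel_matches_analytic(self):
        t = np.arange(250) / 250.0
        x = np.sin(2 * np.pi * 2.0 * t)
        ep = make_epochs(np.tile(x, (1, 2, 1)), labels=[0])
        fm = static_temporal_features(ep)
        got = fm.values[0, :20]
        y = np.sin(2 * np.pi * 2.0 * np.arange(20) / 20.0)
        expected = (y - y.mean()) / y.std(ddof=1)
        core = slice(2, -2)
        assert np.abs(got[core] - expected[core]).max() < 0.03 * np.abs(expected).max()

    def test_flat_channel_rejected(self):
        data = np.random.default_rng(0).standard_normal((1, 2, 250))
        data[0, 1] = 0.0
        with pytest.raises(FeatureError, match="ch1"):
            static_temporal_features(make_epochs(data, labels=[0]))


class TestSegmentation:
    def test_count_and_times(self, null_epochs):
        segs = segment_epoch(null_epochs)
        assert len(segs) == 125
        times = segment_times(len(segs), null_epochs.fs)
        assert times[0] == 0.0
        assert times[-1] == pytest.approx(0.496)

    def test_sliding_indices_exhaustive(self, null_epochs):
        segs = segment_epoch(null_epochs)
        for i, seg in enumerate(segs):
            np.testing.assert_array_equal(seg.data, null_epochs.data[:, :, i:i + 125])

    def test_window_longer_than_epoch_rejected(self):
        ep = make_epochs(np.zeros((1, 2, 100)), labels=[0])
        with pytest.raises(ValueError):
            segment_epoch(ep, window_ms=500.0)


@pytest.fixture(scope="module")
def small():
    return generate_epochs(GeneratorConfig(n_epochs_per_class=2, n_channels=4, seed=3))


class TestDynamicFeatures:

    def test_dynamic_spectral_shapes(self, small):
        out = dynamic_spectral_features(small)
        assert len(out) == 125
        assert all(fm.values.shape == (4, 8) for fm in out)
        assert [fm.segment_index for fm in out] == list(range(125))

    def test_dynamic_temporal_shapes_and_zscore(self, small):
        out = dynamic_temporal_features(small)
        assert len(out) == 125
        assert all(fm.values.shape == (4, 40) for fm in out)
        blocks = out[60].values.reshape(4, 4, 10)
        np.testing.assert_allclose(blocks.mean(axis=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(blocks.std(axis=-1, ddof=1), 1.0, atol=1e-12)

    def test_stationary_segment_tracks_static_band_structure(self):
        # on stationary data with channel-specific rhythms, a window's
        # spectral features track the whole-epoch features across channels;
        # the 16-sample Hamming window's coarse (15.6 Hz) resolution smears
        # the bands, so agreement is strong but not exact
        from prestim import GeneratorConfig, Oscillation, generate_epochs
        cfg = GeneratorConfig(
            n_epochs_per_class=2, n_channels=6, seed=3,
            osc_components=[Oscillation(10.0, 2.0, [0, 1, 2]),
                            Oscillation(20.0, 2.0, [3, 4, 5])])
        ep = generate_epochs(cfg)
        static = static_spectral_features(ep).values
        for idx in (10, 110):
            seg = dynamic_spectral_features(ep)[idx].values
            r = scipy.stats.pearsonr(static.ravel(), seg.ravel())[0]
            assert r > 0.7


def test_null_class_means_indistinguishable():
    """On effect-free data, per-feature class-mean t-tests reject at ~alpha."""
    pvals = []
    for seed in range(50):
        ep = generate_epochs(GeneratorConfig(n_epochs_per_class=15, n_channels=4, seed=seed))
        fm = static_spectral_features(ep)
        hi = fm.values[fm.labels == 1]
        lo = fm.values[fm.labels == 0]
        p = scipy.stats.ttest_ind(hi, lo, axis=0).pvalue
        pvals.extend(p.tolist())
    rate = np.mean(np.asarray(pvals) < 0.01)
    assert rate < 0.03
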