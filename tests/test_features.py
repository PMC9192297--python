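import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegpotato.features import (
    SampEnParams,
    WelchConfig,
    epoch_features,
    mean_psd,
    pearson_correlation,
    sampen_counts,
    sample_entropy,
    welch_psd,
)
from eegpotato.io import Epoch
from oracles import brute_force_sampen_counts


class TestPearsonCorrelation:
    def test_perfect_positive(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_correlation([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1, var = 1.25 each -> rho = 1/1.25 = 0.8
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        r = pearson_correlation(x, y)
        assert pearson_correlation(y, x) == pytest.approx(r)
        assert pearson_correlation(3.0 * x + 7.0, y) == pytest.approx(r)
        assert abs(r) <= 1 + 1e-12


class TestWelchPsd:
    def test_all_zero_input(self):
        spec = welch_psd(np.zeros(1024), fs=256.0)
        assert np.all(spec.power == 0)

    def test_white_noise_variance_identity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60 * 256)
        x = (x - x.mean()) / x.std()
        spec = welch_psd(x, fs=256.0)
        assert abs(np.sum(spec.power) * spec.df - 1.0) < 0.1

    def test_pure_tone_peaks_at_its_bin(self):
        t = np.arange(4 * 256) / 256.0
        spec = welch_psd(np.sin(2 * np.pi * 10 * t), fs=256.0, seg_len=256)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(10.0)

    def test_rectangular_norm_factor_is_one(self):
        spec = welch_psd(np.random.default_rng(1).standard_normal(512), 256.0)
        assert spec.norm_factor == pytest.approx(1.0)
        assert spec.n_segments == 3  # 2 s epoch, 1 s segments, 50% overlap

    def test_single_segment_equals_periodogram(self):
        # independent oracle: plain one-sided periodogram of the
        # mean-removed series with density scaling
        rng = np.random.default_rng(2)
        x = rng.standard_normal(256)
        spec = welch_psd(x, fs=256.0, seg_len=256, overlap=0.0)
        xc = x - x.mean()
        f = np.fft.rfft(xc)
        pxx = (np.abs(f) ** 2) / (256.0 * 256)
        pxx[1:-1] *= 2  # one-sided
        assert spec.n_segments == 1
        np.testing.assert_allclose(spec.power, pxx, atol=1e-12)

    def test_seg_len_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 256.0, seg_len=256)


class TestMeanPsd:
    def test_flat_spectrum(self):
        spec = welch_psd(np.zeros(512), 256.0)
        spec.power = np.full_like(spec.power, 3.5)
        assert mean_psd(spec, (0.5, 100.0)) == pytest.approx(3.5)

    def test_single_bin_band(self):
        spec = welch_psd(np.zeros(512), 256.0)
        spec.power = np.arange(len(spec.freqs), dtype=float)
        k = 10
        f = spec.freqs[k]
        assert mean_psd(spec, (f, f)) == pytest.approx(spec.power[k])

    def test_white_noise_flatness(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(120 * 256)
        spec = welch_psd(x, 256.0)
        full = mean_psd(spec, (0.5, 128.0))
        half = mean_psd(spec, (0.5, 64.0))
        assert half == pytest.approx(full, rel=0.05)

    def test_empty_band_rejected(self):
        spec = welch_psd(np.zeros(512), 256.0)
        with pytest.raises(ValueError):
            mean_psd(spec, (10.2, 10.4))  # between 1 Hz bins


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(64, 5.0)) == 0.0

    def test_alternating_series_is_zero(self):
        x = np.array([0.0, 1.0] * 32)
        assert sample_entropy(x, SampEnParams(m=2, r=0.2)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(200)
        assert sampen_counts(x, SampEnParams(2, 0.2)) == \
            brute_force_sampen_counts(x, 2, 0.2)

    @pytest.mark.parametrize("m,r", [(1, 0.1), (3, 0.5)])
    def test_oracle_equivalence_other_params(self, m, r):
        x = np.random.default_rng(99).standard_normal(150)
        assert sampen_counts(x, SampEnParams(m, r)) == \
            brute_force_sampen_counts(x, m, r)

    def test_monotone_non_increasing_in_r(self):
        x = np.random.default_rng(7).standard_normal(300)
        values = [sample_entropy(x, SampEnParams(2, r))
                  for r in (0.1, 0.2, 0.3, 0.5, 1.0)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0, 3.0]), SampEnParams(m=2))

    def test_non_finite_rejected(self):
        x = np.ones(50)
        x[3] = np.nan
        with pytest.raises(ValueError):
            sample_entropy(x)


class TestEpochFeatures:
    def make_epoch(self, rng, channels):
        data = rng.standard_normal((len(channels), 512))
        return Epoch(index=0, start_s=0.0, data=data, channel_names=channels,
                     fs=256.0)

    def test_vector_arity(self, rng):
        chans = ["FP1F3", "F7T7", "T7P7", "P3O1", "FP2F4",
                 "F8T8", "T8P8", "P4O2", "FZCZ", "CZPZ"]
        ep = self.make_epoch(rng, chans)
        assert epoch_features(ep, chans).shape == (20,)

    def test_identical_channels_identical_features(self, rng):
        ep = self.make_epoch(rng, ["A", "B"])
        ep.data[1] = ep.data[0]
        v = epoch_features(ep, ["A", "B"])
        assert v[0] == v[2] and v[1] == v[3]

    def test_scale_laws(self, rng):
        ep = self.make_epoch(rng, ["A"])
        v1 = epoch_features(ep, ["A"])
        ep10 = Epoch(index=0, start_s=0.0, data=10.0 * ep.data,
                     channel_names=["A"], fs=256.0)
        v10 = epoch_features(ep10, ["A"])
        assert v10[0] == pytest.approx(100.0 * v1[0], rel=1e-9)  # PSD ~ amp^2
        assert v10[1] == pytest.approx(v1[1])  # SampEn scale-free (r ~ sd)

    def test_missing_channel_named_in_error(self, rng):
        ep = self.make_epoch(rng, ["A"])
        with pytest.raises(KeyError, match="FZCZ"):
            epoch_features(ep, ["A", "FZCZ"])

    def test_all_features_finite_on_synthetic_data(self, seizure_fixture):
        from eegpotato.io import segment_epochs
        _, rec, _ = seizure_fixture
        for ep in segment_epochs(rec)[:20]:
            v = epoch_features(ep, rec.channel_names)
            assert np.isfinite(v).all()
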