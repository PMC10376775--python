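import numpy as np
import pytest

from imaware import entropy as ent
from oracles import ORACLES, apen_oracle, peen_oracle, sampen_oracle


class TestWindowing:
    def test_24_windows_of_1000(self):
        wins = ent.window_epoch(np.arange(24000.0))
        assert wins.shape == (24, 1000)

    def test_window_13_starts_at_reference(self):
        wins = ent.window_epoch(np.arange(24000.0))
        assert wins[12, 0] == 12000.0  # reference = sample 12000 (t = 3 s)

    def test_partition_reconstructs_epoch(self):
        x = np.random.default_rng(0).standard_normal(24000)
        assert np.array_equal(ent.window_epoch(x).ravel(), x)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ent.window_epoch(np.zeros(23999))

    def test_analysis_windows_drop_edges(self):
        keep = ent.analysis_windows()
        assert len(keep) == 22
        assert 0 not in keep and 23 not in keep
        before = [w for w in keep if ent.window_condition(w) == "before"]
        assert len(before) == 11


class TestSpectralEntropy:
    def test_pure_sinusoid_near_zero(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * 50 * t / 1000.0)  # exact bin
        assert ent.spectral_entropy(x) < 0.02

    def test_two_equal_sinusoids(self):
        t = np.arange(1000)
        x = (np.sin(2 * np.pi * 50 * t / 1000.0)
             + np.sin(2 * np.pi * 120 * t / 1000.0))
        n_bins = 501
        assert ent.spectral_entropy(x) == pytest.approx(
            np.log(2) / np.log(n_bins), abs=0.01)

    def test_white_noise_periodogram_level(self, rng):
        """Raw-periodogram ordinates of white noise are iid exponential, so the
        expected normalized entropy is 1 - (1 - gamma)/log(n_bins) ~= 0.93."""
        vals = [ent.spectral_entropy(rng.standard_normal(1000)) for _ in range(20)]
        expected = 1.0 - (1.0 - np.euler_gamma) / np.log(501)
        assert np.mean(vals) == pytest.approx(expected, abs=0.01)

    def test_welch_closer_to_flat(self, rng):
        x = rng.standard_normal(1000)
        welch = ent.spectral_entropy(x, ent.EntropyParams(spectrum="welch"))
        assert welch > 0.95

    def test_all_zero_window(self):
        with pytest.warns(UserWarning):
            assert ent.spectral_entropy(np.zeros(1000)) == 0.0


class TestApproximateEntropy:
    def test_constant_series(self):
        assert ent.approximate_entropy(np.full(100, 2.0)) == 0.0

    def test_alternating_series_matches_oracle(self):
        x = np.tile([1.0, 2.0], 50)
        p = ent.EntropyParams(m=2, r=0.5 / x.std())
        assert ent.approximate_entropy(x, p) == pytest.approx(
            apen_oracle(x, 2, 0.5 / x.std()), abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(300)
        a = ent.approximate_entropy(x)
        b = ent.approximate_entropy(3.7 * x - 11.0)
        assert a == pytest.approx(b, abs=1e-10)


class TestSampleEntropy:
    def test_alternating_series_zero(self):
        x = np.array([1.0, 2.0] * 4)
        p = ent.EntropyParams(m=2, r=0.5 / x.std())
        assert ent.sample_entropy(x, p) == pytest.approx(0.0, abs=1e-12)

    def test_constant_series(self):
        assert ent.sample_entropy(np.full(50, 1.0)) == 0.0

    def test_close_to_apen_for_long_iid(self):
        x = np.random.default_rng(0).standard_normal(8000)
        a = ent.approximate_entropy(x)
        s = ent.sample_entropy(x)
        assert abs(a - s) / s < 0.05

    def test_no_matches_returns_nan(self):
        x = np.arange(10.0) ** 3
        p = ent.EntropyParams(m=2, r=1e-6)
        with pytest.warns(UserWarning):
            assert np.isnan(ent.sample_entropy(x, p))


class TestPermutationEntropy:
    def test_monotone_series_zero(self):
        assert ent.permutation_entropy(np.arange(50.0)) == 0.0

    def test_hand_enumerated_example(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        p = ent.EntropyParams(order=2)
        # 4 ascents, 2 descents -> H = H(2/3, 1/3)/log 2 = 0.9183
        assert ent.permutation_entropy(x, p) == pytest.approx(0.91829583, abs=1e-8)

    def test_uniform_noise_saturates(self, rng):
        x = rng.uniform(size=1000)
        assert ent.permutation_entropy(x) == pytest.approx(1.0, abs=0.02)

    def test_constant_series_single_pattern(self):
        # stable tie-breaking: all windows map to the identity pattern
        assert ent.permutation_entropy(np.zeros(100)) == 0.0

    def test_tie_rule_matches_oracle(self):
        x = np.array([1.0, 1.0, 2.0, 2.0, 1.0, 2.0, 1.0, 1.0, 2.0])
        assert ent.permutation_entropy(x) == pytest.approx(
            peen_oracle(x), abs=1e-12)


class TestSvdEntropy:
    def test_constant_nonzero_rank_one(self):
        assert ent.svd_entropy(np.full(100, 5.0)) == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_saturates(self, rng):
        x = rng.standard_normal(5000)
        assert ent.svd_entropy(x) > 0.97

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal(500)
        assert ent.svd_entropy(x) == pytest.approx(ent.svd_entropy(-x), abs=1e-12)

    def test_all_zero_window(self):
        with pytest.warns(UserWarning):
            assert ent.svd_entropy(np.zeros(100)) == 0.0


class TestOracleEquivalence:
    """Each estimator must agree with its brute-force oracle exactly."""

    @pytest.mark.parametrize("measure", ent.MEASURES)
    def test_random_sequences(self, measure, rng):
        params = ent.EntropyParams()
        oracle = ORACLES[measure]
        import warnings

        for _ in range(20):
            x = rng.standard_normal(50)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # SaEn may be undefined at n=50
                fast = ent._FUNCS[measure](x, params)
            if measure in ("ApEn", "SaEn"):
                ref = oracle(x, params.m, params.r)
            else:
                ref = oracle(x)
            assert fast == pytest.approx(ref, abs=1e-10, nan_ok=True)

    def test_shared_pass_matches_individual_estimators(self, rng):
        x = rng.standard_normal(200)
        vals = ent.window_measures(x)
        assert vals["ApEn"] == pytest.approx(ent.approximate_entropy(x), abs=1e-12)
        assert vals["SaEn"] == pytest.approx(ent.sample_entropy(x), abs=1e-12)


class TestAffineInvariance:
    @pytest.mark.parametrize("measure", ent.MEASURES)
    def test_scaling_invariance(self, measure, rng):
        x = rng.standard_normal(300)
        f = ent._FUNCS[measure]
        a = f(x, ent.EntropyParams())
        b = f(5.0 * x, ent.EntropyParams())
        assert a == pytest.approx(b, abs=1e-9)


class TestEpochFeatures:
    def test_feature_table_shape(self, small_synthetic_dataset):
        ds = small_synthetic_dataset
        feats = ent.compute_features(ds.epochs, "S01", measures=("PeEn", "SpEn"))
        # 8 trials x 22 windows x 9 single-electrode clusters x 2 measures
        assert len(feats) == 8 * 22 * 9 * 2
        assert set(feats["condition"]) == {"before", "after"}
        assert set(feats["measure"]) == {"PeEn", "SpEn"}

    def test_fc_shift_sign_pattern(self, small_synthetic_dataset):
        """All five measures respond positively to the fronto-central
        broadband admixture on hit trials."""
        ds = small_synthetic_dataset
        feats = ent.compute_features(ds.epochs, "S01")
        means = feats.groupby(["measure", "cluster", "detection"],
                              observed=True)["value"].mean()
        for measure in ent.MEASURES:
            assert (means[measure, "FC", "hit"]
                    > means[measure, "FC", "miss"]), measure
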