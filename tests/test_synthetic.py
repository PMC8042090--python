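"""Generators: shapes, reproducibility, moments, and the z-score transform."""

import numpy as np
import pytest
from scipy import stats

from leakage_lab import (
    ConnectivitySpec,
    GaussianGridSpec,
    ZScoreStats,
    generate_connectivity_features,
    generate_gaussian_features,
    generate_null_features,
    zscore_standardize,
)
from leakage_lab.datatypes import FeatureMatrix
from leakage_lab.synthetic import DEFAULT_CHANNELS, build_connectivity_index


class TestGaussianGenerator:
    def test_default_spec_dimensions(self):
        fm = generate_gaussian_features(GaussianGridSpec(seed=0))
        assert fm.n_features == 6424
        assert fm.n_samples == 116
        assert fm.class_counts() == (58, 58)

    def test_fixed_seed_bit_identical(self):
        spec = GaussianGridSpec(n_features=40, n_per_class=10, seed=3)
        a = generate_gaussian_features(spec)
        b = generate_gaussian_features(spec)
        assert np.array_equal(a.values, b.values)

    def test_zero_mean_grid_gives_null_mean_difference(self):
        spec = GaussianGridSpec(
            n_features=400, n_per_class=200, mean_grid=(0.0,), per_class_draw=True, seed=4
        )
        fm = generate_gaussian_features(spec)
        diffs = fm.values[fm.labels == 0].mean(0) - fm.values[fm.labels == 1].mean(0)
        # each diff is ~N(0, 2*var/n); pooled check against the widest grid variance
        assert np.abs(diffs).max() < 5 * np.sqrt(2 * 2.3 / 200)

    def test_sample_moments_match_drawn_grid_pairs(self):
        """Moment-matching oracle: per-class sample mean/variance recover the
        drawn (mean, variance) pair within 3 standard errors at n=5000."""
        spec = GaussianGridSpec(n_features=50, n_per_class=5000, per_class_draw=True, seed=5)
        fm, params = generate_gaussian_features(spec, return_params=True)
        n = 5000
        for c in (0, 1):
            block = fm.values[fm.labels == c]
            mean_se = np.sqrt(params.class_vars[c] / n)
            assert np.all(np.abs(block.mean(0) - params.class_means[c]) < 3 * mean_se)
            var_se = params.class_vars[c] * np.sqrt(2.0 / (n - 1))
            assert np.all(np.abs(block.var(0, ddof=1) - params.class_vars[c]) < 3 * var_se)

    def test_per_class_draw_mean_mismatch_fraction(self):
        """With independent grid draws per class, two class means differ with
        probability 1 - 1/|mean_grid| (independent uniforms over grid points)."""
        spec = GaussianGridSpec(n_features=8000, n_per_class=2, per_class_draw=True, seed=6)
        _, params = generate_gaussian_features(spec, return_params=True)
        frac = np.mean(params.class_means[0] != params.class_means[1])
        expected = 1 - 1 / len(spec.mean_grid)
        se = np.sqrt(expected * (1 - expected) / 8000)
        assert abs(frac - expected) < 3 * se

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_per_class": 1},
            {"var_grid": (0.0, 0.1)},
            {"var_grid": (-1.0,)},
            {"mean_grid": ()},
            {"grid_mode": "other"},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GaussianGridSpec(n_features=10, **{"n_per_class": 5, **kwargs})


class TestNullGenerator:
    def test_single_feature_boundary(self):
        fm = generate_null_features(1, 5, seed=1)
        assert fm.values.shape == (10, 1)

    def test_type_one_error_rate_near_alpha(self):
        """Both classes share one distribution per feature, so the two-sided
        t-test at alpha=0.05 should reject for ~5% of features."""
        fm = generate_null_features(6424, 58, seed=2)
        x0 = fm.values[fm.labels == 0]
        x1 = fm.values[fm.labels == 1]
        _, p = stats.ttest_ind(x0, x1, axis=0)
        rate = (p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 6424)
        assert abs(rate - 0.05) < 3 * se


class TestConnectivityGenerator:
    def test_index_enumerates_all_edges(self):
        index = build_connectivity_index()
        assert len(DEFAULT_CHANNELS) == 45
        assert len(index) == 45 * 44 // 2 * 6 == 5940

    def test_default_spec_shape_and_range(self):
        fm, index = generate_connectivity_features(ConnectivitySpec(n_per_class=10, seed=3))
        assert fm.n_features == 5940
        assert len(index) == 5940
        assert fm.values.min() > 0.0 and fm.values.max() < 1.0

    def test_zero_effect_gives_identical_distributions(self):
        spec = ConnectivitySpec(
            n_per_class=300,
            planted_edges=[("Fp1", "F3", "theta", 0.0)],
            seed=4,
        )
        fm, index = generate_connectivity_features(spec)
        col = index.feature_ids.index(index.feature_id_for("Fp1", "F3", "theta"))
        _, p = stats.ttest_ind(
            fm.values[fm.labels == 0, col], fm.values[fm.labels == 1, col]
        )
        assert p > 0.01

    def test_planted_edge_shifts_class_means(self):
        spec = ConnectivitySpec(n_per_class=100, seed=5)
        fm, index = generate_connectivity_features(spec)
        col = index.feature_ids.index(index.feature_id_for("Fp1", "F3", "theta"))
        d = fm.values[fm.labels == 1, col].mean() - fm.values[fm.labels == 0, col].mean()
        assert d > 0.15  # logit shift 1.5 around baseline -0.4 moves PLV by ~0.3

    def test_unknown_planted_edge_rejected(self):
        spec = ConnectivitySpec(planted_edges=[("Fp1", "XX9", "theta", 1.0)])
        with pytest.raises(KeyError):
            generate_connectivity_features(spec)


class TestZScore:
    def test_self_standardization_and_idempotence(self, small_null_matrix):
        std, stats_used = zscore_standardize(small_null_matrix)
        assert np.allclose(std.values.mean(0), 0.0, atol=1e-12)
        assert np.allclose(std.values.std(0, ddof=1), 1.0, atol=1e-12)
        again, _ = zscore_standardize(std, ZScoreStats(np.zeros(std.n_features),
                                                      np.ones(std.n_features)))
        assert np.allclose(again.values, std.values)

    def test_reference_stats_hand_example(self):
        fm = FeatureMatrix(
            np.array([[2.0], [4.0], [2.0], [4.0]]), [0, 0, 1, 1], ["f"], list("abcd")
        )
        out, _ = zscore_standardize(fm, ZScoreStats(np.array([3.0]), np.array([1.0])))
        assert np.allclose(out.values.ravel(), [-1.0, 1.0, -1.0, 1.0])

    def test_zero_sd_feature_warns_and_zeroes(self, caplog):
        fm = FeatureMatrix(
            np.column_stack([np.ones(6), np.arange(6.0)]),
            [0, 0, 0, 1, 1, 1],
            ["const", "var"],
            list("abcdef"),
        )
        with caplog.at_level("WARNING", logger="leakage_lab.synthetic"):
            out, _ = zscore_standardize(fm)
        assert np.all(out.values[:, 0] == 0.0)
        assert any("zero-SD" in r.message for r in caplog.records)


def test_feature_matrix_tsv_round_trip(tmp_path, planted_matrix):
    path = tmp_path / "m.tsv"
    planted_matrix.to_tsv(path)
    back = FeatureMatrix.from_tsv(path)
    assert back.feature_ids == planted_matrix.feature_ids
    assert back.sample_ids == planted_matrix.sample_ids
    assert np.allclose(back.values, planted_matrix.values)
    assert np.array_equal(back.labels, planted_matrix.labels)


def test_connectivity_index_tsv_round_trip(tmp_path):
    index = build_connectivity_index(DEFAULT_CHANNELS[:8])
    path = tmp_path / "idx.tsv"
    index.to_tsv(path)
    from leakage_lab.datatypes import ConnectivityIndex

    back = ConnectivityIndex.from_tsv(path, DEFAULT_CHANNELS[:8])
    assert back.feature_ids == index.feature_ids
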