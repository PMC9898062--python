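"""Scaling, log transform, mean-shift clustering, typing, composition."""

from __future__ import annotations

import numpy as np
import pytest

from myotyper.fibertype import (
    ClusterModel,
    TypingConfig,
    assign_types,
    choose_bandwidth,
    cluster_fibers,
    composition,
    log_transform,
    mean_shift,
    prune_clusters,
    scale_per_sample,
)


class TestScaling:
    def test_constant_column_becomes_one(self):
        x = np.full((20, 3), 7.0)
        out = scale_per_sample(x, ["A"] * 20)
        np.testing.assert_allclose(out, 1.0)

    def test_per_sample_rms_is_one(self, mfi_df):
        mat = mfi_df[["myhc1", "myhc2a", "myhc2x"]].to_numpy()
        out = scale_per_sample(mat, mfi_df["sample"].to_numpy())
        for s in mfi_df["sample"].unique():
            block = out[(mfi_df["sample"] == s).to_numpy()]
            np.testing.assert_allclose(
                np.sqrt((block**2).mean(axis=0)), 1.0, atol=1e-9
            )

    def test_samples_scaled_independently(self):
        rng = np.random.default_rng(1)
        a = rng.random((30, 3)) + 0.1
        b = rng.random((30, 3)) + 0.1
        samples = ["A"] * 30 + ["B"] * 30
        out1 = scale_per_sample(np.vstack([a, b]), samples)
        out2 = scale_per_sample(np.vstack([a, b * 100]), samples)
        np.testing.assert_allclose(out1[:30], out2[:30])
        np.testing.assert_allclose(out1[30:], out2[30:])  # gain invariant

    def test_zero_column_raises_with_sample_name(self):
        x = np.ones((10, 3))
        x[:, 1] = 0.0
        with pytest.raises(ValueError, match="'A'"):
            scale_per_sample(x, ["A"] * 10)


class TestLogTransform:
    @pytest.mark.parametrize(
        "value,expected", [(1.0, 0.0), (np.e, 1.0), (np.e**2, 2.0)]
    )
    def test_known_values(self, value, expected):
        assert log_transform(np.array([[value]]))[0, 0] == pytest.approx(expected)

    def test_zero_hits_floor(self):
        out = log_transform(np.array([[0.0]]), zero_floor=1e-6)
        assert out[0, 0] == pytest.approx(np.log(1e-6))
        assert np.isfinite(out).all()


class TestMeanShift:
    def test_single_point_one_mode_at_point(self):
        modes, labels = mean_shift(np.array([[2.0, 3.0]]), TypingConfig(bandwidth_h=0.5))
        assert labels.tolist() == [1]
        np.testing.assert_allclose(modes, [[2.0, 3.0]], atol=1e-9)

    def test_two_tight_blobs_two_modes(self):
        h = 0.3
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.02 * h, size=(40, 2))
        b = rng.normal(10 * h, 0.02 * h, size=(40, 2))
        pts = np.vstack([a, b])
        modes, labels = mean_shift(pts, TypingConfig(bandwidth_h=h))
        assert len(modes) == 2
        # nearest-blob oracle: labels partition exactly at the blobs
        assert len(set(labels[:40])) == 1
        assert len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_huge_bandwidth_single_mode(self):
        rng = np.random.default_rng(3)
        pts = rng.random((50, 3))
        modes, labels = mean_shift(pts, TypingConfig(bandwidth_h=10.0))
        assert len(modes) == 1
        assert set(labels.tolist()) == {1}

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError, match="finite"):
            mean_shift(np.array([[np.nan, 1.0]]), TypingConfig())

    def test_mode_count_nonincreasing_in_h(self):
        """Coarser bandwidths can only merge modes, never create them."""
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        pts = np.vstack(
            [c + rng.normal(0, 0.03, size=(30, 2)) for c in centers]
        )
        counts = []
        for h in (0.05, 0.1, 0.2, 0.4, 0.8):
            modes, _ = mean_shift(pts, TypingConfig(bandwidth_h=h))
            counts.append(len(modes))
        assert counts == sorted(counts, reverse=True)


class TestPruning:
    def test_small_cluster_pruned_and_renormalized(self):
        labels = np.array([1] * 50 + [2] * 49 + [3])
        new, kept, props = prune_clusters(labels, min_prop=0.02)
        assert kept.tolist() == [1, 2]
        assert (new[labels == 3] == 0).all()
        assert props.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(props, [50 / 99, 49 / 99])

    def test_nothing_below_threshold_unchanged(self):
        labels = np.array([1] * 50 + [2] * 50)
        new, kept, props = prune_clusters(labels, min_prop=0.02)
        np.testing.assert_array_equal(new, labels)

    def test_all_pruned_raises(self):
        labels = np.arange(1, 101)  # 100 singleton clusters, 1% each
        with pytest.raises(ValueError, match="below"):
            prune_clusters(labels, min_prop=0.02)


def _model(points, labels, names=None, samples=None):
    k = int(labels.max())
    counts = np.bincount(labels[labels > 0], minlength=k + 1)[1:]
    return ClusterModel(
        points=points,
        modes=np.zeros((k, points.shape[1])),
        labels=labels,
        proportions=counts / counts.sum(),
        sample_ids=np.asarray(
            samples if samples is not None else ["S1"] * len(labels)
        ),
        type_names=names or [],
    )


class TestAssignTypes:
    def test_dominant_isoform_names_cluster(self):
        pts = np.vstack(
            [
                np.tile([0.0, 2.0, 0.0], (50, 1)),  # MyHC2A dominant
                np.tile([2.0, 0.0, 0.0], (50, 1)),  # MyHC1 dominant
            ]
        )
        m = _model(pts, np.array([1] * 50 + [2] * 50))
        assert assign_types(m) == ["type2A", "type1"]

    def test_close_top_two_is_hybrid(self):
        pts = np.vstack(
            [
                np.tile([0.0, 2.0, 1.95], (50, 1)),  # 2A vs 2X within margin
                np.tile([2.0, 0.0, 0.0], (50, 1)),
            ]
        )
        m = _model(pts, np.array([1] * 50 + [2] * 50))
        names = assign_types(m, TypingConfig(hybrid_margin=0.2))
        assert names[0].startswith("hybrid") and "2A" in names[0] and "2X" in names[0]

    def test_all_dim_cluster_is_low_myhc(self):
        pts = np.vstack(
            [
                np.tile([-9.0, -9.1, -9.2], (10, 1)),
                np.tile([2.0, 0.0, 0.0], (90, 1)),
            ]
        )
        m = _model(pts, np.array([1] * 10 + [2] * 90))
        names = assign_types(m, TypingConfig(low_intensity_quantile=0.10))
        assert names[0] == "low-MyHC"


class TestComposition:
    def test_single_cluster_proportion_one(self):
        pts = np.zeros((20, 3))
        m = _model(pts, np.ones(20, dtype=int), names=["type1"])
        comp = composition(m)
        assert comp.iloc[0, 0] == pytest.approx(1.0)

    def test_pruned_excluded_from_denominator(self):
        labels = np.array([1] * 30 + [2] * 30 + [0] * 40)
        m = _model(np.zeros((100, 3)), labels, names=["type1", "type2A"])
        comp = composition(m)
        np.testing.assert_allclose(comp.iloc[0].to_numpy(float), [0.5, 0.5])

    def test_rows_sum_to_one(self, sweep_models):
        for m in sweep_models.values():
            comp = composition(m)
            sums = comp.sum(axis=1).to_numpy(float)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_sample_without_fibers_warns_nan_row(self):
        labels = np.array([1] * 30 + [0] * 10)
        samples = ["A"] * 30 + ["B"] * 10
        m = _model(np.zeros((40, 3)), labels, names=["type1"], samples=samples)
        with pytest.warns(UserWarning, match="'B'"):
            comp = composition(m)
        assert np.isnan(comp.loc["B"].to_numpy(float)).all()


class TestClusterFibers:
    def test_recovers_three_types(self, mfi_df, sweep_models):
        from sklearn.metrics import adjusted_rand_score

        h = choose_bandwidth(sweep_models)
        model = sweep_models[h]
        assert 3 <= model.n_clusters <= 8
        assert model.pruned_fraction <= 0.02
        ari = adjusted_rand_score(
            mfi_df["true_type"].to_numpy(), model.labels
        )
        assert ari >= 0.9

    def test_unexpected_cluster_count_warns_not_errors(self, mfi_df):
        mat = mfi_df[["myhc1", "myhc2a", "myhc2x"]].to_numpy()[:300]
        with pytest.warns(UserWarning, match="expected"):
            model = cluster_fibers(
                mat,
                mfi_df["sample"].to_numpy()[:300],
                TypingConfig(bandwidth_h=0.5),  # absurdly coarse: 1 cluster
            )
        assert model.n_clusters < 3
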