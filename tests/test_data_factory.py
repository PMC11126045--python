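import numpy as np
import pytest

from aifcorr.grid import TimeGrid, ConcentrationCurve
from aifcorr.aif_population import sample_aif_params, evaluate_aif
from aifcorr.sequence_signal import NOMINAL_BIAS
from aifcorr.data_factory import (
    DatasetSpec,
    make_curve_set,
    make_dataset,
    save_dataset,
    load_dataset,
    simulate_pixel_curves,
    cluster_tissue_curves,
    preprocess_curve,
)


class TestMakeCurveSet:
    def test_nominal_noise_free_round_trip(self, dictionary):
        spec = DatasetSpec(n_train=1, n_val=1, n_test=1, n_tissue=10, noisy=False)
        cs = make_curve_set(np.random.default_rng(0), spec, dictionary, bias=NOMINAL_BIAS)
        err = 100 * abs(cs.saturated_aif.peak - cs.true_aif.peak) / cs.true_aif.peak
        assert err < 0.5

    def test_ladder_ktrans_values(self, dictionary):
        spec = DatasetSpec(n_train=1, n_val=1, n_test=1, n_tissue=10)
        cs = make_curve_set(np.random.default_rng(0), spec, dictionary)
        np.testing.assert_allclose(
            [p.ktrans for p in cs.pk_params], np.arange(0.3, 2.2, 0.2)
        )
        assert len(cs.tissue_curves) == 10

    def test_seeded_bit_reproducibility(self, dictionary):
        spec = DatasetSpec(n_train=1, n_val=1, n_test=1, n_tissue=3)
        a = make_curve_set(np.random.default_rng(42), spec, dictionary)
        b = make_curve_set(np.random.default_rng(42), spec, dictionary)
        np.testing.assert_array_equal(a.saturated_aif.values, b.saturated_aif.values)
        assert a.bias == b.bias
        assert a.aif_params == b.aif_params


class TestMakeDataset:
    def test_split_sizes_and_shapes(self, small_splits):
        splits, spec = small_splits
        assert splits["train"].n_sets == spec.n_train
        assert splits["val"].n_sets == spec.n_val
        assert splits["test"].n_sets == spec.n_test
        assert splits["train"].tissue.shape == (spec.n_train, 10, 120)

    def test_split_disjointness(self, small_splits):
        splits, _ = small_splits
        # different substreams: no training AIF reappears in the test split
        assert not np.isclose(
            splits["train"].true_aif[:, None, :], splits["test"].true_aif[None, :, :]
        ).all(axis=-1).any()

    def test_bit_reproducibility(self, small_splits, dictionary):
        splits, spec = small_splits
        again = make_dataset(spec, dictionary)
        for name in ("train", "val", "test"):
            np.testing.assert_array_equal(again[name].sat_aif, splits[name].sat_aif)
            np.testing.assert_array_equal(again[name].pk, splits[name].pk)

    def test_hybrid_validation_bias_range(self, dictionary):
        spec = DatasetSpec(
            n_train=30, n_val=30, n_test=2, n_tissue=4,
            bias_mode="one_sided", bias_magnitude=0.10, val_bias_magnitude=0.15,
            noisy=False, seed=5,
        )
        splits = make_dataset(spec, dictionary)
        assert np.all(splits["train"].bias[:, 0] >= 1.0)
        assert splits["train"].bias[:, 0].max() <= 1.10
        assert splits["val"].bias[:, 0].max() <= 1.15
        # with ~30 draws the widened range is actually exercised
        assert splits["val"].bias[:, 0].max() > 1.10

    def test_save_load_lossless(self, small_splits, tmp_path):
        splits, spec = small_splits
        path = tmp_path / "ds.h5"
        save_dataset(splits, spec, path)
        loaded, loaded_spec = load_dataset(path)
        assert loaded_spec == spec
        for name in ("train", "val", "test"):
            for field in ("true_aif", "sat_aif", "tissue", "pk", "bias"):
                np.testing.assert_array_equal(
                    getattr(loaded[name], field), getattr(splits[name], field)
                )


class TestPixelCurves:
    @pytest.fixture
    def aif(self, grid):
        return evaluate_aif(sample_aif_params(np.random.default_rng(8)), grid)

    def test_single_cluster_no_jitter_no_noise(self, aif):
        curves, labels = simulate_pixel_curves(
            np.random.default_rng(0), aif, n_pixels=20, n_clusters=1,
            jitter=0.0, noise_fraction=0.0,
        )
        np.testing.assert_allclose(curves, np.tile(curves[0], (20, 1)))
        assert set(labels) == {0}

    def test_seeded_determinism(self, aif):
        a, _ = simulate_pixel_curves(np.random.default_rng(3), aif, n_pixels=10)
        b, _ = simulate_pixel_curves(np.random.default_rng(3), aif, n_pixels=10)
        np.testing.assert_array_equal(a, b)

    def test_kmeans_recovers_separated_clusters(self, aif, grid):
        # two groups far apart in ktrans; oracle = direct group-wise mean
        from aifcorr.tissue_kinetics import PKParams, tissue_curve

        rng = np.random.default_rng(11)
        lo = tissue_curve(aif, PKParams(0.3, 1.5, 0.02, 0.02)).values
        hi = tissue_curve(aif, PKParams(2.1, 8.0, 0.02, 0.02)).values
        curves = np.concatenate([np.tile(lo, (30, 1)), np.tile(hi, (30, 1))])
        curves += rng.normal(0, 0.001, size=curves.shape)
        centers = cluster_tissue_curves(curves, 2, seed=0)
        oracle = np.stack([curves[30:].mean(axis=0), curves[:30].mean(axis=0)])
        np.testing.assert_allclose(centers, oracle, atol=0.001)

    def test_k_equal_one_gives_pointwise_mean(self, aif):
        curves, _ = simulate_pixel_curves(np.random.default_rng(0), aif, n_pixels=12)
        center = cluster_tissue_curves(curves, 1, seed=0)
        np.testing.assert_allclose(center[0], curves.mean(axis=0), rtol=1e-10)

    def test_identical_curves_any_k(self, aif):
        curve = np.tile(np.linspace(0, 1, 120), (8, 1))
        centers = cluster_tissue_curves(curve, 3, seed=0)
        for c in centers:
            np.testing.assert_allclose(c, curve[0], atol=1e-12)

    def test_k_exceeds_curves_rejected(self):
        with pytest.raises(ValueError):
            cluster_tissue_curves(np.zeros((3, 120)), 4)


class TestPreprocess:
    def test_identity_on_aligned_canonical_curve(self, grid):
        values = np.zeros(grid.n_points)
        values[10:40] = np.linspace(1.0, 5.0, 30)  # arrival exactly at index 10
        out = preprocess_curve(grid.values * 60.0, values)
        np.testing.assert_allclose(out.values, values, atol=1e-9)

    def test_shift_invariance(self, grid):
        values = np.zeros(grid.n_points)
        values[20:60] = np.hanning(40) * 4
        t = grid.values * 60.0
        a = preprocess_curve(t, values)
        b = preprocess_curve(t + 3.0, values)  # same curve, timestamps shifted 3 s
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_linear_ramp_interpolates_exactly(self):
        times = np.arange(0, 60.0, 1.0)
        ramp = times.copy()
        out = preprocess_curve(times, ramp, arrival_index=10)
        # linear interpolation of a linear function is exact within the span;
        # slope preserved on the interior
        interior = out.values[11:100]
        diffs = np.diff(interior)
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-9)

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            preprocess_curve(np.array([0.0, 1.0, 1.0]), np.zeros(3))
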