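import numpy as np
import pytest

from aifcorr.grid import TimeGrid, ConcentrationCurve
from aifcorr.data_factory import DatasetSpec, make_dataset
from aifcorr.correction_network import (
    NetworkConfig,
    LossConfig,
    build_model,
    lstm_parameter_count,
    compute_loss,
    train,
    correct_aif,
    _loss_and_grads,
    _tissue_model_term,
)


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self):
        cfg = NetworkConfig(input_channels=11, n_layers=4, hidden_size=32)
        model = build_model(cfg)
        H = 32
        trunk = lstm_parameter_count(4, H, 11)
        # hand computation: layer 0 sees 11 channels, layers 1-3 see 2H
        by_hand = 2 * (4 * H * (11 + H) + 4 * H) + 3 * 2 * (4 * H * (2 * H + H) + 4 * H)
        assert trunk == by_hand
        head = 2 * H * 1 + 1
        assert model.n_parameters() == trunk + head

    def test_param_head_size(self):
        cfg = NetworkConfig(input_channels=11)
        lcfg = LossConfig(kind="aif_plus_param", beta=1.0, n_tissue=10)
        model = build_model(cfg, lcfg)
        assert model.params["phead_W"].shape == (64, 40)

    def test_zero_weights_give_constant_output(self, rng):
        cfg = NetworkConfig(input_channels=3, n_layers=2, hidden_size=4)
        model = build_model(cfg)
        for k in model.params:
            model.params[k][:] = 0.0
        pred, _, _ = model.forward(rng.normal(size=(2, 20, 3)).astype(np.float32))
        np.testing.assert_array_equal(pred, np.zeros_like(pred))

    def test_seeded_initialisation_identical(self):
        cfg = NetworkConfig(input_channels=2, seed=5)
        a, b = build_model(cfg), build_model(cfg)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_channel_mismatch_rejected(self, rng):
        model = build_model(NetworkConfig(input_channels=3))
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(1, 20, 5)))


class TestGradients:
    def test_backprop_matches_numerical_gradients(self):
        # small float64 network; numerical differentiation as the oracle
        rng = np.random.default_rng(0)
        T, B, C, N = 10, 2, 3, 2
        cfg = NetworkConfig(input_channels=C, n_layers=2, hidden_size=4, seed=3)
        lcfg = LossConfig(kind="aif_plus_param", beta=0.5, n_tissue=N)
        model = build_model(cfg, lcfg, dtype=np.float64)
        x = rng.normal(size=(B, T, C))
        y = rng.normal(size=(B, T))
        true_p = rng.uniform(0.2, 1.0, size=(B, N, 4))

        def loss_value():
            pred, pp, _ = model.forward(x)
            return _loss_and_grads(lcfg, pred, y, pp, true_p)[0]

        pred, pp, cache = model.forward(x, want_cache=True)
        _, dpred, dpp = _loss_and_grads(lcfg, pred, y, pp, true_p)
        grads = model.backward(cache, dpred, dpp)

        eps = 1e-6
        for k, v in model.params.items():
            flat = v.ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_value()
                flat[i] = old - eps
                lm = loss_value()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[i]
                assert abs(num - ana) <= 1e-3 * max(1.0, abs(num)), (k, i, num, ana)

    def test_tissue_model_term_gradients(self):
        # isolated check with parameters inside the clamp ranges
        rng = np.random.default_rng(1)
        B, N, T = 2, 2, 15
        grid = TimeGrid(n_points=T)
        A = rng.uniform(0, 3, size=(B, T))
        P = np.stack(
            [
                np.stack(
                    [rng.uniform(0.3, 1.5, N), rng.uniform(1, 5, N),
                     rng.uniform(0.001, 0.05, N), rng.uniform(0, 0.05, N)],
                    axis=1,
                )
                for _ in range(B)
            ]
        )
        tis = rng.normal(size=(B, N, T)) * 0.2
        _, dA, dP = _tissue_model_term(A, P, tis, grid)
        eps = 1e-7
        for b in range(B):
            for i in range(0, T, 3):
                Ap, Am = A.copy(), A.copy()
                Ap[b, i] += eps
                Am[b, i] -= eps
                num = (_tissue_model_term(Ap, P, tis, grid)[0]
                       - _tissue_model_term(Am, P, tis, grid)[0]) / (2 * eps)
                assert num == pytest.approx(dA[b, i], rel=1e-4, abs=1e-9)
            for n in range(N):
                for j in (0, 1, 2):
                    Pp, Pm = P.copy(), P.copy()
                    Pp[b, n, j] += eps
                    Pm[b, n, j] -= eps
                    num = (_tissue_model_term(A, Pp, tis, grid)[0]
                           - _tissue_model_term(A, Pm, tis, grid)[0]) / (2 * eps)
                    assert num == pytest.approx(dP[b, n, j], rel=1e-4, abs=1e-9)


class TestComputeLoss:
    def test_zero_for_perfect_predictions(self, grid):
        rng = np.random.default_rng(2)
        pred = rng.uniform(0, 5, size=(2, grid.n_points))
        params = rng.uniform(0.1, 1.0, size=(2, 3, 4))
        tissue = rng.uniform(0, 1, size=(2, 3, grid.n_points))
        assert compute_loss(LossConfig(), pred, pred) == 0.0
        assert compute_loss(
            LossConfig(kind="aif_plus_param", beta=2.0, n_tissue=3),
            pred, pred, params.reshape(2, 12), params,
        ) == 0.0

    def test_constant_offset_gives_offset_l1(self, rng):
        pred = rng.uniform(0, 5, size=(3, 50))
        assert compute_loss(LossConfig(), pred + 0.37, pred) == pytest.approx(0.37)

    def test_tissue_term_self_consistent_with_generator(self, grid):
        # tissue curves generated with delays on the sample grid must be
        # reproduced exactly by the differentiable forward model
        from aifcorr.aif_population import sample_aif_params, evaluate_aif
        from aifcorr.tissue_kinetics import PKParams, tissue_curve

        aif = evaluate_aif(sample_aif_params(np.random.default_rng(4)), grid)
        pks = [PKParams(0.5, 2.5, 0.02, 2 * grid.dt), PKParams(1.2, 5.0, 0.01, 0.0)]
        tissue = np.stack([tissue_curve(aif, p).values for p in pks])[None]
        params = np.stack([p.to_array() for p in pks])[None]
        loss = compute_loss(
            LossConfig(kind="aif_plus_model_tissue", delta=1.0, n_tissue=2),
            aif.values[None], aif.values[None],
            params.reshape(1, 8), None, tissue, grid,
        )
        assert loss < 1e-6

    def test_invariant_to_tissue_ordering(self, grid):
        rng = np.random.default_rng(6)
        pred = rng.uniform(0, 5, size=(1, grid.n_points))
        true = rng.uniform(0, 5, size=(1, grid.n_points))
        params = rng.uniform(0.1, 1.0, size=(1, 4, 4))
        true_params = rng.uniform(0.1, 1.0, size=(1, 4, 4))
        tissue = rng.uniform(0, 1, size=(1, 4, grid.n_points))
        perm = [2, 0, 3, 1]
        for kind, kwargs in [
            ("aif_plus_param", dict(beta=1.0)),
            ("aif_plus_model_tissue", dict(delta=1.0)),
        ]:
            cfg = LossConfig(kind=kind, n_tissue=4, **kwargs)
            a = compute_loss(cfg, pred, true, params.reshape(1, 16), true_params, tissue, grid)
            b = compute_loss(
                cfg, pred, true, params[:, perm].reshape(1, 16),
                true_params[:, perm], tissue[:, perm], grid,
            )
            assert a == pytest.approx(b, rel=1e-12)

    def test_missing_param_head_rejected(self, rng):
        pred = rng.uniform(size=(1, 20))
        with pytest.raises(ValueError):
            compute_loss(LossConfig(kind="aif_plus_param", beta=1.0, n_tissue=2), pred, pred)


@pytest.fixture(scope="module")
def tiny_splits(dictionary):
    spec = DatasetSpec(n_train=48, n_val=16, n_test=16, n_tissue=2, seed=3)
    return make_dataset(spec, dictionary)


class TestTraining:
    def test_validation_loss_improves(self, dictionary):
        spec = DatasetSpec(n_train=200, n_val=40, n_test=10, n_tissue=2, seed=13)
        splits = make_dataset(spec, dictionary)
        cfg = NetworkConfig(input_channels=3, epochs=10, seed=1)
        tm = train(splits, cfg, LossConfig())
        assert tm.history[-1]["val_loss"] < tm.history[0]["val_loss"]
        assert tm.best_epoch == int(np.argmin([h["val_loss"] for h in tm.history]))

    def test_identical_seeds_identical_history(self, tiny_splits):
        cfg = NetworkConfig(input_channels=3, epochs=2, seed=9)
        a = train(tiny_splits, cfg, LossConfig())
        b = train(tiny_splits, cfg, LossConfig())
        assert a.history == b.history
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_aif_only_input_trains_with_one_channel(self, tiny_splits):
        cfg = NetworkConfig(input_channels=1, epochs=1, seed=2)
        tm = train(tiny_splits, cfg, LossConfig())
        assert tm.params["l0_f_Wx"].shape[0] == 1

    def test_save_load_round_trip(self, tiny_splits, tmp_path):
        cfg = NetworkConfig(input_channels=3, epochs=1, seed=4)
        tm = train(tiny_splits, cfg, LossConfig())
        tm.save(str(tmp_path / "model"))
        from aifcorr.correction_network import TrainedModel

        loaded = TrainedModel.load(str(tmp_path / "model"))
        assert loaded.net_cfg == tm.net_cfg
        x = np.random.default_rng(0).uniform(0, 5, size=(2, 120, 3)).astype(np.float32)
        np.testing.assert_array_equal(loaded.predict(x), tm.predict(x))


class TestCorrectAIF:
    def test_batch_invariance(self, tiny_splits, grid):
        cfg = NetworkConfig(input_channels=3, epochs=1, seed=6)
        tm = train(tiny_splits, cfg, LossConfig())
        ds = tiny_splits["test"]
        x = np.concatenate([ds.sat_aif[:, None], ds.tissue[:, :2]], axis=1).transpose(0, 2, 1)
        x = np.ascontiguousarray(x, dtype=np.float32)
        batch_pred = tm.predict(x)
        single = correct_aif(
            tm,
            ConcentrationCurve(grid, ds.sat_aif[3]),
            [ConcentrationCurve(grid, ds.tissue[3, j]) for j in range(2)],
        )
        np.testing.assert_allclose(single.values, batch_pred[3], atol=1e-6)

    def test_output_non_negative(self, tiny_splits, grid):
        cfg = NetworkConfig(input_channels=1, epochs=1, seed=6)
        tm = train(tiny_splits, cfg, LossConfig())
        ds = tiny_splits["test"]
        out = correct_aif(tm, ConcentrationCurve(grid, ds.sat_aif[0]))
        assert np.all(out.values >= 0)

    def test_channel_count_mismatch_rejected(self, tiny_splits, grid):
        cfg = NetworkConfig(input_channels=3, epochs=1, seed=6)
        tm = train(tiny_splits, cfg, LossConfig())
        with pytest.raises(ValueError):
            correct_aif(tm, ConcentrationCurve(grid, np.zeros(120)), [])
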