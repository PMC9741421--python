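import numpy as np
import pytest

from dotbench.mesh import circular_mask
from dotbench.nn import (
    Adam,
    LossWeights,
    NetworkConfig,
    Parameter,
    Tensor,
    TrainedModel,
    TrainingConfig,
    assemble_network,
    load_model,
    loss_Q,
    reconstruct_nn,
    save_model,
    train_network,
)
from dotbench.nn.layers import BatchNorm, Conv1d, Conv2d, Dense


def _numgrad(f, x, h=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += h
        fp = f()
        x[i] -= 2 * h
        fm = f()
        x[i] += h
        g[i] = (fp - fm) / (2 * h)
    return g


class TestAutogradOps:
    @pytest.mark.parametrize(
        "op",
        [
            lambda t: t.relu(),
            lambda t: t.leaky_relu(),
            lambda t: t.elu(),
            lambda t: t.sigmoid(),
            lambda t: t.softplus(),
            lambda t: (t * t).sum(axis=1),
            lambda t: t.mean(axis=0),
            lambda t: t.reshape(6),
            lambda t: t / 2.5 + 3.0,
        ],
    )
    def test_elementwise_gradients(self, op):
        rng = np.random.default_rng(0)
        x = Parameter(rng.standard_normal((2, 3)) + 0.1)
        out = op(x)
        (out * out).sum().backward()

        def loss():
            return float((op(Tensor(x.data)).data ** 2).sum())

        assert np.allclose(_numgrad(loss, x.data), x.grad, atol=1e-5)

    def test_matmul_gradient(self):
        rng = np.random.default_rng(1)
        a = Parameter(rng.standard_normal((3, 4)))
        b = Parameter(rng.standard_normal((4, 2)))
        ((a @ b) ** 2.0).sum().backward()

        def loss():
            return float(((a.data @ b.data) ** 2).sum())

        assert np.allclose(_numgrad(loss, a.data), a.grad, atol=1e-5)
        assert np.allclose(_numgrad(loss, b.data), b.grad, atol=1e-5)

    def test_shared_node_accumulates(self):
        x = Parameter(np.array([2.0]))
        y = x * 3.0 + x * 4.0
        y.sum().backward()
        assert x.grad[0] == pytest.approx(7.0)


class TestLayerGradients:
    @pytest.mark.parametrize("stride", [1, 3])
    def test_conv1d(self, stride):
        rng = np.random.default_rng(2)
        conv = Conv1d(2, 3, kernel=3, rng=rng, stride=stride)
        x = Parameter(rng.standard_normal((2, 2, 9)))
        (conv(x) ** 2.0).sum().backward()

        def loss():
            return float((conv(Tensor(x.data)).data ** 2).sum())

        assert np.allclose(_numgrad(loss, x.data), x.grad, atol=1e-5)
        assert np.allclose(_numgrad(loss, conv.W.data), conv.W.grad, atol=1e-5)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_conv2d(self, stride):
        rng = np.random.default_rng(3)
        conv = Conv2d(2, 3, kernel=3, rng=rng, stride=stride)
        x = Parameter(rng.standard_normal((2, 2, 6, 6)))
        (conv(x) ** 2.0).sum().backward()

        def loss():
            return float((conv(Tensor(x.data)).data ** 2).sum())

        assert np.allclose(_numgrad(loss, x.data), x.grad, atol=1e-5)
        assert np.allclose(_numgrad(loss, conv.W.data), conv.W.grad, atol=1e-5)
        assert np.allclose(_numgrad(loss, conv.b.data), conv.b.grad, atol=1e-5)

    def test_batchnorm_train_gradient(self):
        rng = np.random.default_rng(4)
        bn = BatchNorm(3)
        x = Parameter(rng.standard_normal((4, 3, 5)))
        (bn(x, train=True) ** 2.0).sum().backward()

        def loss():
            fresh = BatchNorm(3)
            fresh.gamma.data = bn.gamma.data
            fresh.beta.data = bn.beta.data
            return float((fresh(Tensor(x.data), train=True).data ** 2).sum())

        assert np.allclose(_numgrad(loss, x.data), x.grad, atol=1e-4)

    def test_dense_bias_gradient(self):
        rng = np.random.default_rng(5)
        d = Dense(3, 2, rng)
        x = Tensor(rng.standard_normal((4, 3)))
        (d(x) ** 2.0).sum().backward()

        def loss():
            return float((d(x).data ** 2).sum())

        assert np.allclose(_numgrad(loss, d.b.data), d.b.grad, atol=1e-5)


class TestArchitectureContracts:
    @pytest.mark.parametrize("n_sources", [8, 16])
    def test_shapes(self, n_sources):
        cfg = NetworkConfig.small(n_sources=n_sources, seed=0)
        net = assemble_network(cfg)
        B, nd = 3, n_sources - 1
        x = np.random.default_rng(0).standard_normal((B, 2, n_sources * nd))
        a = np.random.default_rng(1).random((B, 2))
        contrast, background = net(Tensor(x.astype(np.float32)),
                                   Tensor(a.astype(np.float32)), train=True)
        assert contrast.shape == (B, 2, 64, 64)
        assert background.shape == (B, 2)

    def test_blockB_pooled_units(self):
        cfg = NetworkConfig.small(seed=0)
        net = assemble_network(cfg)
        x = Tensor(np.zeros((2, 2, 240), np.float32))
        h = net.background_path.conv1(x).relu()
        h = net.background_path.conv2(h).relu()
        pooled = net.background_path.pool(h)
        assert pooled.shape == (2, 16)

    def test_blockA_feature_length(self):
        cfg = NetworkConfig.small(seed=0)
        net = assemble_network(cfg)
        # the dense stage after block A consumes exactly 16 x N_s features
        assert net.domain_transform.fc1.W.shape[0] == 16 * cfg.n_sources == 256

    def test_background_strictly_positive(self):
        net = assemble_network(NetworkConfig.small(seed=1))
        x = np.random.default_rng(2).standard_normal((4, 2, 240)).astype(np.float32)
        a = np.random.default_rng(3).random((4, 2)).astype(np.float32)
        _, bg = net(Tensor(x), Tensor(a), train=True)
        assert np.all(bg.data > 0)

    def test_contrast_masked_and_bounded(self):
        net = assemble_network(NetworkConfig.small(seed=1))
        x = np.random.default_rng(2).standard_normal((2, 2, 240)).astype(np.float32)
        a = np.random.default_rng(3).random((2, 2)).astype(np.float32)
        c, _ = net(Tensor(x), Tensor(a), train=True)
        mask = circular_mask(64)
        assert np.all(c.data[:, :, ~mask] == 0.0)
        assert c.data.min() >= 0.0 and c.data.max() <= 1.0

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_sources=16, n_detectors=14)


class TestLossQ:
    def _tensors(self, B=2, grid=64):
        mask = circular_mask(grid)
        c = np.random.default_rng(0).random((B, 2, grid, grid)) * mask
        bg = np.random.default_rng(1).random((B, 2))
        return Tensor(c), Tensor(bg), c.copy(), bg.copy(), mask

    def test_zero_iff_perfect(self):
        pc, pb, tc, tb, mask = self._tensors()
        assert float(loss_Q(pc, pb, tc, tb, mask).data) == pytest.approx(0.0, abs=1e-15)

    def test_background_weight_hand_value(self):
        # only mu_a0 off by 0.01 with w_a = 100^2 -> Q = 1.0
        pc, pb, tc, tb, mask = self._tensors()
        tb2 = tb.copy()
        tb2[:, 0] += 0.01
        q = loss_Q(pc, pb, tc, tb2, mask)
        assert float(q.data) == pytest.approx(1.0, rel=1e-12)

    def test_contrast_offset_hand_value(self):
        # both contrast images off by 0.1 on every masked pixel -> Q = 0.02
        pc, pb, tc, tb, mask = self._tensors()
        tc2 = tc + 0.1 * mask[None, None]
        q = loss_Q(pc, pb, tc2, tb, mask, LossWeights(1.0, 1.0, 1.0, 1.0))
        assert float(q.data) == pytest.approx(0.02, rel=1e-12)

    def test_shape_mismatch(self):
        pc, pb, tc, tb, mask = self._tensors()
        with pytest.raises(ValueError):
            loss_Q(pc, pb, tc, tb, np.ones((8, 8), bool))


def _toy_dataset(n=24, n_sources=8, grid=64, seed=0):
    """Random-but-learnable toy dataset for training-loop tests."""
    from dotbench.dataset import DatasetFile

    rng = np.random.default_rng(seed)
    nd = n_sources - 1
    inputs = rng.standard_normal((n, n_sources, nd, 2))
    aux = np.column_stack([rng.uniform(10, 100, n), rng.uniform(60, 150, n)])
    mask = circular_mask(grid)
    truth_c = rng.random((n, grid, grid, 2)) * 0.1 * mask[None, :, :, None]
    truth_b = np.column_stack([rng.uniform(0.005, 0.03, n), rng.uniform(0.5, 3, n)])
    split = np.zeros(n, dtype=np.int8)
    split[-max(2, n // 5) :] = 1
    return DatasetFile(inputs, aux, truth_c, truth_b, split)


class TestTraining:
    def test_loss_decreases_and_history(self):
        ds = _toy_dataset()
        cfg = NetworkConfig.small(n_sources=8, seed=0)
        net = assemble_network(cfg)
        tc = TrainingConfig(learning_rate=2e-3, epochs=6, batch_size=8, seed=0)
        trained = train_network(net, ds, tc)
        assert trained.epochs_run == 6
        assert len(trained.history["validation"]) == 6
        assert 1 <= trained.selected_epoch <= 6
        assert trained.history["train"][-1] < trained.history["train"][0]

    def test_determinism(self):
        ds = _toy_dataset()
        results = []
        for _ in range(2):
            net = assemble_network(NetworkConfig.small(n_sources=8, seed=3))
            tc = TrainingConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=3)
            results.append(train_network(net, ds, tc).history["train"])
        assert results[0] == results[1]

    def test_training_q_matches_module_loss(self):
        # the Q recorded by the training path equals module-level loss_Q
        ds = _toy_dataset()
        net = assemble_network(NetworkConfig.small(n_sources=8, seed=1))
        tc = TrainingConfig(learning_rate=0.0, epochs=1, batch_size=64, seed=1)
        trained = train_network(net, ds, tc)
        x, a = net.prepare_inputs(ds.inputs, ds.aux)
        tr = ds.train_indices
        from dotbench.nn.autograd import no_grad

        with no_grad():
            pc, pb = net(Tensor(x[tr]), Tensor(a[tr]), train=True)
            q = loss_Q(
                pc, pb,
                ds.truth_contrast[tr].transpose(0, 3, 1, 2),
                ds.truth_background[tr],
                circular_mask(64),
            )
        # lr = 0: weights unchanged, so epoch-1 training Q must match
        # (batch norm uses batch statistics in both paths; single batch)
        assert trained.history["train"][0] == pytest.approx(
            float(q.data), rel=1e-5
        )

    def test_requires_split(self):
        ds = _toy_dataset()
        ds.split[:] = 0
        net = assemble_network(NetworkConfig.small(n_sources=8, seed=0))
        with pytest.raises(ValueError):
            train_network(net, ds, TrainingConfig(epochs=1, seed=0))


@pytest.fixture(scope="module")
def overfit_model():
    """Overfit the network to a single homogeneous-phantom sample."""
    from dotbench.dataset import DatasetFile, generate_dataset
    from dotbench.mesh import ParameterRanges

    ranges = ParameterRanges(
        diameter_mm=(100.0, 100.0), frequency_MHz=(100.0, 100.0)
    )
    ds = generate_dataset(
        1, ranges=ranges, partition=(1.0, 0.0, 0.0), seed=7, n_rings=8
    )
    # duplicate the sample so train and validation both exist
    ds2 = DatasetFile(
        np.repeat(ds.inputs, 4, axis=0),
        np.repeat(ds.aux, 4, axis=0),
        np.repeat(ds.truth_contrast, 4, axis=0),
        np.repeat(ds.truth_background, 4, axis=0),
        np.array([0, 0, 0, 1], dtype=np.int8),
        phantoms=list(ds.phantoms) * 4,
    )
    net = assemble_network(NetworkConfig.small(seed=7))
    tc = TrainingConfig(learning_rate=1e-2, epochs=250, batch_size=4, seed=7)
    trained = train_network(net, ds2, tc)
    return trained, ds2


class TestReconstructNn:

    def test_mask_and_positivity(self, overfit_model):
        trained, ds = overfit_model
        img = reconstruct_nn(trained, ds.inputs[0], aux=tuple(ds.aux[0]))
        mask = circular_mask(64)
        assert np.all(img.mu_a_grid[~mask] == 0.0)
        assert np.all(img.mu_a_grid[mask] > 0.0)
        assert np.all(img.mu_s_grid[mask] > 0.0)

    def test_single_sample_recovery(self, overfit_model):
        trained, ds = overfit_model
        img = reconstruct_nn(trained, ds.inputs[0], aux=tuple(ds.aux[0]))
        mask = circular_mask(64)
        mu_a0, mu_s0 = ds.truth_background[0]
        assert np.all(np.abs(img.mu_a_grid[mask] / mu_a0 - 1.0) < 0.2)
        assert np.all(np.abs(img.mu_s_grid[mask] / mu_s0 - 1.0) < 0.2)

    def test_shape_mismatch(self, overfit_model):
        trained, _ = overfit_model
        with pytest.raises(ValueError):
            reconstruct_nn(trained, np.zeros((8, 7, 2)), aux=(100.0, 100.0))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        ds = _toy_dataset()
        net = assemble_network(NetworkConfig.small(n_sources=8, seed=2))
        tc = TrainingConfig(learning_rate=1e-3, epochs=2, batch_size=8, seed=2)
        trained = train_network(net, ds, tc)
        wpath, cpath = tmp_path / "m.npz", tmp_path / "m.json"
        save_model(trained, str(wpath), str(cpath))
        back = load_model(str(wpath), str(cpath))
        assert back.selected_epoch == trained.selected_epoch
        x, a = net.prepare_inputs(ds.inputs[:2], ds.aux[:2])
        from dotbench.nn.autograd import no_grad

        with no_grad():
            c1, b1 = trained.model(Tensor(x), Tensor(a), train=False)
            c2, b2 = back.model(Tensor(x), Tensor(a), train=False)
        assert np.allclose(c1.data, c2.data)
        assert np.allclose(b1.data, b2.data)


class TestAdam:
    def test_minimizes_quadratic(self):
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            ((p * p).sum()).backward()
            opt.step()
        assert np.allclose(p.data, 0.0, atol=1e-2)
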