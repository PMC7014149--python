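"""CNN-LSTM: shape contract, gradients, training, ensembling."""

import numpy as np
import pytest

from squatform import convlstm, simulate, segment
from squatform.core import FORM_ORDER, SensorPlacement, SquatForm


class TestBuildNetwork:
    @pytest.mark.parametrize("rows", [6, 12, 30])
    def test_shape_contract(self, rows):
        # any stacked input (1, 2, 5 placements) builds, and the LSTM
        # sees exactly 5 time steps after three 1x2 poolings of 40
        net = convlstm.build_network(
            convlstm.NetworkSpec(input_rows=rows), rng_seed=0
        )
        x = np.random.default_rng(0).normal(size=(3, rows, 40))
        probs, cache = net.forward(x.astype(np.float32))
        assert probs.shape == (3, 6)
        C, R, S = cache[2]
        assert (C, R, S) == (32, rows, 5)

    def test_softmax_normalized(self):
        net = convlstm.build_network(convlstm.NetworkSpec(), 1)
        x = np.random.default_rng(1).normal(size=(8, 6, 40))
        probs, _ = net.forward(x.astype(np.float32))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_identical_seed_identical_parameters(self):
        a = convlstm.build_network(convlstm.NetworkSpec(), 7)
        b = convlstm.build_network(convlstm.NetworkSpec(), 7)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_indivisible_time_axis_errors(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            convlstm.build_network(convlstm.NetworkSpec(input_cols=42), 0)

    def test_channels_must_double(self):
        with pytest.raises(ValueError, match="double"):
            convlstm.NetworkSpec(conv_channels=(8, 12, 32))


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        # every parameter tensor checked at a random coordinate against
        # a central finite difference, in float64
        spec = convlstm.NetworkSpec(
            input_rows=6, input_cols=8, lstm_cells=5,
            dense_width=7, dropout_rate=0.0,
        )
        net = convlstm.build_network(spec, 3)
        net.params = {k: v.astype(np.float64) for k, v in net.params.items()}
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 6, 8))
        y = np.array([0, 1, 2, 3])
        _, grads = net.loss_and_grads(x, y, train=False)
        for k, v in net.params.items():
            idx = tuple(rng.integers(0, s) for s in v.shape)
            eps = 1e-6
            v[idx] += eps
            lp, _ = net.loss_and_grads(x, y, train=False)
            v[idx] -= 2 * eps
            lm, _ = net.loss_and_grads(x, y, train=False)
            v[idx] += eps
            num = (lp - lm) / (2 * eps)
            denom = max(1e-8, abs(num) + abs(grads[k][idx]))
            assert abs(num - grads[k][idx]) / denom < 1e-5, k


def _tiny_separable_set(n_per_class=10, seed=0):
    """Six well-separated synthetic classes of 6x40 matrices."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    t = np.linspace(0, 2 * np.pi, 40)
    for c in range(6):
        for _ in range(n_per_class):
            base = np.sin(t * (c % 3 + 1)) * (1 + c)
            mat = np.tile(base, (6, 1)) + rng.normal(0, 0.05, (6, 40))
            X.append(mat)
            y.append(c)
    return np.array(X, dtype=np.float32), np.array(y)


class TestTrainNetwork:
    def test_overfits_tiny_separable_set(self):
        X, y = _tiny_separable_set()
        spec = convlstm.NetworkSpec(dropout_rate=0.0)
        net = convlstm.build_network(spec, 0)
        net = convlstm.train_network(
            net, X, y, convlstm.TrainConfig(epochs=60, batch_size=16, rng_seed=0)
        )
        acc = np.mean(np.argmax(net.predict_proba(X), axis=1) == y)
        assert acc >= 0.95

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_first_epochs_decrease_loss(self, seed):
        X, y = _tiny_separable_set(seed=seed)
        net = convlstm.build_network(convlstm.NetworkSpec(), seed)
        _, hist = convlstm.train_network(
            net, X, y,
            convlstm.TrainConfig(epochs=5, batch_size=16, rng_seed=seed),
            record_history=True,
        )
        assert hist[-1] < hist[0]

    def test_training_deterministic(self):
        X, y = _tiny_separable_set(seed=4)
        losses = []
        for _ in range(2):
            net = convlstm.build_network(convlstm.NetworkSpec(), 5)
            _, hist = convlstm.train_network(
                net, X, y,
                convlstm.TrainConfig(epochs=3, batch_size=16, rng_seed=5),
                record_history=True,
            )
            losses.append(hist[-1])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_dimension_mismatch_errors(self):
        net = convlstm.build_network(convlstm.NetworkSpec(), 0)
        with pytest.raises(ValueError, match="does not match spec"):
            convlstm.train_network(
                net, np.zeros((4, 5, 40)), [0, 1, 2, 3]
            )

    def test_single_class_errors(self):
        net = convlstm.build_network(convlstm.NetworkSpec(), 0)
        with pytest.raises(ValueError, match="2 classes"):
            convlstm.train_network(net, np.zeros((4, 6, 40)), [2, 2, 2, 2])


class TestEnsemble:
    def test_exactly_three_members_with_distinct_weights(self):
        X, y = _tiny_separable_set(n_per_class=4)
        ens = convlstm.train_ensemble(
            convlstm.NetworkSpec(), X, y,
            convlstm.TrainConfig(epochs=1, batch_size=16, rng_seed=3),
        )
        assert len(ens.members) == 3
        w = [m.params["denseW2"] for m in ens.members]
        assert not np.allclose(w[0], w[1]) and not np.allclose(w[1], w[2])

    def test_wrong_member_count_rejected(self):
        net = convlstm.build_network(convlstm.NetworkSpec(), 0)
        with pytest.raises(ValueError, match="exactly 3"):
            convlstm.EnsembleModel(members=[net, net])

    def test_identical_members_equal_single_output(self):
        net = convlstm.build_network(convlstm.NetworkSpec(), 2)
        net.norm_mean = np.zeros(6, dtype=np.float32)
        net.norm_std = np.ones(6, dtype=np.float32)
        ens = convlstm.EnsembleModel(members=[net, net, net])
        x = np.random.default_rng(0).normal(size=(5, 6, 40))
        np.testing.assert_allclose(
            convlstm.predict_ensemble(ens, x), net.predict_proba(x), atol=1e-7
        )

    def test_mean_of_one_hot_members(self):
        # arithmetic-mean ensembling of (1,0,..), (0,1,0,..), (0,0,1,..)
        class _Fixed:
            def __init__(self, k):
                self.k = k

            def predict_proba(self, x):
                out = np.zeros((len(x), 6))
                out[:, self.k] = 1.0
                return out

        ens = convlstm.EnsembleModel.__new__(convlstm.EnsembleModel)
        ens.members = [_Fixed(0), _Fixed(1), _Fixed(2)]
        got = convlstm.predict_ensemble(ens, np.zeros((2, 6, 40)))
        np.testing.assert_allclose(got[0], [1 / 3, 1 / 3, 1 / 3, 0, 0, 0])

    def test_ensemble_output_is_convex_combination(self):
        X, y = _tiny_separable_set(n_per_class=4)
        ens = convlstm.train_ensemble(
            convlstm.NetworkSpec(), X, y,
            convlstm.TrainConfig(epochs=1, batch_size=16, rng_seed=1),
        )
        probs = convlstm.predict_ensemble(ens, X[:5])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_joint_member_math_matches_single_network():
    """The vectorized 3-member pass reproduces each member's own
    forward pass, loss, and gradients exactly (no dropout)."""
    spec = convlstm.NetworkSpec(dropout_rate=0.0)
    members = [convlstm.build_network(spec, k) for k in range(3)]
    params = {
        k: np.stack([m.params[k] for m in members]) for k in members[0].params
    }
    rng = np.random.default_rng(0)
    xb = rng.normal(size=(3, 5, 6, 40)).astype(np.float32)
    y = rng.integers(0, 6, (3, 5))
    losses, grads = convlstm._joint_loss_and_grads(
        params, spec, xb, y, rng=None, train=False
    )
    for k, m in enumerate(members):
        loss_k, grads_k = m.loss_and_grads(xb[k], y[k], train=False)
        assert abs(loss_k - losses[k]) < 1e-6
        for name in grads_k:
            np.testing.assert_allclose(
                grads[name][k], grads_k[name], rtol=2e-4, atol=1e-6
            )


def test_stack_dataset_orders_and_labels(small_multisensor_dataset):
    _, reps = small_multisensor_dataset
    X, y = convlstm.stack_dataset(
        reps, [SensorPlacement.RIGHT_THIGH, SensorPlacement.LUMBAR]
    )
    assert X.shape[1:] == (12, 40)
    assert set(y) <= set(range(6))
    # lumbar rows first (fixed site order)
    lum = reps[0].matrices[SensorPlacement.LUMBAR]
    np.testing.assert_allclose(X[0, :6], lum, rtol=1e-5)
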