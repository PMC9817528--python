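import numpy as np
import pytest

import equigait as eg
from equigait import _nn
from equigait.models import (
    ConfigError,
    ShapeError,
    predict_proba,
    segments_to_arrays,
    small_config,
)


def separable_data(rng, n=64, T=30, ni=6):
    """Linearly separable classes: distinct constant levels on channel 0."""
    y = rng.integers(0, 5, n)
    X = rng.normal(0, 0.05, (n, ni, T))
    for i in range(n):
        X[i, 0] += y[i] - 2.0
    return X.astype(np.float32), y


class TestBuildModel:
    def test_unsupported_arch_rejected(self):
        with pytest.raises(ConfigError):
            eg.ModelConfig(arch="transformer")

    def test_cnn_layer_shapes(self):
        m = eg.build_model(eg.ModelConfig(arch="cnn1d", ni=6))
        chans = [(c.params["W"].shape[1], c.params["W"].shape[0]) for c in m.convs]
        assert chans == [(6, 16), (16, 32), (32, 64), (64, 128)]
        assert [c.d for c in m.convs] == [12, 8, 4, 1]

    def test_lstm_is_single_layer_feeding_head(self):
        m = eg.build_model(eg.ModelConfig(arch="lstm", ni=6, units=200))
        assert m.rnn.params["Wh"].shape == (200, 800)
        assert m.head1.params["W"].shape == (200, 128)
        assert m.head2.params["W"].shape == (128, 5)

    def test_bilstm_splits_units_over_directions(self):
        m = eg.build_model(eg.ModelConfig(arch="bilstm", ni=6, units=400))
        assert m.rnn_f.params["Wh"].shape == (200, 800)
        assert m.rnn_b.params["Wh"].shape == (200, 800)
        assert m.head1.params["W"].shape == (400, 128)

    @pytest.mark.parametrize("arch", ["lstm", "bilstm", "gru", "cnn1d"])
    def test_probability_head_contract(self, arch):
        m = eg.build_model(small_config(arch), seed=1)
        X = np.random.default_rng(0).normal(size=(4, 6, 25)).astype(np.float32)
        p = predict_proba(m, X)
        assert p.shape == (4, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_channel_mismatch_rejected(self):
        m = eg.build_model(small_config("gru", ni=6))
        with pytest.raises(ShapeError):
            m.forward(np.zeros((2, 3, 10), dtype=np.float32))


class TestGradients:
    """Finite-difference checks of the hand-derived backward passes."""

    @pytest.mark.parametrize(
        "make",
        [
            lambda rng: _nn.LSTMCellSeq(rng, 3, 4),
            lambda rng: _nn.GRUCellSeq(rng, 3, 4),
            lambda rng: _nn.DilatedConv1d(rng, 3, 4, dilation=2),
        ],
        ids=["lstm", "gru", "conv1d"],
    )
    def test_numeric_gradient(self, make):
        rng = np.random.default_rng(0)
        layer = make(rng)
        recurrent = not isinstance(layer, _nn.DilatedConv1d)
        x = rng.normal(size=(2, 5, 3) if recurrent else (2, 3, 5)).astype(
            np.float32
        )
        head = _nn.Dense(rng, 4, 2)
        y = np.array([0, 1])

        def loss_value():
            out = layer.forward(x)
            feat = out[:, -1] if recurrent else out.mean(axis=2)
            l, _ = _nn.cross_entropy(head.forward(feat), y)
            return l

        layer.zero_grad()
        head.zero_grad()
        out = layer.forward(x)
        feat = out[:, -1] if recurrent else out.mean(axis=2)
        _, dlogits = _nn.cross_entropy(head.forward(feat), y)
        dfeat = head.backward(dlogits)
        if recurrent:
            dout = np.zeros_like(out)
            dout[:, -1] = dfeat
        else:
            dout = np.repeat(
                (dfeat / out.shape[2])[:, :, None], out.shape[2], axis=2
            ).astype(np.float32)
        layer.backward(dout)

        eps = 1e-3
        for name, P in layer.params.items():
            flat = P.reshape(-1)
            for i in rng.choice(flat.size, size=4, replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_value()
                flat[i] = old - eps
                lm = loss_value()
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = layer.grads[name].reshape(-1)[i]
                assert numeric == pytest.approx(analytic, rel=0.02, abs=1e-4)


class TestTrainModel:
    @pytest.mark.parametrize("arch", ["lstm", "bilstm", "gru", "cnn1d"])
    def test_overfits_separable_data(self, arch):
        rng = np.random.default_rng(1)
        X, y = separable_data(rng)
        m = eg.build_model(small_config(arch), seed=0)
        m, hist = eg.train_model(
            m, (X, y), (X, y), eg.TrainConfig(epochs=20, batch_size=8, seed=0)
        )
        acc = (predict_proba(m, X).argmax(axis=1) == y).mean()
        assert acc == 1.0
        assert len(hist) <= 20

    def test_loss_decreases_early(self):
        rng = np.random.default_rng(2)
        X, y = separable_data(rng, n=128)
        m = eg.build_model(small_config("cnn1d"), seed=0)
        _, hist = eg.train_model(m, (X, y), (X, y), eg.TrainConfig(epochs=5, seed=0))
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_identical_seeds_identical_weights(self):
        rng = np.random.default_rng(3)
        X, y = separable_data(rng, n=48, T=20)
        weights = []
        for _ in range(2):
            m = eg.build_model(small_config("lstm"), seed=9)
            m, _ = eg.train_model(m, (X, y), (X, y), eg.TrainConfig(epochs=2, seed=9))
            weights.append(m.get_weights())
        for a, b in zip(*weights):
            assert np.array_equal(a, b)

    def test_empty_val_rejected(self):
        X = np.zeros((4, 6, 10), dtype=np.float32)
        y = np.zeros(4, dtype=np.int64)
        m = eg.build_model(small_config("gru"))
        with pytest.raises(ConfigError):
            eg.train_model(m, (X, y), (X[:0], y[:0]), eg.TrainConfig(epochs=1))

    def test_best_checkpoint_restored(self):
        rng = np.random.default_rng(4)
        X, y = separable_data(rng, n=48, T=20)
        m = eg.build_model(small_config("gru"), seed=0)
        m, hist = eg.train_model(m, (X, y), (X, y), eg.TrainConfig(epochs=8, seed=0))
        logits = m.forward(X.astype(np.float32))
        loss, _ = _nn.cross_entropy(logits, y)
        assert loss == pytest.approx(min(h["val_loss"] for h in hist), abs=1e-5)


class TestPredict:
    def test_order_preserved(self, quiet_ride):
        segs = eg.segments_from_ride(
            quiet_ride.device_trace,
            quiet_ride.gps,
            quiet_ride.label_events,
            frame="horse",
        )
        m = eg.build_model(small_config("cnn1d"), seed=0)
        X, _ = segments_to_arrays(segs)
        p_all = predict_proba(m, X)
        p_one = predict_proba(m, X[3:4])
        assert np.allclose(p_all[3], p_one[0], atol=1e-6)

    def test_trained_model_recovers_single_gait_ride(self):
        """A model trained on a two-gait corpus labels a pure-walk ride
        as walk nearly everywhere."""
        plan = eg.RidePlan(
            bouts=[eg.Bout(eg.Gait.WALK, 15.0), eg.Bout(eg.Gait.TOLT, 15.0)],
            seed=0,
        )
        b = eg.simulate_ride(plan)
        segs = eg.segments_from_ride(
            b.device_trace, b.gps, b.label_events, frame="horse"
        )
        m = eg.build_model(small_config("cnn1d"), seed=0)
        m, _ = eg.train_model(
            m, segs, segs, eg.TrainConfig(epochs=10, batch_size=16, seed=0)
        )
        walk_plan = eg.RidePlan(bouts=[eg.Bout(eg.Gait.WALK, 12.0)], seed=5)
        wb = eg.simulate_ride(walk_plan)
        wsegs = eg.segments_from_ride(
            wb.device_trace, wb.gps, wb.label_events, frame="horse"
        )
        pred = predict_proba(m, wsegs).argmax(axis=1)
        assert (pred == int(eg.Gait.WALK)).mean() > 0.9

    def test_save_load_round_trip(self, tmp_path):
        m = eg.build_model(small_config("bilstm"), seed=2)
        X = np.random.default_rng(0).normal(size=(3, 6, 20)).astype(np.float32)
        p1 = predict_proba(m, X)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = eg.SequenceClassifier.load(path)
        assert np.allclose(p1, predict_proba(m2, X), atol=1e-7)
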