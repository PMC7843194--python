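import numpy as np
import pytest

from sdaeconn import (DenoisingAutoencoder, SDAEResults,
                      StackedDenoisingAutoencoder, TrainConfig, corrupt,
                      sigmoid, stack_train, train_autoencoder)
from sdaeconn.sdae import _init_autoencoder


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("a", [-3.0, -1.0, 0.0, 1.0, 3.0])
    def test_symmetry(self, a):
        assert sigmoid(a) + sigmoid(-a) == pytest.approx(1.0)

    def test_matches_closed_form(self):
        assert sigmoid(2.0) == pytest.approx(1.0 / (1.0 + np.exp(-2.0)),
                                             abs=1e-15)

    def test_range_and_monotonicity(self):
        a = np.linspace(-30, 30, 101)
        s = sigmoid(a)
        assert np.all((s > 0) & (s < 1))
        assert np.all(np.diff(s) > 0)

    def test_saturates_without_overflow(self):
        assert sigmoid(1000.0) == pytest.approx(1.0)
        assert sigmoid(-1000.0) == pytest.approx(0.0)


class TestCorrupt:
    def test_fraction_zero_is_identity(self):
        x = np.random.default_rng(0).random((5, 7))
        np.testing.assert_array_equal(corrupt(x, 0.0, 1), x)

    def test_fraction_one_zeroes_everything(self):
        x = np.ones((5, 7))
        assert np.all(corrupt(x, 1.0, 1) == 0.0)

    def test_masking_rate_binomial_bound(self):
        x = np.ones((100, 100))
        zeroed = np.mean(corrupt(x, 0.5, 123) == 0.0)
        # 3 binomial standard deviations around 0.5 at n=10000
        assert abs(zeroed - 0.5) < 3 * 0.5 / 100

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(1).random((20, 30))
        np.testing.assert_array_equal(corrupt(x, 0.4, 7), corrupt(x, 0.4, 7))


class TestEncodeDecode:
    def test_zero_weights_give_half(self):
        ae = DenoisingAutoencoder(np.zeros((3, 4)), np.zeros(3),
                                  np.zeros((4, 3)), np.zeros(4))
        assert np.all(ae.encode(np.ones((4, 5))) == 0.5)
        assert np.all(ae.decode(np.zeros((3, 2))) == 0.5)

    def test_decode_zero_hidden_gives_sigmoid_bias(self):
        rng = np.random.default_rng(2)
        b_dec = rng.standard_normal(4)
        ae = DenoisingAutoencoder(rng.standard_normal((3, 4)), np.zeros(3),
                                  rng.standard_normal((4, 3)), b_dec)
        np.testing.assert_allclose(ae.decode(np.zeros((3, 1)))[:, 0],
                                   sigmoid(b_dec))

    def test_matches_matrix_product_oracle(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((3, 2))
        b = rng.standard_normal(3)
        ae = DenoisingAutoencoder(W, b, rng.standard_normal((2, 3)),
                                  rng.standard_normal(2))
        x = rng.standard_normal((2, 6))
        expect = 1.0 / (1.0 + np.exp(-(W @ x + b[:, None])))
        np.testing.assert_allclose(ae.encode(x), expect, atol=1e-14)

    def test_dimension_mismatch_rejected(self):
        ae = DenoisingAutoencoder(np.zeros((3, 4)), np.zeros(3),
                                  np.zeros((4, 3)), np.zeros(4))
        with pytest.raises(ValueError):
            ae.encode(np.ones((5, 2)))

    def test_transposed_shape_invariant_enforced(self):
        with pytest.raises(ValueError):
            DenoisingAutoencoder(np.zeros((3, 4)), np.zeros(3),
                                 np.zeros((3, 4)), np.zeros(4))


class TestTraining:
    def test_learning_rate_zero_is_noop(self):
        rng = np.random.default_rng(4)
        x = rng.random((5, 300))
        cfg = TrainConfig(learning_rate=0.0, seed=9)
        ae, loss = train_autoencoder(x, 3, cfg)
        init = _init_autoencoder(5, 3, np.random.default_rng(9))
        np.testing.assert_array_equal(ae.W, init.W)
        assert loss == pytest.approx(init.reconstruction_error(x))

    def test_constant_input_converges(self):
        x = np.full((4, 2000), 0.5)
        cfg = TrainConfig(corruption_fraction=0.0, learning_rate=1.0,
                          minibatch=200, epochs=60, seed=0)
        _, loss = train_autoencoder(x, 2, cfg)
        # loss is summed over 4 channels; bias alone can realize 0.5
        assert loss < 1e-3

    def test_reference_config_runs_on_multichannel_data(self):
        """Reference hyperparameters (0.5/1/200/8) train end to end."""
        rng = np.random.default_rng(5)
        x = rng.random((12, 1200))
        cfg = TrainConfig(corruption_fraction=0.5, learning_rate=1.0,
                          minibatch=200, epochs=8, seed=1)
        ae, loss = train_autoencoder(x, 8, cfg)
        assert np.isfinite(loss)
        assert ae.n_hidden == 8

    def test_bit_identical_across_reruns(self):
        rng = np.random.default_rng(6)
        x = rng.random((6, 500))
        cfg = TrainConfig(seed=77, epochs=4)
        a1, _ = train_autoencoder(x, 3, cfg)
        a2, _ = train_autoencoder(x, 3, cfg)
        for f in ("W", "b", "W_dec", "b_dec"):
            np.testing.assert_array_equal(getattr(a1, f), getattr(a2, f))

    def test_oversized_hidden_warns(self):
        x = np.random.default_rng(7).random((3, 100))
        with pytest.warns(UserWarning):
            train_autoencoder(x, 5, TrainConfig(epochs=1))


class TestStack:
    def test_stage_dimensions(self, chain_recording):
        rec, _ = chain_recording
        model = stack_train(rec.area_data(1), 8, 3, TrainConfig(seed=0))
        assert (model.stage1.n_hidden, model.stage2.n_hidden) == (8, 3)
        assert model.stage2.n_input == 8

    def test_degenerate_one_one(self):
        rng = np.random.default_rng(8)
        model = stack_train(rng.standard_normal((2, 400)), 1, 1,
                            TrainConfig(seed=0, epochs=2))
        assert model.stage1.n_hidden == 1 and model.stage2.n_hidden == 1

    def test_m_greater_than_n_rejected(self):
        with pytest.raises(ValueError):
            StackedDenoisingAutoencoder(2, 5)

    def test_training_reduces_stage1_loss(self, chain_recording):
        """Trained reconstruction beats the random initialization."""
        rec, _ = chain_recording
        x = rec.area_data(1)
        for seed in range(5):
            cfg = TrainConfig(seed=seed, epochs=8)
            model = stack_train(x, 8, 3, cfg)
            xs = model.scale(x)
            untrained = _init_autoencoder(
                x.shape[0], 8, np.random.default_rng(seed))
            assert model.recon_err_1 < untrained.reconstruction_error(xs)

    def test_hidden_activations_in_unit_interval(self, chain_recording):
        rec, _ = chain_recording
        x = rec.area_data(2)
        model = stack_train(x, 6, 2, TrainConfig(seed=3, epochs=2))
        y2 = model.transform(x)
        z = model.reconstruct(x)
        assert np.all((y2 > 0) & (y2 < 1))
        assert np.all((z > 0) & (z < 1))

    def test_fit_deterministic(self, chain_recording):
        rec, _ = chain_recording
        x = rec.area_data(1)
        m1 = stack_train(x, 5, 2, TrainConfig(seed=5, epochs=2))
        m2 = stack_train(x, 5, 2, TrainConfig(seed=5, epochs=2))
        np.testing.assert_array_equal(m1.stage2.W, m2.stage2.W)


class TestFeatureExtraction:
    def test_m_equal_one_returns_single_unit(self, chain_recording):
        rec, _ = chain_recording
        x = rec.area_data(1)
        model = stack_train(x, 4, 1, TrainConfig(seed=2, epochs=2))
        np.testing.assert_allclose(model.extract_feature(x),
                                   model.transform(x)[0])

    def test_average_of_hidden_series(self, chain_recording):
        rec, _ = chain_recording
        x = rec.area_data(1)
        model = stack_train(x, 6, 3, TrainConfig(seed=2, epochs=2))
        np.testing.assert_allclose(model.extract_feature(x),
                                   model.transform(x).mean(axis=0),
                                   atol=1e-15)

    def test_feature_length_matches_input(self, chain_recording):
        rec, _ = chain_recording
        x = rec.area_data(3)
        model = stack_train(x, 5, 2, TrainConfig(seed=1, epochs=1))
        assert model.extract_feature(x).shape == (x.shape[1],)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, chain_recording):
        rec, _ = chain_recording
        x = rec.area_data(1)
        model = stack_train(x, 5, 2, TrainConfig(seed=4, epochs=2))
        back = SDAEResults.load(model.save(tmp_path / "model.npz"))
        np.testing.assert_array_equal(back.stage1.W, model.stage1.W)
        np.testing.assert_allclose(back.extract_feature(x),
                                   model.extract_feature(x))
        assert back.config == model.config
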