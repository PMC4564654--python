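import numpy as np
import pytest

import tonalnet as tn
from tonalnet.network import (
    DivergenceError,
    checkpoint_epochs,
    forward,
    forward_indices,
    init_network,
    load_checkpoint,
    loss_and_gradients,
    save_checkpoint,
    _pack_corpus,
    _sgd_epochs,
)


class TestActivation:
    def test_odd_symmetry_and_known_value(self, rng):
        assert tn.activation(0.0) == 0.0
        assert tn.activation(1.0) == pytest.approx(0.7615941559557649, abs=1e-15)
        x = rng.normal(size=100) * 5
        np.testing.assert_allclose(tn.activation(-x), -tn.activation(x))

    def test_matches_exponential_form_and_is_stable(self):
        x = np.linspace(-5, 5, 101)
        literal = (np.exp(x) - np.exp(-x)) / (np.exp(x) + np.exp(-x))
        np.testing.assert_allclose(tn.activation(x), literal, rtol=1e-15)
        assert tn.activation(1e4) == 1.0  # no overflow
        assert np.all(np.abs(tn.activation(x)) < 1)


class TestBinarize:
    def test_positive_maps_to_one_others_to_zero(self):
        out = tn.binarize(np.array([0.3, -0.2, 0.0, 1e-9]))
        np.testing.assert_array_equal(out, [1, 0, 0, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tn.binarize(np.array([1.0, 0.0]))


class TestInit:
    def test_seeded_reproducibility_and_difference(self):
        a = init_network(5)
        b = init_network(5)
        c = init_network(6)
        np.testing.assert_array_equal(a.w1, b.w1)
        assert not np.array_equal(a.w1, c.w1)
        assert a.layer_sizes == (2232, 45, 30, 24)

    def test_init_scale_bounds_parameters(self):
        s = init_network(1, init_scale=0.05)
        for arr in (s.w1, s.b1, s.w2, s.b2, s.w3, s.b3):
            assert np.all(np.abs(arr) <= 0.05)


class TestForward:
    def test_zero_parameters_give_zero_outputs(self):
        s = init_network(0, layer_sizes=(20, 6, 5, 24))
        for arr in (s.w1, s.b1, s.w2, s.b2, s.w3, s.b3):
            arr[...] = 0.0
        out = forward(s, np.ones(20))
        np.testing.assert_array_equal(out, np.zeros(24))

    def test_outputs_bounded_and_shape_checked(self, mini_state, rng):
        out = forward(mini_state, rng.random(20))
        assert out.shape == (24,)
        assert np.all(np.abs(out) < 1)
        with pytest.raises(ValueError):
            forward(mini_state, rng.random(21))

    def test_sparse_and_dense_paths_agree(self, rng):
        s = init_network(2)
        chromas = rng.integers(0, 12, size=40)
        from tonalnet.encoding import active_indices, encode_melody

        dense = forward(s, encode_melody(chromas))
        sparse = forward_indices(s, active_indices(chromas))
        np.testing.assert_allclose(dense, sparse, atol=1e-12)


class TestGradients:
    def test_backprop_matches_central_finite_differences(self, rng):
        """Analytic gradients for all three layers, biases and the input match
        a central finite-difference oracle on a 20-input miniature."""
        state = init_network(9, layer_sizes=(20, 6, 5, 24))
        x = (rng.random(20) < 0.4).astype(float)
        target = np.zeros(24)
        target[rng.integers(24)] = 1.0
        _, grads = loss_and_gradients(state, x, target)
        eps = 1e-6

        def fd(get, set_):
            orig = get()
            set_(orig + eps)
            lp, _ = loss_and_gradients(state, x, target)
            set_(orig - eps)
            lm, _ = loss_and_gradients(state, x, target)
            set_(orig)
            return (lp - lm) / (2 * eps)

        checked = 0
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            arr = getattr(state, name)
            flat = arr.reshape(-1)
            for idx in rng.choice(flat.size, size=min(12, flat.size), replace=False):
                num = fd(
                    lambda: flat[idx],
                    lambda v: flat.__setitem__(idx, v),
                )
                ana = grads[name].reshape(-1)[idx]
                assert ana == pytest.approx(num, rel=1e-5, abs=1e-9)
                checked += 1
        assert checked >= 50

        # input gradient against the same oracle
        for idx in rng.choice(20, size=5, replace=False):
            num = fd(lambda: x[idx], lambda v: x.__setitem__(idx, v))
            assert grads["x"][idx] == pytest.approx(num, rel=1e-5, abs=1e-9)

    def test_compiled_sgd_step_matches_reference_backprop(self, tiny_augmented_corpus):
        """One step of the compiled training kernel equals a manual update
        with the reference (numpy) gradients, to machine precision."""
        from tonalnet.encoding import encode_melody

        corpus = tn.Corpus(tiny_augmented_corpus.melodies[:1], augmented=True)
        idx_mat, lengths, targets = _pack_corpus(corpus)
        lr = 0.01
        kernel_state = init_network(5)
        ref_state = kernel_state.copy()
        perms = np.zeros((1, 1), dtype=np.int64)
        losses = _sgd_epochs(
            kernel_state.w1, kernel_state.b1, kernel_state.w2, kernel_state.b2,
            kernel_state.w3, kernel_state.b3,
            idx_mat, lengths, targets, perms, lr, 0.0, 1.0,
        )
        m = corpus.melodies[0]
        target = tn.encode_key(m.key)
        loss, grads = loss_and_gradients(ref_state, encode_melody(m), target)
        assert losses[0] == pytest.approx(loss, rel=1e-12)
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            expected = getattr(ref_state, name) - lr * grads[name]
            np.testing.assert_allclose(
                getattr(kernel_state, name), expected, atol=1e-14
            )


class TestCheckpointSchedule:
    def test_full_scale_schedule_has_ten_test_times(self):
        epochs = checkpoint_epochs(50_000, 5_000)
        assert epochs == list(range(5_000, 50_001, 5_000))
        assert len(epochs) == 10

    def test_non_dividing_interval_forces_final_checkpoint(self):
        assert checkpoint_epochs(10, 4) == [4, 8, 10]

    def test_baseline_prepended_on_request(self):
        assert checkpoint_epochs(10, 5, include_baseline=True) == [0, 5, 10]


class TestTraining:
    def test_toy_separable_corpus_reaches_full_agreement(self, tiny_augmented_corpus):
        state = init_network(1)
        cfg = tn.TrainingConfig(
            n_epochs=500, learning_rate=0.05, checkpoint_interval=100, seed=1
        )
        cps = tn.train(state, tiny_augmented_corpus, cfg)
        assert len(cps) == 5
        assert [cp.epoch for cp in cps] == [100, 200, 300, 400, 500]
        assert tn.agreement_rate(cps[-1].state, tiny_augmented_corpus) == 100.0

    def test_epoch_loss_trend_is_decreasing(self, tiny_augmented_corpus):
        state = init_network(2)
        cfg = tn.TrainingConfig(
            n_epochs=300, learning_rate=0.02, checkpoint_interval=50, seed=2
        )
        cps = tn.train(state, tiny_augmented_corpus, cfg)
        losses = [cp.training_loss for cp in cps]
        assert losses[-1] < losses[0]
        assert all(np.isfinite(losses))

    def test_fixed_seed_gives_bit_identical_checkpoints(self, tiny_augmented_corpus):
        cfg = tn.TrainingConfig(
            n_epochs=50, learning_rate=0.05, checkpoint_interval=25, seed=3
        )
        runs = []
        for _ in range(2):
            state = init_network(4)
            runs.append(tn.train(state, tiny_augmented_corpus, cfg))
        for cp_a, cp_b in zip(*runs):
            np.testing.assert_array_equal(cp_a.state.w1, cp_b.state.w1)
            np.testing.assert_array_equal(cp_a.state.w3, cp_b.state.w3)
            assert cp_a.training_loss == cp_b.training_loss

    def test_unaugmented_or_empty_corpus_rejected(self):
        state = init_network(0)
        base = tn.generate_corpus(tn.CorpusSpec(n_major=1, n_minor=0, seed=0))
        cfg = tn.TrainingConfig(n_epochs=10, checkpoint_interval=10)
        with pytest.raises(ValueError):
            tn.train(state, base, cfg)
        with pytest.raises(ValueError):
            tn.train(state, tn.Corpus([], augmented=True), cfg)

    def test_non_finite_loss_raises_divergence_error_with_epoch(
        self, tiny_augmented_corpus
    ):
        # bounded tanh outputs keep the loss finite under any learning rate,
        # so corrupt a parameter to exercise the divergence guard
        state = init_network(1)
        state.b1[0] = np.nan
        cfg = tn.TrainingConfig(
            n_epochs=10, learning_rate=0.01, checkpoint_interval=10, seed=1
        )
        with pytest.raises(DivergenceError) as exc:
            tn.train(state, tiny_augmented_corpus, cfg)
        assert exc.value.epoch == 1

    def test_transposed_training_item_maps_to_transposed_key(
        self, tiny_augmented_corpus
    ):
        # capacity sanity: a converged network generalizes the key of a
        # transposed copy at well above the 1/24 chance rate
        state = init_network(1)
        cfg = tn.TrainingConfig(
            n_epochs=500, learning_rate=0.05, checkpoint_interval=500, seed=1
        )
        cps = tn.train(state, tiny_augmented_corpus, cfg)
        hits = sum(
            tn.identify_key(cps[-1].state, m) == m.key for m in tiny_augmented_corpus
        )
        assert hits / len(tiny_augmented_corpus) > 3 / 24


class TestCheckpointIO:
    def test_roundtrip(self, tmp_path, tiny_augmented_corpus):
        state = init_network(1)
        cfg = tn.TrainingConfig(n_epochs=20, learning_rate=0.05, checkpoint_interval=20, seed=1)
        (cp,) = tn.train(state, tiny_augmented_corpus, cfg)
        path = tmp_path / "cp.npz"
        save_checkpoint(cp, path)
        loaded = load_checkpoint(path)
        assert loaded.epoch == cp.epoch
        assert loaded.training_loss == cp.training_loss
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            np.testing.assert_array_equal(
                getattr(loaded.state, name), getattr(cp.state, name)
            )
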