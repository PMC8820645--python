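import numpy as np
import pytest

from crossomics import (
    ArchitectureSpec,
    OmicsMatrix,
    TrainConfig,
    assign_dropout,
    build_model,
    embed,
    fit,
    load_model,
    reconstruct,
    resolve_layer_sizes,
    save_model,
    select_epochs,
)


class TestResolveLayerSizes:
    def test_n_layers_geometric(self):
        spec = ArchitectureSpec(embed_dim=4, size_mode="n_layers", n_in_layers=2)
        enc, _ = resolve_layer_sizes(100, 4, spec)
        # shrinkage (4/100)^(1/2) = 0.2 -> [20, 4]
        assert enc == [20, 4]

    def test_single_layer(self):
        spec = ArchitectureSpec(embed_dim=4, size_mode="n_layers", n_in_layers=1)
        enc, _ = resolve_layer_sizes(100, 4, spec)
        assert enc == [4]

    def test_explicit_identity(self):
        spec = ArchitectureSpec(embed_dim=32, size_mode="explicit",
                                encoder_sizes=[512, 128, 32])
        enc, _ = resolve_layer_sizes(1000, 32, spec)
        assert enc == [512, 128, 32]

    def test_shrinkage_mode_descends_to_bottleneck(self):
        spec = ArchitectureSpec(embed_dim=4, size_mode="shrinkage", shrinkage=0.5)
        enc, _ = resolve_layer_sizes(100, 4, spec)
        assert enc == [50, 25, 12, 6, 4]

    def test_bad_shrinkage_rejected(self):
        spec = ArchitectureSpec(embed_dim=4, size_mode="shrinkage", shrinkage=1.5)
        with pytest.raises(ValueError, match="shrinkage"):
            resolve_layer_sizes(100, 4, spec)

    def test_decoder_ends_at_q(self):
        spec = ArchitectureSpec(embed_dim=4, size_mode="n_layers",
                                n_in_layers=2, n_out_layers=2)
        _, dec = resolve_layer_sizes(100, 4, spec, q=100, s=0)
        assert dec == [20, 100]


class TestAssignDropout:
    def test_flat(self):
        spec = ArchitectureSpec(dropout_max=0.3, flat_dropout=True)
        assert assign_dropout(spec, 3) == [0.3, 0.3, 0.3]

    def test_graded_linear(self):
        spec = ArchitectureSpec(dropout_max=0.4, flat_dropout=False)
        np.testing.assert_allclose(assign_dropout(spec, 3), [0.4, 0.2, 0.0])

    @pytest.mark.parametrize("flat", [True, False])
    def test_zero_max(self, flat):
        spec = ArchitectureSpec(dropout_max=0.0, flat_dropout=flat)
        assert assign_dropout(spec, 4) == [0.0] * 4


class TestBuildModel:
    def test_confounder_width(self):
        arch = ArchitectureSpec(embed_dim=3, n_in_layers=2, n_out_layers=2)
        m0 = build_model(arch, p=20, q=30, s=0)
        m3 = build_model(arch, p=20, q=30, s=3)
        assert m0.dec_weights[0][0].shape[0] == 3
        assert m3.dec_weights[0][0].shape[0] == 6

    def test_forward_shape(self, rng):
        arch = ArchitectureSpec(embed_dim=3, n_in_layers=2, n_out_layers=2)
        m = build_model(arch, p=20, q=30, s=0, rng=rng)
        out = m.forward(rng.standard_normal((7, 20)), None)
        assert out.shape == (7, 30)


def _signal_pair(n=150, p=6, r=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(-0.5, 0.5, (n, p))
    Y = X[:, :r].copy()
    ids = [f"s{i}" for i in range(n)]
    x = OmicsMatrix(X, ids, [f"x{j}" for j in range(p)])
    y = OmicsMatrix(Y, ids, [f"y{j}" for j in range(r)])
    return x, y


class TestTraining:
    ARCH = ArchitectureSpec(embed_dim=3, size_mode="explicit",
                            encoder_sizes=[5, 3], decoder_sizes=[4],
                            dropout_max=0.0)

    def test_epoch_selection_is_argmin_and_deterministic(self):
        x, y = _signal_pair()
        cfg = TrainConfig(max_epochs=30, seed=7, batch_size=32)
        b1, h1 = select_epochs(x, y, None, self.ARCH, cfg)
        b2, h2 = select_epochs(x, y, None, self.ARCH, cfg)
        assert b1 == b2
        np.testing.assert_allclose(h1, h2, atol=1e-6)
        assert b1 == int(np.argmin(h1)) + 1

    def test_identity_signal_learned(self):
        # Y duplicates 3 columns of X: the identity map is representable,
        # so full-data reconstruction error should be far below Y variance
        x, y = _signal_pair()
        cfg = TrainConfig(max_epochs=200, seed=7, batch_size=32,
                          learning_rate=5e-3)
        model = fit(x, y, None, self.ARCH, cfg)
        mse = float(np.mean((reconstruct(model, x) - y.values) ** 2))
        assert mse < 0.1 * y.values.var(axis=0).mean()

    def test_same_seed_same_selection(self):
        x, y = _signal_pair()
        cfg = TrainConfig(max_epochs=20, seed=11, batch_size=32)
        m1 = fit(x, y, None, self.ARCH, cfg)
        m2 = fit(x, y, None, self.ARCH, cfg)
        assert m1.selected_epochs == m2.selected_epochs
        np.testing.assert_allclose(m1.net.enc_weights[0][0],
                                   m2.net.enc_weights[0][0])

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_nonfinite_loss_reported(self):
        x, y = _signal_pair()
        cfg = TrainConfig(max_epochs=5, seed=1, learning_rate=1e160, batch_size=32)
        with pytest.raises(FloatingPointError, match="epoch"):
            select_epochs(x, y, None, self.ARCH, cfg)


class TestEmbedReconstruct:
    def _fitted(self):
        x, y = _signal_pair()
        cfg = TrainConfig(max_epochs=5, seed=3, batch_size=32)
        return fit(x, y, None, TestTraining.ARCH, cfg), x, y

    def test_embedding_shape_and_determinism(self):
        model, x, _ = self._fitted()
        e1 = embed(model, x)
        e2 = embed(model, x)
        assert e1.values.shape == (x.n_samples, 3)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_identical_rows_embed_identically(self):
        model, x, _ = self._fitted()
        X2 = x.values.copy()
        X2[1] = X2[0]
        x2 = OmicsMatrix(X2, x.sample_ids, x.feature_ids)
        e = embed(model, x2)
        np.testing.assert_array_equal(e.values[0], e.values[1])

    def test_reconstruct_composes_embed_and_decode(self):
        model, x, _ = self._fitted()
        e = embed(model, x)
        np.testing.assert_allclose(
            reconstruct(model, x), model.net.decode(e.values, None)
        )

    def test_feature_mismatch_rejected(self, rng):
        model, x, _ = self._fitted()
        bad = OmicsMatrix(rng.standard_normal((4, 2)), list("abcd"), ["u", "v"])
        with pytest.raises(ValueError, match="features"):
            embed(model, bad)

    def test_missing_confounders_rejected(self, rng, confounders):
        from crossomics import encode_confounders
        enc = encode_confounders(confounders)
        n = len(enc.sample_ids)
        x = OmicsMatrix(rng.uniform(-0.5, 0.5, (n, 8)), enc.sample_ids,
                        [f"x{j}" for j in range(8)])
        y = OmicsMatrix(rng.standard_normal((n, 6)), enc.sample_ids,
                        [f"y{j}" for j in range(6)])
        arch = ArchitectureSpec(embed_dim=2, size_mode="explicit",
                                encoder_sizes=[4, 2], decoder_sizes=[4],
                                dropout_max=0.0)
        cfg = TrainConfig(max_epochs=3, seed=0, batch_size=3, holdout_frac=0.34)
        model = fit(x, y, enc, arch, cfg)
        assert model.s == 2
        with pytest.raises(ValueError, match="confounder"):
            reconstruct(model, x)  # c omitted


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        x, y = _signal_pair()
        cfg = TrainConfig(max_epochs=4, seed=5, batch_size=32)
        model = fit(x, y, None, TestTraining.ARCH, cfg)
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert back.selected_epochs == model.selected_epochs
        np.testing.assert_array_equal(
            embed(back, x).values, embed(model, x).values
        )


class TestNullData:
    def test_no_fake_signal_on_independent_y(self):
        # Y independent of X: holdout error should plateau near total Y
        # variance rather than dip substantially below it
        rng = np.random.default_rng(0)
        n = 500
        ids = [f"s{i}" for i in range(n)]
        x = OmicsMatrix(rng.uniform(-0.5, 0.5, (n, 20)), ids,
                        [f"x{j}" for j in range(20)])
        Y = rng.standard_normal((n, 15))
        Y = (Y - Y.mean(0)) / Y.std(0)
        y = OmicsMatrix(Y, ids, [f"y{j}" for j in range(15)])
        arch = ArchitectureSpec(embed_dim=3, n_in_layers=2, n_out_layers=2,
                                dropout_max=0.2)
        cfg = TrainConfig(max_epochs=40, seed=2)
        _, hist = select_epochs(x, y, None, arch, cfg)
        assert min(hist) > 0.8  # within 20% of unit holdout variance
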