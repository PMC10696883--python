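import numpy as np
import pytest

from crnn_tfbs._network import CRNNetwork
from crnn_tfbs.crnn import (
    BindingClassifier,
    ModelConfig,
    consistency_check,
    grid_search,
    load_model,
)
from crnn_tfbs.errors import ConfigError, InputError, ModelIOError
from crnn_tfbs.evaluate import roc_auc
from crnn_tfbs.negatives import build_balanced_dataset, split_dataset
from crnn_tfbs.synthdata import SyntheticConfig, simulate_reads

TINY = ModelConfig(
    conv_kernels=8, kernel_len=5, rnn_units=8, dense_units=8,
    batch_size=64, max_epochs=4, patience=2, seed=0,
)


def tiny_data(n=120, seed=0):
    reads, _ = simulate_reads(SyntheticConfig(n_reads=n, seed=seed))
    ds = build_balanced_dataset(reads, seed=seed)
    return split_dataset(ds, seed=seed)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(conv_dropout=1.0),
            dict(dense_dropout=-0.1),
            dict(max_norm=0.0),
            dict(kernel_len=25),
            dict(rnn_cell="gru"),
            dict(learning_rate=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            ModelConfig(**kw)

    def test_architecture_variants_build(self):
        for use_conv in (True, False):
            for bidirectional in (True, False):
                cfg = TINY.replace(use_conv=use_conv, bidirectional=bidirectional)
                model = BindingClassifier(cfg)
                assert model.n_parameters > 0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences everywhere
        (conv, pooling, both LSTM directions, dense layers)."""
        cfg = ModelConfig(
            conv_kernels=3, kernel_len=3, pool_size=2, conv_dropout=0.0,
            rnn_units=4, dense_units=5, dense_dropout=0.0, input_length=8,
            seed=3,
        )
        net = CRNNetwork(cfg)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 8, 4))
        y = np.array([1.0, 0.0, 1.0, 0.0])
        prob, cache = net.forward(X, train=True, rng=rng)
        grads = net.backward(cache, y)
        eps = 1e-6
        for key, W in net.params.items():
            flat_idx = rng.choice(W.size, size=min(8, W.size), replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, W.shape)
                orig = W[ix]
                W[ix] = orig + eps
                l1 = net.loss(net.forward(X)[0], y)
                W[ix] = orig - eps
                l2 = net.loss(net.forward(X)[0], y)
                W[ix] = orig
                num = (l1 - l2) / (2 * eps)
                assert abs(num - grads[key][ix]) < 1e-5 * max(
                    1.0, abs(num) + abs(grads[key][ix])
                ), f"gradient mismatch at {key}{ix}"

    def test_gradcheck_without_conv(self):
        cfg = ModelConfig(
            use_conv=False, rnn_units=3, dense_units=4, conv_dropout=0.0,
            dense_dropout=0.0, input_length=6, bidirectional=True, seed=5,
        )
        net = CRNNetwork(cfg)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 6, 4))
        y = np.array([1.0, 0.0, 1.0])
        _, cache = net.forward(X, train=True, rng=rng)
        grads = net.backward(cache, y)
        eps = 1e-6
        for key, W in net.params.items():
            fi = int(rng.integers(W.size))
            ix = np.unravel_index(fi, W.shape)
            orig = W[ix]
            W[ix] = orig + eps
            l1 = net.loss(net.forward(X)[0], y)
            W[ix] = orig - eps
            l2 = net.loss(net.forward(X)[0], y)
            W[ix] = orig
            num = (l1 - l2) / (2 * eps)
            assert abs(num - grads[key][ix]) < 1e-5 * max(1.0, abs(num))


class TestPredict:
    def test_untrained_scores_in_unit_interval(self, rng):
        model = BindingClassifier(TINY)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(30)]
        scores = model.predict(seqs)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_same_config_same_seed_identical_initial_predictions(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(10)]
        a = BindingClassifier(TINY).predict(seqs)
        b = BindingClassifier(TINY).predict(seqs)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_input_identical_scores(self, rng):
        model = BindingClassifier(TINY)
        s = "".join(rng.choice(list("ACGT"), 20))
        scores = model.predict([s, s, s])
        assert scores[0] == scores[1] == scores[2]

    def test_batch_size_invariance(self, rng):
        model = BindingClassifier(TINY.replace(batch_size=7))
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(50)]
        single = np.array([model.predict([s])[0] for s in seqs])
        batched = model.predict(seqs)
        np.testing.assert_allclose(single, batched, atol=1e-6)

    def test_wrong_length_names_offenders(self):
        model = BindingClassifier(TINY)
        from crnn_tfbs.seqio import SequenceRecord

        recs = [
            SequenceRecord(id="ok", seq="A" * 20),
            SequenceRecord(id="bad", seq="A" * 19),
        ]
        with pytest.raises(InputError, match="bad"):
            model.predict(recs)


class TestTraining:
    def test_learns_planted_motif_and_is_deterministic(self):
        train, val, test = tiny_data(n=400, seed=9)
        cfg = TINY.replace(
            conv_kernels=16, kernel_len=8, max_epochs=20, patience=6, seed=9
        )
        fit_a = BindingClassifier(cfg).fit(train, val)
        fit_b = BindingClassifier(cfg).fit(train, val)
        assert fit_a.validation_auc == pytest.approx(fit_b.validation_auc, abs=1e-6)
        assert fit_a.validation_auc > 0.8  # planted signal recovered
        model = fit_a.model
        scores = model.predict([r for r, _ in test.records])
        y = test.labels()
        assert roc_auc(scores[y == 1], scores[y == 0]).auc > 0.8
        # motif-bearing reads outscore their shuffles on average
        assert scores[y == 1].mean() > scores[y == 0].mean()

    def test_history_and_summary(self):
        train, val, _ = tiny_data(n=150, seed=3)
        fit = BindingClassifier(TINY.replace(seed=3)).fit(train, val)
        assert len(fit.history) >= 1
        assert {"epoch", "train_loss", "val_loss", "val_auc"} <= set(fit.history[0])
        text = fit.summary()
        assert "validation ROC-AUC" in text and "parameters" in text

    def test_empty_training_set_rejected(self):
        from crnn_tfbs.negatives import LabelledDataset

        _, val, _ = tiny_data(n=150, seed=3)
        with pytest.raises(InputError):
            BindingClassifier(TINY).fit(LabelledDataset(records=[]), val)


class TestPersistence:
    def test_round_trip_reproduces_predictions(self, tmp_path, rng):
        train, val, _ = tiny_data(n=150, seed=4)
        model = BindingClassifier(TINY.replace(seed=4))
        model.fit(train, val)
        probes = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(100)]
        before = model.predict(probes)
        model.save(tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        after = loaded.predict(probes)
        np.testing.assert_allclose(before, after, atol=1e-6)
        assert loaded.config == model.config
        assert loaded.fitted

    def test_truncated_blob_raises(self, tmp_path):
        model = BindingClassifier(TINY)
        model.save(tmp_path / "m")
        blob = tmp_path / "m" / "params.npz"
        blob.write_bytes(blob.read_bytes()[:40])
        with pytest.raises(ModelIOError):
            load_model(tmp_path / "m")

    def test_version_mismatch_raises(self, tmp_path):
        import json

        model = BindingClassifier(TINY)
        model.save(tmp_path / "m")
        manifest = json.loads((tmp_path / "m" / "config.json").read_text())
        manifest["format"] = "crnn-tfbs-model-v999"
        (tmp_path / "m" / "config.json").write_text(json.dumps(manifest))
        with pytest.raises(ModelIOError, match="incompatible"):
            load_model(tmp_path / "m")


class TestGridSearch:
    def test_singleton_grid(self):
        train, val, _ = tiny_data(n=150, seed=6)
        res = grid_search([TINY.replace(seed=6)], train, val)
        assert res.best_config == TINY.replace(seed=6)
        assert len(res.table) == 1

    def test_table_has_one_row_per_config_and_best_attains_max(self):
        train, val, _ = tiny_data(n=200, seed=7)
        grid = [
            TINY.replace(seed=7),
            TINY.replace(seed=7, use_conv=False),
            TINY.replace(seed=7, bidirectional=False),
        ]
        res = grid_search(grid, train, val)
        assert len(res.table) == len(grid)
        best_auc = max(auc for _, auc in res.table)
        assert dict(res.table)[res.best_config] == best_auc

    def test_invalid_config_fails_before_training(self):
        with pytest.raises(ConfigError):
            grid_search([TINY, TINY.replace(kernel_len=99)], None, None)

    def test_empty_grid_rejected(self):
        with pytest.raises(InputError):
            grid_search([], None, None)


class TestConsistencyCheck:
    def test_repeats_and_determinism(self):
        reads, _ = simulate_reads(SyntheticConfig(n_reads=150, seed=8))
        ds = build_balanced_dataset(reads, seed=8)
        a = consistency_check(TINY.replace(seed=8), ds, repeats=2, base_seed=5)
        b = consistency_check(TINY.replace(seed=8), ds, repeats=2, base_seed=5)
        assert a == b
        assert len(a.aucs) == 2
        assert a.mean == pytest.approx(np.mean(a.aucs), abs=1e-12)

    def test_repeats_lower_bound(self):
        reads, _ = simulate_reads(SyntheticConfig(n_reads=50, seed=8))
        ds = build_balanced_dataset(reads, seed=8)
        with pytest.raises(InputError):
            consistency_check(TINY, ds, repeats=1)
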