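"""Model contract: topology, training loop, early stopping, determinism."""

import numpy as np
import pytest

import labwatch as lw
from labwatch.models import (ARCHITECTURES, LabForecaster, ModelSpec,
                             TrainConfig, build_model, classify, fit_boosting,
                             load_results, predict_probabilities, save_results,
                             time_encode, train_model)
from labwatch.nn.autodiff import Tensor
from labwatch.windowing import Sample, SplitDataset


def _toy_dataset(n=80, W=4, C=2, seed=0, rule="first_channel"):
    """Hand-built SplitDataset where the label is a simple function of the
    last input row, so every learner can be checked for basic learning."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        x = rng.normal(size=(W, C))
        if rule == "first_channel":
            y = np.array([x[-1, j] > 0 for j in range(C)], dtype=np.uint8)
        else:  # constant-zero labels
            y = np.zeros(C, dtype=np.uint8)
        samples.append(Sample(inputs=x, demographics=np.array([60.0, 1.0, 80.0]),
                              target=y, stay_id=f"s{i}", target_step=W))
    n_tr = int(0.7 * n)
    n_va = int(0.15 * n)
    ds = SplitDataset(train=samples[:n_tr],
                      validation=samples[n_tr:n_tr + n_va],
                      test=samples[n_tr + n_va:],
                      fractions=(0.7, 0.15, 0.15), seed=seed,
                      channel_names=[f"c{j}" for j in range(C)], window=W)
    from labwatch.windowing import _fit_normalization
    _fit_normalization(ds)
    return ds


NEURAL = [a for a in ARCHITECTURES if a != "gbm"]


@pytest.mark.parametrize("arch", NEURAL)
def test_untrained_outputs_are_probabilities(arch, bench_dataset):
    ds = bench_dataset
    spec = ModelSpec(arch, ds.window, ds.n_channels)
    net = build_model(spec, seed=1)
    net.set_training(False)
    X, D, _ = ds.arrays("test")
    out = 1 / (1 + np.exp(-net(Tensor(X[:8]), Tensor(D[:8])).data))
    assert out.shape == (8, ds.n_channels)
    assert np.all((out > 0) & (out < 1))


def test_mcnn_has_two_parallel_streams():
    spec = ModelSpec("mcnn", 6, 5)
    net = build_model(spec, seed=0)
    assert len(net.streams) == 2
    ks = sorted(s.W.data.shape[0] for s in net.streams)
    assert ks == [2, 4]


def test_tcn_blocks_preserve_sequence_length():
    spec = ModelSpec("tcn", 6, 4)
    net = build_model(spec, seed=0)
    x = Tensor(np.random.default_rng(0).normal(size=(3, 6, 4)))
    z = x
    for b in net.blocks:
        z = b(z)
        assert z.shape[:2] == (3, 6)


def test_tcn_convolutions_are_causal():
    # perturbing a late time step never changes earlier outputs
    spec = ModelSpec("tcn", 6, 4)
    net = build_model(spec, seed=0)
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, 6, 4))
    x2 = x.copy()
    x2[0, 5, :] += 10.0
    z1, z2 = Tensor(x), Tensor(x2)
    for b in net.blocks:
        z1, z2 = b(z1), b(z2)
    np.testing.assert_allclose(z1.data[0, :5], z2.data[0, :5], atol=1e-12)


class TestTimeEncoding:
    def test_zero_frequencies_give_constant_periodic_components(self):
        from labwatch.nn import TimeEncoding
        enc = TimeEncoding(4, np.random.default_rng(0))
        enc.w.data[1:] = 0.0
        emb = enc.encode(np.arange(6)).data
        assert np.allclose(emb[:, 1:], emb[0, 1:])

    def test_unit_slope_linear_component_equals_indices(self):
        from labwatch.nn import TimeEncoding
        enc = TimeEncoding(3, np.random.default_rng(0))
        enc.w.data[0], enc.b.data[0] = 1.0, 0.0
        emb = enc.encode(np.arange(6)).data
        assert np.allclose(emb[:, 0], np.arange(6))

    def test_distinct_steps_have_distinct_embeddings(self):
        emb = time_encode(np.array([0, 3]), width=8, seed=2)
        assert not np.allclose(emb[0], emb[1])

    def test_width_below_two_rejected(self):
        from labwatch.nn import TimeEncoding
        with pytest.raises(ValueError):
            TimeEncoding(1, np.random.default_rng(0))


class TestTraining:
    def test_constant_validation_loss_stops_after_patience(self):
        # zero learning rate freezes the network, so the validation loss
        # never moves and the stopping rule fires after `patience` epochs
        ds = _toy_dataset()
        cfg = TrainConfig(max_epochs=40, learning_rate=0.0, patience=10)
        res = train_model(ds, ModelSpec("cnn", ds.window, ds.n_channels), cfg)
        assert res.n_epochs == 10

    def test_improving_loss_never_stops_early(self):
        ds = _toy_dataset()
        cfg = TrainConfig(max_epochs=12, learning_rate=5e-3, patience=10)
        res = train_model(ds, ModelSpec("cnn", ds.window, ds.n_channels), cfg)
        assert res.n_epochs == 12
        assert list(res.history["epoch"]) == list(range(1, 13))

    @pytest.mark.parametrize("arch", ["lstm", "mcnn", "gbm"])
    def test_learns_separable_rule_above_majority_baseline(self, arch):
        ds = _toy_dataset(n=200, seed=4)
        _, _, Ytr = ds.arrays("train")
        majority = max(Ytr.mean(), 1 - Ytr.mean())
        cfg = TrainConfig(max_epochs=20, learning_rate=1e-2, seed=0)
        spec = ModelSpec(arch, ds.window, ds.n_channels,
                         hyperparameters={"n_rounds": 50} if arch == "gbm" else {})
        res = train_model(ds, spec, cfg)
        X, D, Y = ds.arrays("train")
        pred = res.classify(res.predict_proba(X, D))
        acc = (pred == Y).mean()
        assert acc > majority

    def test_seed_reproducibility_bitwise(self):
        ds = _toy_dataset(n=60, seed=2)
        cfg = TrainConfig(max_epochs=5, seed=7)
        spec = ModelSpec("mcnn", ds.window, ds.n_channels)
        X, D, _ = ds.arrays("test")
        p1 = train_model(ds, spec, cfg).predict_proba(X, D)
        p2 = train_model(ds, spec, cfg).predict_proba(X, D)
        assert np.array_equal(p1, p2)

    def test_history_records_every_epoch(self):
        ds = _toy_dataset()
        cfg = TrainConfig(max_epochs=4)
        res = train_model(ds, ModelSpec("cnn", ds.window, ds.n_channels), cfg)
        assert set(res.history.columns) >= {"epoch", "train_loss", "val_loss",
                                            "val_accuracy", "val_f1"}
        assert len(res.history) == 4


class TestBoosting:
    def test_constant_label_degenerates_to_prior(self):
        ds = _toy_dataset(rule="zeros")
        res = fit_boosting(ds, gbm_config={"n_rounds": 10})
        assert all(res.degenerate_labels)
        X, D, _ = ds.arrays("test")
        p = res.predict_proba(X, D)
        assert np.all(p <= 0.0 + 1e-9)

    def test_separable_stump_is_perfect_on_training_data(self):
        ds = _toy_dataset(n=300, C=1, seed=5)
        res = fit_boosting(ds, gbm_config={"n_rounds": 100,
                                           "min_child_samples": 1})
        X, D, Y = ds.arrays("train")
        pred = res.classify(res.predict_proba(X, D))
        assert (pred == Y).mean() == 1.0

    def test_one_booster_per_label(self, bench_dataset):
        res = fit_boosting(bench_dataset, gbm_config={"n_rounds": 5})
        assert len(res.boosters) == 25
        assert "boosters fitted:    25" in res.summary()


class TestPredictClassify:
    def test_empty_sample_list_gives_empty_matrix(self, bench_dataset):
        cfg = TrainConfig(max_epochs=1)
        res = train_model(bench_dataset,
                          ModelSpec("cnn", bench_dataset.window,
                                    bench_dataset.n_channels), cfg)
        assert predict_probabilities(res, []).shape == (0, 25)

    def test_inference_is_deterministic(self, bench_dataset):
        cfg = TrainConfig(max_epochs=1)
        res = train_model(bench_dataset,
                          ModelSpec("lstm", bench_dataset.window,
                                    bench_dataset.n_channels), cfg)
        samples = bench_dataset.test[:5] * 2  # same inputs twice
        p = predict_probabilities(res, samples)
        assert np.array_equal(p[:5], p[5:])

    def test_threshold_is_strict(self):
        p = np.array([[0.5, 0.50001, 1.0, 0.0]])
        assert classify(p, 0.5).tolist() == [[0, 1, 1, 0]]

    def test_positive_count_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        p = rng.random((50, 10))
        counts = [classify(p, th).sum() for th in np.linspace(0.05, 0.95, 10)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify(np.array([[1.5]]), 0.5)
        with pytest.raises(ValueError):
            classify(np.array([[0.5]]), 1.0)
        with pytest.raises(ValueError):
            ModelSpec("resnet", 6, 25)
        with pytest.raises(ValueError):
            ModelSpec("cnn", 2, 25, hyperparameters={"kernel_size": 3})


def test_checkpoint_roundtrip(tmp_path, bench_dataset):
    for arch, kw in (("cnn", {}), ("gbm", {"n_rounds": 5})):
        spec = ModelSpec(arch, bench_dataset.window, bench_dataset.n_channels,
                         hyperparameters=kw)
        res = train_model(bench_dataset, spec, TrainConfig(max_epochs=2))
        save_results(res, tmp_path / arch)
        back = load_results(tmp_path / arch, bench_dataset)
        X, D, _ = bench_dataset.arrays("test")
        np.testing.assert_allclose(res.predict_proba(X, D),
                                   back.predict_proba(X, D), atol=1e-12)
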