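import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tasteeg import nn
from tasteeg.model import (
    BranchSpec,
    ModelConfig,
    ModelError,
    TrainConfig,
    bandpower_baseline,
    build_model,
    load_model,
    predict,
    save_model,
    train,
)
from tasteeg.preprocess import PreprocessConfig, preprocess_recordings, split
from tasteeg.synth import generate_dataset

from .conftest import tiny_model_config, tiny_synth_config


def closed_form_param_count(config: ModelConfig) -> int:
    """Layer-by-layer parameter-count oracle, written independently of the
    network construction code."""
    window_len, n_channels = config.input_shape
    total = 0
    concat_width = 0
    for b in config.branches:
        total += (b.kernel_len * n_channels + 1) * b.n_filters
        conv_len = window_len - b.kernel_len + 1
        concat_width += (conv_len // b.pool_len) * b.n_filters
    prev = concat_width
    for size in config.dense_sizes:
        total += (prev + 1) * size
        prev = size
    total += (prev + 1) * config.n_classes
    return total


def random_model_config(rng: np.random.Generator) -> ModelConfig:
    window_len = int(rng.integers(64, 513))
    n_channels = int(rng.integers(1, 4))
    branches = tuple(
        BranchSpec(
            n_filters=int(rng.integers(2, 33)),
            kernel_len=int(rng.integers(3, min(64, window_len) + 1)),
            pool_len=int(rng.integers(1, 9)),
        )
        for _ in range(3)
    )
    n_dense = int(rng.integers(1, 5))
    dense_sizes = tuple(int(rng.integers(4, 65)) for _ in range(n_dense))
    return ModelConfig(branches=branches, dense_sizes=dense_sizes,
                       n_classes=int(rng.integers(2, 6)),
                       input_shape=(window_len, n_channels))


class TestBuildModel:
    def test_forward_on_zero_window_is_probability_vector(self):
        net = build_model(ModelConfig(), seed=0)
        logits = net.forward(np.zeros((1, 1028, 2), dtype=np.float32), training=False)
        probs = nn.softmax(logits)
        assert probs.shape == (1, 4)
        assert abs(probs.sum() - 1.0) < 1e-6
        assert (probs >= 0).all()

    def test_default_parameter_count_matches_oracle(self):
        config = ModelConfig()
        assert build_model(config).n_params == closed_form_param_count(config)

    def test_parameter_count_oracle_on_random_configs(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            config = random_model_config(rng)
            assert build_model(config).n_params == closed_form_param_count(config)

    def test_two_branches_rejected(self):
        with pytest.raises(ModelError, match="3 branches"):
            ModelConfig(branches=(BranchSpec(), BranchSpec()))

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ModelError, match="kernel"):
            ModelConfig(branches=(BranchSpec(kernel_len=7),
                                  BranchSpec(kernel_len=2000),
                                  BranchSpec(kernel_len=31)))

    def test_seeded_init_reproducible(self):
        a = build_model(ModelConfig(), seed=3)
        b = build_model(ModelConfig(), seed=3)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa, pb)


class TestSoftmax:
    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=4,
                    max_size=4))
    def test_softmax_valid_distribution(self, logits):
        probs = nn.softmax(np.array([logits]))
        assert abs(probs.sum() - 1.0) < 1e-6
        assert (probs >= 0).all() and (probs <= 1).all()

    def test_softmax_extreme_logits_stable(self):
        probs = nn.softmax(np.array([[1e4, -1e4, 0.0, 0.0]]))
        assert np.all(np.isfinite(probs))
        assert abs(probs.sum() - 1.0) < 1e-6


@pytest.fixture(scope="module")
def tiny_split(request):
    rs = generate_dataset(tiny_synth_config(effect_size=6.0, seed=11))
    cfg = PreprocessConfig(window_len=128, stride_s=0.5)  # 7 windows/recording
    wm, _ = preprocess_recordings(rs, cfg)
    return split(wm, fraction=0.7, mode="group", seed=11)


@pytest.fixture(scope="module")
def tiny_trained(tiny_split):
    net = build_model(tiny_model_config(), seed=11)
    return train(net, tiny_split,
                 TrainConfig(epochs=40, batch_size=32, learning_rate=3e-3, seed=11))


class TestTrain:
    def test_loss_decreases_on_learnable_data(self, tiny_trained):
        history = tiny_trained.history
        assert history[-1]["train_loss"] < history[0]["train_loss"]

    def test_high_separability_reaches_high_training_accuracy(self, tiny_trained):
        assert tiny_trained.history[-1]["train_acc"] > 0.9

    def test_epochs_one_gives_single_history_entry(self, tiny_split):
        net = build_model(tiny_model_config(), seed=0)
        tm = train(net, tiny_split, TrainConfig(epochs=1, batch_size=32, seed=0))
        assert len(tm.history) == 1

    def test_empty_train_set_rejected(self, tiny_split):
        import dataclasses

        empty = dataclasses.replace(tiny_split,
                                    train=tiny_split.train.subset(np.array([], dtype=int)))
        net = build_model(tiny_model_config(), seed=0)
        with pytest.raises(ModelError, match="empty"):
            train(net, empty, TrainConfig(epochs=1, seed=0))

    def test_history_bounded_by_epochs(self, tiny_split):
        net = build_model(tiny_model_config(), seed=1)
        tm = train(net, tiny_split,
                   TrainConfig(epochs=30, batch_size=32, seed=1,
                               early_stopping=True, patience=2))
        assert len(tm.history) <= 30

    def test_label_permutation_equivariance_loose(self, tiny_split):
        # renaming the classes must not change learnability; compared at a
        # loose tolerance after a short run
        import dataclasses

        perm = {"water": "sucralose", "sucralose": "water",
                "sucrose": "aspartame", "aspartame": "sucrose"}

        def relabel(wm):
            return dataclasses.replace(
                wm, labels=np.array([perm[l] for l in wm.labels]),
                class_order=tuple(perm[c] for c in wm.class_order))

        permuted = dataclasses.replace(tiny_split, train=relabel(tiny_split.train),
                                       test=relabel(tiny_split.test))
        tc = TrainConfig(epochs=15, batch_size=32, seed=5)
        acc_a = train(build_model(tiny_model_config(), seed=5), tiny_split,
                      tc).history[-1]["train_acc"]
        acc_b = train(build_model(tiny_model_config(), seed=5), permuted,
                      tc).history[-1]["train_acc"]
        assert abs(acc_a - acc_b) < 0.2


class TestPredict:
    def test_probability_rows_sum_to_one(self, tiny_trained, tiny_split):
        _, probs = predict(tiny_trained, tiny_split.test)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6

    def test_train_set_prediction_consistent_with_history(self, tiny_trained,
                                                          tiny_split):
        # dropout off at inference: accuracy on the training set should be
        # at least the final (dropout-noised) training accuracy - 0.02
        labels, _ = predict(tiny_trained, tiny_split.train)
        acc = float((labels == tiny_split.train.labels).mean())
        assert acc >= tiny_trained.history[-1]["train_acc"] - 0.02

    def test_empty_window_matrix_gives_empty_outputs(self, tiny_trained,
                                                     tiny_split):
        empty = tiny_split.test.subset(np.array([], dtype=int))
        labels, probs = predict(tiny_trained, empty)
        assert len(labels) == 0 and probs.shape == (0, 4)

    def test_shape_mismatch_rejected(self, tiny_trained, tiny_split):
        import dataclasses

        bad = dataclasses.replace(tiny_split.test,
                                  windows=tiny_split.test.windows[:, :64, :])
        with pytest.raises(ModelError, match="shape"):
            predict(tiny_trained, bad)

    def test_save_load_roundtrip(self, tiny_trained, tiny_split, tmp_path):
        save_model(tiny_trained, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        a, pa = predict(tiny_trained, tiny_split.test)
        b, pb = predict(loaded, tiny_split.test)
        assert np.array_equal(a, b)
        np.testing.assert_allclose(pa, pb, rtol=1e-5)


class TestBandpowerBaseline:
    def test_separable_classes_recovered(self, tiny_split):
        bands = [(8, 12), (14, 18), (22, 26), (30, 34)]
        report = bandpower_baseline(tiny_split, bands, fs=128.0)
        assert report.macro_recall > 0.9

    def test_effect_size_zero_is_chance_level(self):
        rs = generate_dataset(tiny_synth_config(effect_size=0.0, seed=21,
                                                n_subjects=10))
        wm, _ = preprocess_recordings(rs, PreprocessConfig(window_len=128, stride_s=0.5))
        ds = split(wm, fraction=0.7, mode="group", seed=21)
        report = bandpower_baseline(ds, [(8, 12), (14, 18), (22, 26), (30, 34)],
                                    fs=128.0)
        # cluster-level binomial 99% CI around 0.25: windows from one
        # recording are heavily correlated, so n = number of test recordings
        n_groups = len(set(ds.test.groups))
        half_width = 2.576 * np.sqrt(0.25 * 0.75 / n_groups)
        assert abs(report.macro_recall - 0.25) < half_width + 0.05

    def test_single_wide_band_on_equal_power_classes_near_chance(self, tiny_split):
        # every class puts the same total power into 8-40 Hz, so one wide
        # band power is class-invariant
        report = bandpower_baseline(tiny_split, [(8, 40)], fs=128.0)
        assert report.macro_recall < 0.5

    def test_empty_band_list_rejected(self, tiny_split):
        with pytest.raises(ModelError, match="nonempty"):
            bandpower_baseline(tiny_split, [], fs=128.0)

    def test_band_outside_nyquist_rejected(self, tiny_split):
        with pytest.raises(ModelError, match="band"):
            bandpower_baseline(tiny_split, [(8, 100)], fs=128.0)


class TestGradients:
    def test_dense_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        layer = nn.Dense(5, 3, rng)
        x = rng.normal(size=(4, 5)).astype(np.float64)
        onehot = np.eye(3)[rng.integers(0, 3, size=4)]

        def loss_fn():
            logits = layer.forward(x, training=True)
            loss, _ = nn.softmax_cross_entropy(logits, onehot)
            return loss

        logits = layer.forward(x, training=True)
        _, dlogits = nn.softmax_cross_entropy(logits, onehot)
        layer.backward(dlogits)
        analytic = layer.dW.copy()

        eps = 1e-5
        for i, j in [(0, 0), (2, 1), (4, 2)]:
            layer.W[i, j] += eps
            up = loss_fn()
            layer.W[i, j] -= 2 * eps
            down = loss_fn()
            layer.W[i, j] += eps
            numeric = (up - down) / (2 * eps)
            assert analytic[i, j] == pytest.approx(numeric, abs=1e-4)

    def test_conv_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        conv = nn.Conv1D(2, 3, 5, rng)
        conv.W = conv.W.astype(np.float64)
        x = rng.normal(size=(2, 16, 2))
        target = rng.normal(size=(2, 12, 3))

        def loss_fn():
            y = conv.forward(x, training=True)
            return 0.5 * float(((y - target) ** 2).sum())

        y = conv.forward(x, training=True)
        conv.backward(y - target)
        analytic = conv.dW.copy()

        eps = 1e-6
        for i, j in [(0, 0), (5, 2), (9, 1)]:
            conv.W[i, j] += eps
            up = loss_fn()
            conv.W[i, j] -= 2 * eps
            down = loss_fn()
            conv.W[i, j] += eps
            numeric = (up - down) / (2 * eps)
            assert analytic[i, j] == pytest.approx(numeric, rel=1e-3)

    def test_maxpool_backward_routes_to_argmax(self):
        pool = nn.MaxPool1D(2)
        x = np.array([[[1.0], [3.0], [2.0], [0.0]]])
        out = pool.forward(x, training=True)
        assert out[0, :, 0].tolist() == [3.0, 2.0]
        dx = pool.backward(np.ones_like(out))
        assert dx[0, :, 0].tolist() == [0.0, 1.0, 1.0, 0.0]
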