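import numpy as np
import pytest

from amps import datasets, models, nn
from amps.datasets import Dataset, DatasetSplit


def window_dataset(n, W_s, a=0, seed=0, signal=True):
    """Toy windows where (optionally) column sums encode the label."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2).astype(np.uint8)
    X = np.zeros((n, W_s, 4 + a), dtype=np.uint8)
    codes = rng.integers(0, 4, size=(n, W_s))
    if signal:  # label 1 -> pure 'A' windows, label 0 -> pure 'T'
        codes[y == 1] = 0
        codes[y == 0] = 3
    for j in range(4):
        X[:, :, j] = codes == j
    if a:
        X[:, :, 4:] = rng.integers(0, 2, size=(n, W_s, a))
    keys = [f"w{i}" for i in range(n)]
    centers = [("chr1", i, "+", "CG") for i in range(n)]
    return Dataset(y=y, centers=centers, keys=keys, X=X)


def neighbor_dataset(n, W_p=20, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2).astype(np.uint8)
    V = np.clip(y[:, None] * 0.9 + 0.05
                + rng.normal(0, noise, size=(n, W_p)), 0, 1)
    keys = [f"v{i}" for i in range(n)]
    centers = [("chr1", i, "+", "CG") for i in range(n)]
    return Dataset(y=y, centers=centers, keys=keys, V=V)


def make_split(ds, seed=0):
    return datasets.split_80_10_10(ds, seed=seed)


class TestArchitectures:
    def test_cnn_param_count_closed_form(self):
        W_s, a = 100, 3
        model = models.build_amps_cnn(W_s, a)
        k = 4 + a
        conv = k * (4 + a) * 16 + 16
        flat = 16 * (W_s - k + 1)
        dense1 = flat * 128 + 128
        dense2 = 128 + 1
        assert model.n_params == conv + dense1 + dense2

    def test_cnn_no_annotations_input_width(self):
        model = models.build_amps_cnn(50, 0)
        out = model.net.forward(np.zeros((2, 50, 4), dtype=np.float32))
        assert out.shape == (2, 1)

    def test_cnn_kernel_width_follows_annotations(self):
        model = models.build_amps_cnn(50, 3)
        conv = model.net.layers[0]
        assert conv.kernel_size == 7 and conv.in_channels == 7

    def test_cnn_all_zero_input_probability_in_unit_interval(self):
        model = models.build_amps_cnn(50, 0, seed=3)
        probs, _ = models.predict(model, window_dataset(4, 50, signal=False))
        assert ((probs > 0) & (probs < 1)).all()

    def test_mlp_param_count_closed_form(self):
        model = models.build_neighbor_mlp(20)
        expected = (20 * 20 + 20) + (20 * 16 + 16) + (16 * 8 + 8) + (8 + 1)
        assert model.n_params == expected

    def test_mlp_rejects_mismatched_input(self):
        with pytest.raises(ValueError):
            models.build_neighbor_mlp(30)
        model = models.build_neighbor_mlp(30, widths=(30, 16, 8))
        assert model.net.forward(np.zeros((1, 30), dtype=np.float32)).shape \
            == (1, 1)

    def test_mlp_scalar_probability(self):
        model = models.build_neighbor_mlp(20)
        probs, _ = models.predict(model, neighbor_dataset(6))
        assert probs.shape == (6,)

    def test_combined_forward_and_zero_neighbors(self):
        model = models.build_combined(60, 3, 20, seed=1)
        X = np.zeros((3, 60, 7), dtype=np.float32)
        V = np.zeros((3, 20), dtype=np.float32)
        out = model.net.forward((X, V))
        assert out.shape == (3, 1)

    def test_combined_param_count_closed_form(self):
        W_s, a, W_p = 60, 3, 20
        model = models.build_combined(W_s, a, W_p)
        k = 4 + a
        conv1 = k * (4 + a) * 16 + 16
        conv2 = k * 16 * 16 + 16
        flat = 16 * (W_s - 2 * (k - 1))
        head = ((flat + W_p) * 16 + 16) + (16 * 8 + 8) + (8 + 1)
        assert model.n_params == conv1 + conv2 + head

    def test_same_seed_identical_untrained_model(self):
        a = models.build_neighbor_mlp(20, seed=5)
        b = models.build_neighbor_mlp(20, seed=5)
        ds = neighbor_dataset(10)
        pa, _ = models.predict(a, ds)
        pb, _ = models.predict(b, ds)
        assert (pa == pb).all()


class TestRandomForest:
    def test_memorizes_separable_data(self):
        ds = window_dataset(100, 16, seed=1)
        split = DatasetSplit(ds, ds, ds, seed=0)
        trained = models.train(models.build_random_forest(0), split)
        assert models.accuracy(trained, ds) == 1.0

    def test_probabilities_sum_to_one(self):
        ds = window_dataset(40, 16, seed=2)
        split = DatasetSplit(ds, ds, ds, seed=0)
        trained = models.train(models.build_random_forest(0), split)
        X = ds.X.reshape(len(ds), -1).astype(np.float32)
        proba = trained.model.net.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_seed_determinism(self):
        ds = window_dataset(60, 16, seed=3, signal=False)
        split = DatasetSplit(ds, ds, ds, seed=0)
        p1, _ = models.predict(models.train(models.build_random_forest(7),
                                            split), ds)
        p2, _ = models.predict(models.train(models.build_random_forest(7),
                                            split), ds)
        assert (p1 == p2).all()


class TestTraining:
    def test_learns_separable_windows(self):
        ds = window_dataset(400, 24, seed=4)
        split = make_split(ds)
        cfg = models.TrainConfig(epochs=5, learning_rate=0.05, seed=1)
        trained = models.train(models.build_amps_cnn(24, 0, seed=1), split, cfg)
        assert models.accuracy(trained, split.test) >= 0.95

    def test_neighbor_signal_separates_extremes(self):
        ds = neighbor_dataset(600, seed=5)
        split = make_split(ds)
        cfg = models.TrainConfig(epochs=8, learning_rate=0.05, seed=2)
        trained = models.train(models.build_neighbor_mlp(20, seed=2), split,
                               cfg)
        lo = Dataset(y=np.array([0], dtype=np.uint8),
                     centers=[("c", 0, "+", "CG")], keys=["lo"],
                     V=np.zeros((1, 20)))
        hi = Dataset(y=np.array([1], dtype=np.uint8),
                     centers=[("c", 1, "+", "CG")], keys=["hi"],
                     V=np.ones((1, 20)))
        p_lo, _ = models.predict(trained, lo)
        p_hi, _ = models.predict(trained, hi)
        assert p_hi[0] > p_lo[0]

    def test_combined_tracks_neighbor_only_signal(self):
        # windows are noise, neighbor vectors carry the label: the combined
        # net should land close to the neighbor-only MLP
        rng = np.random.default_rng(12)
        n, W_s = 800, 32
        ds = window_dataset(n, W_s, seed=12, signal=False)
        ds.V = np.clip(ds.y[:, None] * 0.9 + 0.05
                       + rng.normal(0, 0.05, size=(n, 20)), 0, 1)
        split = make_split(ds, seed=12)
        cfg = models.TrainConfig(epochs=8, learning_rate=0.05, seed=12)
        combined = models.train(models.build_combined(W_s, 0, 20, seed=12),
                                split, cfg)
        mlp = models.train(models.build_neighbor_mlp(20, seed=12), split, cfg)
        acc_combined = models.accuracy(combined, split.test)
        acc_mlp = models.accuracy(mlp, split.test)
        assert acc_combined >= 0.8
        assert abs(acc_combined - acc_mlp) <= 0.15

    def test_history_and_best_epoch_contract(self):
        ds = neighbor_dataset(200, seed=6)
        split = make_split(ds)
        cfg = models.TrainConfig(epochs=4, seed=3)
        trained = models.train(models.build_neighbor_mlp(20, seed=3), split,
                               cfg)
        assert len(trained.history) == 4
        accs = [h["val_accuracy"] for h in trained.history]
        assert accs[trained.best_epoch] == max(accs)

    def test_same_seed_identical_history(self):
        ds = neighbor_dataset(200, seed=7)
        split = make_split(ds)
        cfg = models.TrainConfig(epochs=3, seed=9)
        t1 = models.train(models.build_neighbor_mlp(20, seed=9), split, cfg)
        t2 = models.train(models.build_neighbor_mlp(20, seed=9), split, cfg)
        assert t1.history == t2.history

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_noise_never_far_below_chance(self, seed):
        ds = neighbor_dataset(300, seed=seed, noise=0.5)
        rng = np.random.default_rng(seed)
        rng.shuffle(ds.y)  # destroy any residual signal
        split = make_split(ds, seed=seed)
        cfg = models.TrainConfig(epochs=2, seed=seed)
        trained = models.train(models.build_neighbor_mlp(20, seed=seed),
                               split, cfg)
        assert trained.history[trained.best_epoch]["val_accuracy"] >= 0.35

    def test_nan_loss_aborts(self):
        ds = neighbor_dataset(100, seed=8)
        split = make_split(ds)
        model = models.build_neighbor_mlp(20, seed=0)
        model.net.layers[0].params["W"][:] = np.inf
        with pytest.raises(RuntimeError, match="non-finite"):
            models.train(model, split, models.TrainConfig(epochs=1, seed=0))

    def test_empty_partition_rejected(self):
        ds = neighbor_dataset(100)
        empty = ds.subset(np.array([], dtype=np.int64))
        with pytest.raises(ValueError):
            models.train(models.build_neighbor_mlp(20),
                         DatasetSplit(ds, empty, ds, seed=0))


class TestPredict:
    def test_probability_half_calls_methylated(self):
        model = models.build_neighbor_mlp(20, seed=0)
        for layer, name in model.net.parameters():
            layer.params[name][:] = 0.0  # logit 0 -> probability 0.5
        probs, calls = models.predict(model, neighbor_dataset(4))
        assert np.allclose(probs, 0.5)
        assert (calls == 1).all()

    def test_empty_input(self):
        model = models.build_neighbor_mlp(20, seed=0)
        ds = neighbor_dataset(10).subset(np.array([], dtype=np.int64))
        probs, calls = models.predict(model, ds)
        assert len(probs) == 0 and len(calls) == 0

    def test_batch_size_invariance(self):
        model = models.build_amps_cnn(24, 0, seed=4)
        ds = window_dataset(30, 24, seed=9, signal=False)
        p1, c1 = models.predict(model, ds, batch_size=7)
        p2, c2 = models.predict(model, ds, batch_size=512)
        assert np.allclose(p1, p2)
        assert (c1 == c2).all()

    def test_shape_mismatch_raises(self):
        model = models.build_amps_cnn(24, 0, seed=4)
        with pytest.raises(ValueError):
            models.predict(model, neighbor_dataset(4))


class TestSerialization:
    def test_network_round_trip(self, tmp_path):
        ds = neighbor_dataset(120, seed=10)
        split = make_split(ds)
        cfg = models.TrainConfig(epochs=2, seed=1)
        trained = models.train(models.build_neighbor_mlp(20, seed=1), split,
                               cfg)
        path = tmp_path / "model.npz"
        models.save_model(trained, path)
        again = models.load_model(path)
        assert again.spec == trained.spec
        assert again.history == trained.history
        p1, _ = models.predict(trained, ds)
        p2, _ = models.predict(again, ds)
        assert np.allclose(p1, p2)

    def test_random_forest_round_trip(self, tmp_path):
        ds = window_dataset(60, 16, seed=11)
        split = DatasetSplit(ds, ds, ds, seed=0)
        trained = models.train(models.build_random_forest(3), split)
        path = tmp_path / "rf.bin"
        models.save_model(trained, path)
        again = models.load_model(path)
        p1, _ = models.predict(trained, ds)
        p2, _ = models.predict(again, ds)
        assert (p1 == p2).all()
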