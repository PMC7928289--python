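"""Decoders: ANOVA selection, linear fits, network architecture contracts."""

import numpy as np
import pytest

from fmrileak.experiments import separable_trial_set
from fmrileak.models import (
    CNN3D,
    M2DCNN,
    ModelConfig,
    ModelError,
    anova_select,
    build_3dcnn,
    build_m2dcnn,
    fit_decoder,
    fit_linear_decoder,
    learning_rate_at,
    m2dcnn_param_count,
    predict_labels,
    train_network,
)


def brute_force_f(X, y):
    """Independent one-way F statistic, straight from the definition."""
    out = np.zeros(X.shape[1])
    groups = [X[y == c] for c in np.unique(y)]
    grand = X.mean(axis=0)
    k = len(groups)
    n = X.shape[0]
    for j in range(X.shape[1]):
        ssb = sum(len(g) * (g[:, j].mean() - grand[j]) ** 2 for g in groups)
        ssw = sum(((g[:, j] - g[:, j].mean()) ** 2).sum() for g in groups)
        if ssw == 0:
            out[j] = 0.0
        else:
            out[j] = (ssb / (k - 1)) / (ssw / (n - k))
    return out


class TestAnovaSelect:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ranking(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((30, 20))
        y = rng.permutation([0] * 15 + [1] * 15)
        sel = anova_select(X, y, k=5)
        f = brute_force_f(X, y)
        expected = np.sort(np.argsort(-f, kind="stable")[:5])
        np.testing.assert_array_equal(sel, expected)

    def test_perfectly_separated_voxel_wins(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 3))
        y = np.array([0] * 10 + [1] * 10)
        X[:, 1] = y * 10.0 + rng.standard_normal(20) * 0.01
        assert anova_select(X, y, k=1)[0] == 1

    def test_tie_breaks_to_lower_index(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(20)
        y = np.array([0, 1] * 10)
        X = np.column_stack([base + y, base + y, rng.standard_normal(20)])
        sel = anova_select(X, y, k=1)
        assert sel[0] == 0  # voxels 0 and 1 identical: lower index first

    def test_k_equals_all_is_identity(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 6))
        y = np.array([0, 1] * 6)
        np.testing.assert_array_equal(anova_select(X, y, k=6), np.arange(6))

    def test_errors(self):
        X = np.ones((6, 3))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ModelError):
            anova_select(X, y, k=4)
        with pytest.raises(ModelError):
            anova_select(X, np.zeros(6, dtype=int), k=1)

    def test_zero_variance_voxel_ranked_last(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 4))
        X[:, 2] = 7.0  # constant
        y = np.array([0, 1] * 10)
        sel = anova_select(X, y, k=3)
        assert 2 not in sel


class TestLinearDecoders:
    @pytest.mark.parametrize("family", ["plr", "svm"])
    def test_separable_blobs_perfect_accuracy(self, family):
        ds = separable_trial_set(60, (6, 6, 6), seed=0)
        order = np.random.default_rng(0).permutation(60)
        train, test = ds.subset(order[:40]), ds.subset(order[40:])
        cfg = ModelConfig(family=family, n_selected_voxels=50)
        model = fit_linear_decoder(cfg, train)
        _, acc_train = predict_labels(model, train)
        _, acc_test = predict_labels(model, test)
        assert acc_train == 1.0
        assert acc_test == 1.0
        assert model.best_param in cfg.reg_grid

    def test_pure_noise_is_at_chance(self):
        """Held-out accuracy on label-free noise ~ 0.5 over 50 draws."""
        rng = np.random.default_rng(0)
        cfg = ModelConfig(family="plr", n_selected_voxels=10, inner_folds=2)
        accs = []
        for draw in range(50):
            from .conftest import random_trial_dataset

            ds = random_trial_dataset(
                n_trials=60, shape=(3, 3, 3), seed=1000 + draw
            )
            train, test = ds.subset(np.arange(40)), ds.subset(np.arange(40, 60))
            if len(np.unique(train.labels)) < 2:
                continue
            model = fit_linear_decoder(cfg, train)
            _, acc = predict_labels(model, test)
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_single_class_train_rejected(self):
        from .conftest import random_trial_dataset

        ds = random_trial_dataset(n_trials=20, seed=0)
        ds.labels[:] = 1
        with pytest.raises(ModelError):
            fit_linear_decoder(ModelConfig(family="plr", n_selected_voxels=5), ds)


class TestM2DCNNArchitecture:
    def test_forward_gives_two_scores(self):
        net = build_m2dcnn((16, 16, 16))
        x = np.random.default_rng(0).standard_normal((3, 16, 16, 16))
        assert net.forward(x).shape == (3, 2)

    def test_param_count_closed_form(self):
        for shape in [(16, 16, 16), (6, 8, 10)]:
            net = M2DCNN(shape, n_filters=4, kernel=3, pool=2)
            assert net.n_params() == m2dcnn_param_count(shape, n_filters=4)

    def test_axis_permutation_preserves_param_count(self):
        base = m2dcnn_param_count((6, 8, 10), n_filters=4)
        for perm in [(10, 6, 8), (8, 10, 6), (10, 8, 6)]:
            assert m2dcnn_param_count(perm, n_filters=4) == base

    def test_kernel_too_large_rejected(self):
        with pytest.raises(ModelError):
            M2DCNN((2, 2, 2), kernel=3)


class TestCNN3DArchitecture:
    def test_forward_gives_two_scores(self):
        net = build_3dcnn((16, 16, 16), t_boxcars=4)
        x = np.random.default_rng(0).standard_normal((2, 4, 16, 16, 16))
        assert net.forward(x).shape == (2, 2)

    def test_single_boxcar_degenerates_to_3d(self):
        net = build_3dcnn((10, 10, 10), t_boxcars=1)
        x = np.random.default_rng(0).standard_normal((2, 1, 10, 10, 10))
        assert net.forward(x).shape == (2, 2)

    def test_volume_smaller_than_kernel_stack_rejected(self):
        with pytest.raises(ModelError):
            CNN3D((4, 4, 4), 4, kernel=3, pool=2, n_conv_layers=2)


class TestTraining:
    def test_learning_rate_schedule(self):
        cfg = ModelConfig(family="m2dcnn", lr_decay_gamma=0.97)
        for e in [0, 1, 10, 299]:
            assert learning_rate_at(cfg, e) == pytest.approx(
                0.001 * 0.97**e, abs=1e-12
            )

    def test_fixed_seed_reproducible(self):
        ds = separable_trial_set(20, (6, 6, 6), seed=3)
        cfg = ModelConfig(family="m2dcnn", epochs=3, n_filters=2, batch_size=8)
        m1 = fit_decoder(cfg, ds, None, seed=5)
        m2 = fit_decoder(cfg, ds, None, seed=5)
        assert m1.history["loss"] == m2.history["loss"]

    def test_history_recorded_and_best_checkpoint_used(self):
        train = separable_trial_set(30, (6, 6, 6), seed=4)
        valid = separable_trial_set(10, (6, 6, 6), seed=4)
        cfg = ModelConfig(family="m2dcnn", epochs=4, n_filters=2, batch_size=8)
        net = M2DCNN((6, 6, 6), n_filters=2, dropout=0.5,
                     rng=np.random.default_rng(0))
        model = train_network(net, cfg, train, valid, seed=0)
        assert len(model.history["loss"]) == 4
        assert len(model.history["valid_acc"]) == 4

    def test_wrong_form_rejected(self):
        ds_box = separable_trial_set(10, (6, 6, 6), form="boxcar", seed=0)
        with pytest.raises(ModelError):
            fit_decoder(ModelConfig(family="m2dcnn"), ds_box, None)
        ds_avg = separable_trial_set(10, (6, 6, 6), seed=0)
        with pytest.raises(ModelError):
            fit_decoder(ModelConfig(family="cnn3d"), ds_avg, None)


class TestPredictLabels:
    def test_accuracy_contracts(self):
        ds = separable_trial_set(20, (6, 6, 6), seed=6)
        cfg = ModelConfig(family="plr", n_selected_voxels=30)
        model = fit_linear_decoder(cfg, ds)
        pred, acc = predict_labels(model, ds)
        assert acc == np.mean(pred == ds.labels)
        flipped = ds.with_labels(1 - pred)
        _, acc0 = predict_labels(model, flipped)
        assert acc0 == 0.0
        exact = ds.with_labels(pred)
        _, acc1 = predict_labels(model, exact)
        assert acc1 == 1.0

    def test_permutation_invariance(self):
        ds = separable_trial_set(20, (6, 6, 6), seed=6)
        cfg = ModelConfig(family="plr", n_selected_voxels=30)
        model = fit_linear_decoder(cfg, ds)
        _, acc = predict_labels(model, ds)
        perm = np.random.default_rng(0).permutation(20)
        _, acc_perm = predict_labels(model, ds.subset(perm))
        assert acc == acc_perm
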