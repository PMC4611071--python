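"""SCG training: gradients, convergence, cross-validation, pruning."""

import dataclasses

import numpy as np
import pytest

from senscreen import scg
from senscreen.scg import (
    MLPParams,
    forward,
    init_mlp,
    kfold_cv,
    parameter_scan,
    prune_by_mse,
    train_scg,
)

XOR_X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
XOR_Y = np.array([[0.0, 1], [1, 0], [1, 0], [0, 1]])


def two_clusters(n=200, separation=6.0, dim=5, seed=0):
    """Linearly separable blobs: class means separated by `separation` sd."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(half, dim)),
            rng.normal(separation, 1.0, size=(n - half, dim)),
        ]
    )
    Y = np.vstack([np.tile([1.0, 0.0], (half, 1)), np.tile([0.0, 1.0], (n - half, 1))])
    return X, Y


class TestInit:
    def test_seed_reproducibility(self):
        p = MLPParams(n_inputs=5, hidden_layers=[7], seed=42)
        a, b = init_mlp(p), init_mlp(p)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_seeds_differ(self):
        p1 = MLPParams(n_inputs=5, seed=1)
        p2 = MLPParams(n_inputs=5, seed=2)
        assert not np.array_equal(init_mlp(p1).weights[0], init_mlp(p2).weights[0])

    def test_fan_in_bound(self):
        p = MLPParams(n_inputs=16, hidden_layers=[9], seed=0)
        m = init_mlp(p)
        assert np.abs(m.weights[0]).max() <= 1 / 4  # fan_in 16
        assert np.abs(m.weights[1]).max() <= 1 / 3  # fan_in 9

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            MLPParams(n_inputs=0)
        with pytest.raises(ValueError):
            MLPParams(n_inputs=3, hidden_layers=[0])


class TestForward:
    def test_zero_weights_give_half(self):
        p = MLPParams(n_inputs=3, hidden_layers=[4], seed=0)
        m = init_mlp(p)
        for w in m.weights:
            w[...] = 0
        for b in m.biases:
            b[...] = 0
        out = forward(m, np.array([[1.0, -2.0, 3.0]]))
        np.testing.assert_allclose(out, [[0.5, 0.5]])

    def test_outputs_bounded(self, rng):
        p = MLPParams(n_inputs=6, seed=3)
        m = init_mlp(p)
        out = forward(m, rng.normal(size=(50, 6)) * 10)
        assert ((out > 0) & (out < 1)).all()

    def test_hand_computed_2_2_2_network(self):
        p = MLPParams(n_inputs=2, hidden_layers=[2], seed=0)
        m = init_mlp(p)
        m.weights[0][...] = [[0.5, -1.0], [0.25, 0.75]]
        m.biases[0][...] = [0.1, -0.2]
        m.weights[1][...] = [[1.0, 0.5], [-0.5, 2.0]]
        m.biases[1][...] = [0.0, -1.0]
        x = np.array([1.0, 2.0])
        h = np.tanh([0.5 * 1 + 0.25 * 2 + 0.1, -1.0 * 1 + 0.75 * 2 - 0.2])
        z = [h[0] * 1.0 + h[1] * -0.5, h[0] * 0.5 + h[1] * 2.0 - 1.0]
        expected = 1 / (1 + np.exp(-np.asarray(z)))
        np.testing.assert_allclose(forward(m, x)[0], expected, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        m = init_mlp(MLPParams(n_inputs=4, seed=0))
        with pytest.raises(ValueError):
            forward(m, np.zeros((1, 3)))


class TestGradient:
    @pytest.mark.parametrize("layout,wd", [((3, [4]), 0.0), ((2, [2]), 0.0),
                                           ((5, [3]), 0.1), ((4, [2, 3]), 0.0)])
    def test_backprop_matches_central_differences(self, layout, wd, rng):
        n_in, hidden = layout
        p = MLPParams(n_inputs=n_in, hidden_layers=hidden, seed=7, weight_decay=wd)
        m = init_mlp(p)
        assert m.n_weights <= 50
        X = rng.normal(size=(9, n_in))
        Y = rng.uniform(size=(9, 2))
        _, grad = scg.loss_and_grad(m, X, Y)
        w0 = scg._get_flat(m)
        eps = 1e-6
        num = np.zeros_like(w0)
        for i in range(len(w0)):
            wp = w0.copy(); wp[i] += eps
            scg._set_flat(m, wp)
            ep, _ = scg.loss_and_grad(m, X, Y)
            wm = w0.copy(); wm[i] -= eps
            scg._set_flat(m, wm)
            em, _ = scg.loss_and_grad(m, X, Y)
            num[i] = (ep - em) / (2 * eps)
        scg._set_flat(m, w0)
        assert np.abs(num - grad).max() < 1e-6


class TestTraining:
    def test_xor_trains_on_most_seeds(self):
        solved = 0
        for seed in range(10):
            p = MLPParams(n_inputs=2, hidden_layers=[2], max_epochs=500, seed=seed)
            m = scg.fit(XOR_X, XOR_Y, p)
            solved += scg.normalized_mse(m, XOR_X, XOR_Y) < 0.01
        assert solved >= 9

    def test_separable_clusters_fit_perfectly(self):
        X, Y = two_clusters()
        p = MLPParams(n_inputs=X.shape[1], max_epochs=100, seed=0)
        m = scg.fit(X, Y, p)
        out = forward(m, X)
        pred = (out[:, 0] >= out[:, 1]).astype(int)
        truth = (Y[:, 0] >= Y[:, 1]).astype(int)
        assert (pred == truth).all()

    def test_accepted_steps_never_increase_error(self):
        X, Y = two_clusters(n=60, dim=3, seed=2)
        p = MLPParams(
            n_inputs=3, hidden_layers=[5], max_epochs=200, seed=1, plateau_window=0
        )
        m = init_mlp(p)
        _, history = train_scg(m, X, Y, p)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_same_seed_identical_history(self):
        X, Y = two_clusters(n=40, dim=3, seed=4)
        p = MLPParams(n_inputs=3, hidden_layers=[4], max_epochs=50, seed=9)
        _, h1 = train_scg(init_mlp(p), X, Y, p)
        _, h2 = train_scg(init_mlp(p), X, Y, p)
        assert h1 == h2

    def test_model_json_roundtrip(self, tmp_path):
        X, Y = two_clusters(n=30, dim=3, seed=5)
        p = MLPParams(n_inputs=3, hidden_layers=[4], max_epochs=20, seed=0)
        m = scg.fit(X, Y, p)
        m.to_json(tmp_path / "m.json")
        back = scg.MLPModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(forward(back, X), forward(m, X))


class TestCrossValidation:
    def test_leave_one_out_has_singleton_folds(self):
        X, Y = two_clusters(n=12, dim=2, separation=8, seed=1)
        p = MLPParams(n_inputs=2, hidden_layers=[2], max_epochs=60, seed=0)
        report = kfold_cv(X, Y, p, k=12, seed=0)
        assert sorted(np.bincount(report.fold_of)) == [1] * 12

    def test_fold_sizes_and_stratification(self):
        X, Y = two_clusters(n=103, dim=2, seed=3)
        p = MLPParams(n_inputs=2, hidden_layers=[2], max_epochs=5, seed=0)
        report = kfold_cv(X, Y, p, k=10, seed=0)
        sizes = np.bincount(report.fold_of, minlength=10)
        assert sizes.max() - sizes.min() <= 1
        labels = (Y[:, 0] >= Y[:, 1]).astype(int)
        global_frac = labels.mean()
        for fold in range(10):
            frac = labels[report.fold_of == fold].mean()
            n_fold = sizes[fold]
            # active count within +-1 compound of the proportional share
            assert abs(frac * n_fold - global_frac * n_fold) <= 1 + 1e-9

    def test_separable_fixture_high_cv_accuracy(self):
        X, Y = two_clusters(n=120, dim=4, seed=6)
        p = MLPParams(n_inputs=4, hidden_layers=[5], max_epochs=80, seed=0)
        report = kfold_cv(X, Y, p, k=5, seed=0)
        assert report.accuracy > 0.95
        assert ((report.per_compound_mse >= 0) & (report.per_compound_mse <= 1)).all()


class TestPruning:
    def _report(self, mses):
        return scg.CVReport(
            fold_of=np.zeros(len(mses), dtype=int),
            fold_confusions=[],
            accuracy=1.0,
            kappa=1.0,
            per_compound_mse=np.asarray(mses),
        )

    def test_exact_prediction_retained_and_opposite_excluded(self):
        # (1,0) vs target (1,0): mse 0; (0,1) vs (1,0): mse 1
        report = self._report([0.0, 1.0])
        assert prune_by_mse(report, 0.4).tolist() == [0]

    def test_raising_threshold_never_shrinks(self, rng):
        report = self._report(rng.uniform(size=50))
        prev: set = set()
        for thr in (0.1, 0.3, 0.5, 0.9):
            kept = set(prune_by_mse(report, thr).tolist())
            assert prev <= kept
            prev = kept

    def test_label_noise_flagged_by_cv_mse(self):
        X, Y = two_clusters(n=100, dim=4, separation=6, seed=8)
        rng = np.random.default_rng(8)
        flipped = rng.choice(100, size=7, replace=False)
        Yn = Y.copy()
        Yn[flipped] = 1 - Yn[flipped]
        hits = 0
        for seed in range(5):
            p = MLPParams(n_inputs=4, hidden_layers=[5], max_epochs=60, seed=seed)
            report = kfold_cv(X, Yn, p, k=5, seed=seed)
            excluded = set(np.where(report.per_compound_mse > 0.4)[0])
            hits += len(excluded & set(flipped.tolist())) >= 5
        assert hits >= 4  # noisy labels are consistently misclassified


class TestParameterScan:
    def test_single_config_single_row(self):
        X, Y = two_clusters(n=40, dim=2, seed=2)
        rows = parameter_scan(
            X, Y, [{"hidden_layers": [3], "max_epochs": 20}], k=4, seed=0
        )
        assert len(rows) == 1 and rows[0]["best"]

    def test_duplicate_configs_identical_metrics(self):
        X, Y = two_clusters(n=40, dim=2, seed=2)
        grid = [{"hidden_layers": [3], "max_epochs": 20}] * 2
        rows = parameter_scan(X, Y, grid, k=4, seed=0)
        assert rows[0]["accuracy"] == rows[1]["accuracy"]
        assert rows[0]["kappa"] == rows[1]["kappa"]

    def test_scg_at_least_matches_plain_gradient(self):
        X, Y = two_clusters(n=80, dim=3, separation=4, seed=5)
        wins = 0
        for seed in range(5):
            grid = [
                {"hidden_layers": [20], "trainer": "scg", "max_epochs": 40},
                {"hidden_layers": [20], "trainer": "gd", "max_epochs": 40},
            ]
            rows = parameter_scan(X, Y, grid, k=4, seed=seed)
            wins += rows[0]["kappa"] >= rows[1]["kappa"]
        assert wins >= 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            parameter_scan(np.zeros((4, 2)), np.zeros((4, 2)), [])
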