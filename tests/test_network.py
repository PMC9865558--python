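"""Rendering-layer network: gradients, construction, training, search."""

import numpy as np
import pytest

import illumopt as il
from illumopt.network import (
    NeuralLightingClassifier,
    NNConfig,
    build_model,
    cross_entropy,
    grid_search,
    init_lighting,
    table2_grid,
    train,
)
from illumopt.spectral import render
from illumopt.synthetic import PatchDataset


def _random_batch(rng, n, p, nch, nl):
    A = rng.normal(size=(n, p, p, nch, nl))
    y = np.zeros((n, 2))
    y[np.arange(n), rng.integers(0, 2, n)] = 1.0
    return A, y


class TestRenderingLayer:
    def test_identical_to_spectral_render(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 5, 5, 3, 8))
        x = rng.normal(size=8)
        cfg = NNConfig(model_kind="cnn", seed=0)
        tm = build_model(cfg, 5, 3, 8, x0=x)
        assert np.array_equal(
            tm.model.rendering.forward(A), render(A, x)
        )

    def test_unit_weight_selects_sublight_block(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(2, 1, 1, 3, 6))
        e2 = np.zeros(6)
        e2[2] = 1.0
        assert np.allclose(render(A, e2), A[..., 2])

    def test_jacobian_matches_finite_differences(self):
        """d(output)/dx_i is the i-th sub-light block of the input."""
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 1, 1, 3, 5))
        x = rng.normal(size=5)
        eps = 1e-6
        for i in range(5):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (render(A, xp) - render(A, xm)) / (2 * eps)
            rel = np.abs(fd - A[..., i]) / np.maximum(np.abs(A[..., i]), 1e-8)
            assert rel.max() < 1e-4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            render(np.zeros((2, 1, 1, 3, 5)), np.zeros(4))


class TestInitLighting:
    def test_uniform_ones(self):
        assert np.array_equal(init_lighting("uniform_ones", 7), np.ones(7))

    def test_d65_approx_delegates_to_pseudo_inverse(self, sublights, grid_full):
        d65 = il.load_d65(grid_full)
        x = init_lighting("d65_approx", 24, sublights, d65)
        assert np.allclose(
            x, il.approximate_illuminant(sublights, d65).x_approx
        )

    def test_d65_approx_requires_inputs(self):
        with pytest.raises(ValueError):
            init_lighting("d65_approx", 24)

    @pytest.mark.parametrize("scheme,lo,hi", [
        ("random_pm1", -1.0, 1.0), ("random_01", 0.0, 1.0),
    ])
    def test_random_schemes_deterministic_and_bounded(self, scheme, lo, hi):
        a = init_lighting(scheme, 50, seed=3)
        b = init_lighting(scheme, 50, seed=3)
        assert np.array_equal(a, b)
        assert a.min() >= lo and a.max() <= hi
        assert not np.array_equal(a, init_lighting(scheme, 50, seed=4))


class TestBuildModel:
    def test_fcl_parameter_count_hand_computed(self):
        # x:24 | 3->10: 40 | 10->10 twice: 220 | 10->2: 22  => 306
        cfg = NNConfig(model_kind="fcl", n_layers=3, n_units=10)
        tm = build_model(cfg, 1, 3, 24)
        assert tm.model.n_parameters() == 24 + 40 + 110 + 110 + 22

    def test_cnn_parameter_count_hand_computed(self):
        # x:24 | conv 3x3x3x10+10: 280 | conv 3x3x10x10+10: 910
        # | fc 10->10: 110 | 10->2: 22
        cfg = NNConfig(model_kind="cnn", n_layers=3, n_units=10)
        tm = build_model(cfg, 5, 3, 24)
        assert tm.model.n_parameters() == 24 + 280 + 910 + 110 + 22

    def test_zero_weights_give_even_softmax(self):
        cfg = NNConfig(model_kind="fcl", n_layers=3, n_units=10,
                       dropout_p=0.0)
        tm = build_model(cfg, 1, 3, 24)
        for layer in tm.model.head:
            if hasattr(layer, "W"):
                layer.W[:] = 0.0
        proba = tm.model.predict_proba(np.zeros((4, 1, 1, 3, 24)))
        assert np.allclose(proba, 0.5)

    def test_grid_enumerates_18_architectures(self):
        for kind in ("fcl", "cnn"):
            grid = table2_grid(kind)
            assert len(grid) == 18
            assert len({(c.n_layers, c.n_units, c.activation) for c in grid}) == 18

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_model(NNConfig(model_kind="fcl"), 5, 3, 24)
        with pytest.raises(ValueError):
            build_model(NNConfig(model_kind="cnn"), 1, 3, 24)

    def test_cnn_consumes_5x5_patch_exactly(self):
        cfg = NNConfig(model_kind="cnn", n_layers=3, dropout_p=0.0)
        tm = build_model(cfg, 5, 3, 24)
        logits = tm.model.forward(np.zeros((2, 5, 5, 3, 24)))
        assert logits.shape == (2, 2)


class TestCrossEntropy:
    def test_equal_logits_ln2(self):
        assert cross_entropy([0.0, 0.0], [1.0, 0.0]) == pytest.approx(
            np.log(2.0), rel=1e-12
        )

    def test_extreme_logits_stable(self):
        loss = cross_entropy([1000.0, -1000.0], [1.0, 0.0])
        assert loss == pytest.approx(0.0, abs=1e-12)
        loss_wrong = cross_entropy([1000.0, -1000.0], [0.0, 1.0])
        assert np.isfinite(loss_wrong) and loss_wrong > 100

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            z = rng.normal(scale=3, size=2)
            c = rng.integers(0, 2)
            y = np.eye(2)[c]
            direct = -np.log(np.exp(z[c]) / np.exp(z).sum())
            assert cross_entropy(z, y) == pytest.approx(direct, rel=1e-10)

    def test_batch_mean(self):
        z = np.array([[0.0, 0.0], [1.0, 0.0]])
        y = np.eye(2)
        single = [cross_entropy(zi, yi) for zi, yi in zip(z, y)]
        assert cross_entropy(z, y) == pytest.approx(np.mean(single))


class TestEndToEndGradients:
    @pytest.mark.parametrize("kind,p", [("fcl", 1), ("cnn", 5)])
    def test_loss_gradient_wrt_x_matches_finite_differences(self, kind, p):
        rng = np.random.default_rng(5)
        cfg = NNConfig(model_kind=kind, n_layers=3, n_units=10,
                       dropout_p=0.0, seed=7)
        tm = build_model(cfg, p, 3, 6)
        A, y = _random_batch(rng, 8, p, 3, 6)
        tm.model.loss_and_backward(A, y, train=False)
        grad = tm.model.rendering.grad_x.copy()
        x = tm.model.rendering.x
        eps = 1e-6
        for i in range(6):
            orig = x[i]
            x[i] = orig + eps
            lp = cross_entropy(tm.model.forward(A), y)
            x[i] = orig - eps
            lm = cross_entropy(tm.model.forward(A), y)
            x[i] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - grad[i]) / max(abs(fd), abs(grad[i]), 1e-8) < 1e-4

    def test_two_forms_of_forward_agree(self):
        """Explicit rendering inside the net equals the classifier applied
        to pre-rendered images."""
        rng = np.random.default_rng(6)
        cfg = NNConfig(model_kind="cnn", dropout_p=0.0, seed=1)
        tm = build_model(cfg, 5, 3, 8)
        A, _ = _random_batch(rng, 10, 5, 3, 8)
        with_rendering = tm.model.forward(A)
        pre = render(A, tm.model.rendering.x)
        without = tm.model.forward_from_rendered(pre)
        rel = np.abs(with_rendering - without) / np.maximum(
            np.abs(without), 1e-12
        )
        assert rel.max() < 1e-6


class TestTrain:
    def _separable_toy(self, rng, n=60):
        """1x1 pixels, 2 lights; class decided by the sign of light-0
        response."""
        A = rng.normal(size=(n, 1, 1, 2, 2))
        y = np.where(A[:, 0, 0, 0, 0] > 0, 1, -1)
        A[:, 0, 0, :, 0] += np.where(y > 0, 2.0, -2.0)[:, None]
        return PatchDataset(A, y, 1, target_class=1)

    def test_loss_falls_on_separable_toy(self):
        rng = np.random.default_rng(7)
        ds = self._separable_toy(rng)
        cfg = NNConfig(model_kind="fcl", epochs=400, dropout_p=0.0, seed=0)
        tm = build_model(cfg, 1, 2, 2)
        train(tm, ds, cfg)
        assert tm.loss_history[-1] < 0.1 * np.log(2.0)

    def test_frozen_lighting_stays_bit_identical(self):
        rng = np.random.default_rng(8)
        ds = self._separable_toy(rng)
        x0 = np.array([0.3, -0.7])
        cfg = NNConfig(model_kind="fcl", epochs=20, seed=0)
        tm = build_model(cfg, 1, 2, 2, x0=x0, trainable_lighting=False)
        train(tm, ds, cfg)
        assert np.array_equal(tm.x, x0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        ds = self._separable_toy(rng)
        cfg = NNConfig(model_kind="fcl", epochs=15, seed=3)
        runs = []
        for _ in range(2):
            tm = build_model(cfg, 1, 2, 2)
            train(tm, ds, cfg)
            runs.append((tm.x.copy(), list(tm.loss_history)))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_single_class_rejected(self):
        rng = np.random.default_rng(10)
        ds = self._separable_toy(rng)
        bad = PatchDataset(ds.A, np.ones_like(ds.y), 1, 1)
        cfg = NNConfig(model_kind="fcl", epochs=1)
        tm = build_model(cfg, 1, 2, 2)
        with pytest.raises(ValueError):
            train(tm, bad, cfg)

    def test_learned_update_targets_discriminative_band(self, pixel_ds):
        """The gradient-driven change of x concentrates (above the chance
        share) on the sub-lights overlapping the discriminative band."""
        from conftest import COVERING

        x0 = init_lighting("random_pm1", 24, seed=0)
        clf = NeuralLightingClassifier(
            epochs=400, random_state=0, x0=x0
        ).fit(pixel_ds.A, pixel_ds.y)
        delta = np.abs(clf.x_ - x0)
        share = delta[list(COVERING)].sum() / delta.sum()
        assert share > len(COVERING) / 24


@pytest.fixture(scope="module")
def toy_ds():
    rng = np.random.default_rng(11)
    A = rng.normal(size=(40, 1, 1, 2, 2))
    y = np.where(A[:, 0, 0, 0, 0] > 0, 1, -1)
    A[:, 0, 0, :, 0] += np.where(y > 0, 2.0, -2.0)[:, None]
    return il.assign_folds(PatchDataset(A, y, 1, 1), 4, seed=0)


class TestGridSearch:

    def test_table_rows_and_argmax_contract(self, toy_ds):
        grid = [
            NNConfig(model_kind="fcl", n_layers=3, n_units=u, epochs=30,
                     seed=0)
            for u in (5, 10)
        ]
        best, table = grid_search(toy_ds, grid, 4)
        assert len(table) == 2
        best_row = max(table, key=lambda r: r["mean_f1"])
        assert best.config == best_row["config"]
        assert all(len(r["fold_f1"]) == 4 for r in table)

    def test_singleton_grid_reduces_to_cv_train(self, toy_ds):
        cfg = NNConfig(model_kind="fcl", epochs=30, seed=0)
        best, table = grid_search(toy_ds, [cfg], 4)
        assert len(table) == 1 and best.config == cfg

    def test_empty_grid_rejected(self, toy_ds):
        with pytest.raises(ValueError):
            grid_search(toy_ds, [], 4)


class TestEstimator:
    def test_chance_level_on_shuffled_labels(self, pixel_ds):
        """With labels shuffled there is nothing to learn: held-out F1
        stays in the chance band implied by the positive prevalence."""
        rng = np.random.default_rng(12)
        y_shuf = rng.permutation(pixel_ds.y)
        tr = slice(0, 400)
        te = slice(400, None)
        clf = NeuralLightingClassifier(epochs=100, random_state=0)
        clf.fit(pixel_ds.A[tr], y_shuf[tr])
        f1 = il.binary_metrics(y_shuf[te], clf.predict(pixel_ds.A[te]))[0]
        # prevalence ~ 3/8; an uninformed classifier's F1 stays below ~0.65
        assert f1 < 0.65

    def test_sklearn_interface_and_flat_input(self, pixel_ds):
        flat = pixel_ds.A.reshape(pixel_ds.n_samples, -1)
        clf = NeuralLightingClassifier(
            epochs=30, patch_size=1, n_channels=3, n_lights=24,
            random_state=0,
        )
        clf.fit(flat, pixel_ds.y)
        ref = NeuralLightingClassifier(epochs=30, random_state=0)
        ref.fit(pixel_ds.A, pixel_ds.y)
        assert np.allclose(clf.x_, ref.x_)
        assert clf.get_params()["epochs"] == 30
        proba = clf.predict_proba(flat[:5])
        assert proba.shape == (5, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
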