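import numpy as np
import pytest

from clonomark import (
    HyperNetParams,
    LabeledDataset,
    TrainConfig,
    AdaptiveLogisticRegression,
    StandardANN,
    bce_loss,
    hypernet_forward,
    model_forward,
    predict_proba,
    roc,
)
from clonomark.model import _loss_and_grads, load_params

from .oracles import hypernet_reference, pairwise_auc, selu_reference


def random_params(g, h, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return HyperNetParams.init_random(g, h, rng, input_scale=scale)


def separable_dataset(n_per_class=30, n_donors=6, seed=0):
    """Two-gene toy data: malignant cells high in gene 1, no noise overlap."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    x1 = np.concatenate([rng.uniform(8, 10, n_per_class), rng.uniform(0, 2, n_per_class)])
    x2 = rng.uniform(3, 5, n)
    y = np.array([1] * n_per_class + [0] * n_per_class)
    order = rng.permutation(n)
    return LabeledDataset(
        matrix=np.column_stack([x1, x2])[order],
        gene_names=["g_up", "g_flat"],
        cell_ids=[f"c{i}" for i in range(n)],
        donor_ids=[f"d{i % n_donors}" for i in range(n)],
        targets=y[order],
    )


class TestForwardPasses:
    def test_zero_params_give_uniform_weights_and_half_probability(self):
        params = HyperNetParams.zeros(4, 3)
        x = np.array([5.0, 1.0, 0.0, 2.5])
        a = hypernet_forward(params, x)
        assert np.allclose(a, 0.25)
        assert model_forward(params, x) == 0.5

    def test_uniform_weights_closed_form(self):
        params = HyperNetParams.zeros(4, 2)
        params.w_D = 1.0
        x = np.array([4.0, 0.0, 0.0, 0.0])
        # a uniform -> a.x = 1 -> sigmoid(1)
        assert model_forward(params, x) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_equation_evaluation(self, seed):
        params = random_params(5, 3, seed=seed)
        rng = np.random.default_rng(100 + seed)
        x = rng.gamma(2.0, 2.0, size=5)
        a_ref, p_ref = hypernet_reference(params, x)
        assert np.allclose(hypernet_forward(params, x), a_ref, atol=1e-6)
        assert model_forward(params, x) == pytest.approx(p_ref, abs=1e-6)

    def test_weights_normalised_and_positive_for_extreme_inputs(self):
        params = random_params(20, 6, seed=1)
        for x in [np.zeros(20), np.full(20, 1e6), np.linspace(0, 1e4, 20)]:
            a = hypernet_forward(params, x)
            assert a.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(a > 0)

    def test_full_scale_gene_count_shape(self):
        # the real assay measures ~44.8k genes; shape-only smoke test
        g = 44782
        params = HyperNetParams.zeros(g, 2)
        a = hypernet_forward(params, np.ones(g))
        assert a.shape == (g,)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_raises(self):
        params = HyperNetParams.zeros(4, 3)
        with pytest.raises(ValueError):
            hypernet_forward(params, np.ones(5))
        with pytest.raises(ValueError):
            predict_proba(params, np.ones((2, 5)))


class TestPredict:
    def test_zero_params_all_half(self):
        params = HyperNetParams.zeros(6, 2)
        assert np.allclose(predict_proba(params, np.random.default_rng(0).random((7, 6))), 0.5)

    def test_vectorisation_matches_per_row_forward(self):
        params = random_params(8, 3, seed=2)
        X = np.random.default_rng(3).gamma(2, 2, size=(100, 8))
        batch = predict_proba(params, X)
        looped = np.array([model_forward(params, row) for row in X])
        assert np.allclose(batch, looped, atol=1e-9)


class TestBceLoss:
    def test_hand_values(self):
        assert bce_loss(np.array([0.5]), np.array([1])) == pytest.approx(np.log(2), abs=1e-12)
        assert bce_loss(np.array([0.9, 0.2]), np.array([1, 0])) == pytest.approx(
            np.mean([-np.log(0.9), -np.log(0.8)]), abs=1e-12
        )

    def test_perfect_predictions_and_clamping(self):
        assert bce_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-10
        assert np.isfinite(bce_loss(np.array([0.0]), np.array([1])))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1, 0]))


class TestGradients:
    @pytest.mark.parametrize("seed", range(3))
    def test_analytic_gradients_match_finite_differences(self, seed):
        """Central finite differences on every parameter of a G=10, H=4
        instance agree with backpropagation to 1e-4 relative error."""
        g, h, n = 10, 4, 8
        params = random_params(g, h, seed=seed)
        rng = np.random.default_rng(200 + seed)
        X = rng.gamma(2.0, 2.0, size=(n, g))
        y = rng.integers(0, 2, size=n).astype(float)
        _, grads = _loss_and_grads(params, X, y)
        eps = 1e-6
        base = params.to_dict()

        def loss_at(k, idx, delta):
            d = {kk: np.array(vv, dtype=float) for kk, vv in base.items()}
            arr = np.atleast_1d(d[k])
            arr[idx] += delta
            d[k] = arr if np.ndim(base[k]) else float(arr[0])
            return bce_loss(predict_proba(HyperNetParams(**d), X), y)

        for k, v in base.items():
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            gk = np.atleast_1d(np.asarray(grads[k], dtype=float))
            for idx in np.ndindex(arr.shape):
                num = (loss_at(k, idx, eps) - loss_at(k, idx, -eps)) / (2 * eps)
                diff = abs(num - gk[idx])
                assert diff < 1e-8 or diff / max(abs(num), abs(gk[idx])) < 1e-4, \
                    f"gradient mismatch in {k}{idx}"


class TestRoc:
    def test_perfect_and_constant_scores(self):
        y = np.array([0, 0, 1, 1])
        assert roc(np.array([0.1, 0.2, 0.8, 0.9]), y).auc == 1.0
        assert roc(np.zeros(4), y).auc == 0.5

    def test_matches_pairwise_concordance(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.2, 0.9, 0.5])
        y = np.array([0, 0, 1, 1, 1, 0, 1, 0])
        assert roc(scores, y).auc == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(50)
        y = rng.integers(0, 2, 50)
        base = roc(scores, y).auc
        for f in (lambda s: 3 * s + 1, np.exp, lambda s: s**3):
            assert roc(f(scores), y).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(1)
        r = roc(rng.random(100), rng.integers(0, 2, 100))
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)
        assert 0.0 <= r.auc <= 1.0


class TestTraining:
    def test_separable_toy_reaches_perfect_training_auc(self):
        ds = separable_dataset()
        res = AdaptiveLogisticRegression(ds, hidden=8).fit(
            TrainConfig(seed=0, epochs=300, learning_rate=0.01)
        )
        losses = res.history["train_loss"].to_numpy()
        assert np.all(np.diff(losses[:10]) < 0), "loss should fall over first epochs"
        assert res.roc("train").auc == 1.0

    def test_identical_seed_reproduces_parameters_bitwise(self):
        ds = separable_dataset(seed=1)
        cfg = TrainConfig(seed=4, epochs=40)
        r1 = AdaptiveLogisticRegression(ds, hidden=8).fit(cfg)
        r2 = AdaptiveLogisticRegression(ds, hidden=8).fit(cfg)
        for k, v in r1.params.to_dict().items():
            assert np.array_equal(v, r2.params.to_dict()[k]), k
        assert r1.history.equals(r2.history)

    def test_single_class_training_raises(self):
        ds = separable_dataset()
        ds.targets[:] = 1
        with pytest.raises(ValueError, match="single class"):
            AdaptiveLogisticRegression(ds, hidden=4).fit(TrainConfig(epochs=5))

    def test_save_load_round_trip(self, tmp_path):
        ds = separable_dataset(seed=2)
        res = AdaptiveLogisticRegression(ds, hidden=4).fit(TrainConfig(seed=0, epochs=20))
        path = tmp_path / "model.npz"
        res.save(path)
        params, genes, cfg = load_params(path)
        assert genes == ds.gene_names
        for k, v in res.params.to_dict().items():
            assert np.array_equal(np.asarray(v), np.asarray(params.to_dict()[k])), k

    def test_summary_mentions_fit_quality(self):
        ds = separable_dataset(seed=3)
        res = AdaptiveLogisticRegression(ds, hidden=4).fit(TrainConfig(seed=0, epochs=20))
        text = res.summary()
        assert "AUC" in text and "epochs" in text


class TestStandardAnn:
    def test_zero_init_outputs_half(self):
        ds = separable_dataset()
        model = StandardANN(ds, widths=(5, 4))
        params = {k: np.zeros_like(v) for k, v in
                  model._init_params(2, np.random.default_rng(0)).items()}
        assert np.allclose(model._apply(params, ds.matrix), 0.5)

    def test_forward_matches_layerwise_reference(self):
        ds = separable_dataset()
        model = StandardANN(ds, widths=(5, 4))
        params = model._init_params(2, np.random.default_rng(1))
        x = np.array([2.0, 7.0])
        got = model._apply(params, x[None, :])[0]
        assert got == pytest.approx(selu_reference(params, (5, 4), x), abs=1e-6)

    def test_separable_toy_high_auc(self):
        ds = separable_dataset(seed=5)
        res = StandardANN(ds, widths=(16, 8)).fit(
            TrainConfig(seed=1, epochs=300, learning_rate=0.01)
        )
        assert res.roc("train").auc >= 0.99

    def test_gradients_match_finite_differences(self):
        ds = separable_dataset()
        model = StandardANN(ds, widths=(4, 3))
        params = model._init_params(2, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        X = rng.gamma(2, 2, size=(6, 2))
        y = rng.integers(0, 2, 6).astype(float)
        _, grads = model._loss_grads(params, X, y)
        eps = 1e-6
        for k in params:
            arr = params[k]
            for idx in np.ndindex(arr.shape):
                orig = arr[idx]
                arr[idx] = orig + eps
                up = bce_loss(model._apply(params, X), y)
                arr[idx] = orig - eps
                down = bce_loss(model._apply(params, X), y)
                arr[idx] = orig
                num = (up - down) / (2 * eps)
                g = grads[k][idx]
                diff = abs(num - g)
                assert diff < 1e-8 or diff / max(abs(num), abs(g)) < 1e-4
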