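import numpy as np
import pytest

from textrisk.calibration import default_calibration
from textrisk.cohort import generate_cohort
from textrisk.evaluation import roc_and_auc
from textrisk.models import (AUX_DIMS, ModelConfig, build_model, build_mtm,
                             build_partial_model, build_stm, composite_loss,
                             load_model, predict, save_model, train)
from textrisk.nn import bce_with_logits, mse_loss
from textrisk.psychometrics import (assemble_auxiliary_targets,
                                    fit_auxiliary_stats)


def _toy_config(variant="mtm", **kw):
    base = dict(variant=variant, input_dim=7, shared_layers=(6, 5),
                subnetwork_layers=(4,), dropout=0.0, seed=3)
    base.update(kw)
    return ModelConfig(**base)


def _toy_batch(rng, n=3, d=7):
    X = rng.standard_normal((n, d))
    y = (rng.random(n) > 0.5).astype(float)
    aux = {name: rng.standard_normal((n, k))
           for name, k in AUX_DIMS.items()}
    return X, y, aux


class TestArchitecture:
    def test_stm_parameter_count_by_hand(self):
        model = build_stm(ModelConfig(variant="stm", input_dim=8,
                                      shared_layers=(4,), dropout=0.0))
        assert sum(p.size for p, _ in model.params()) == 8 * 4 + 4 + 4 + 1

    def test_stm_zeroed_head_outputs_half(self, rng):
        model = build_stm(_toy_config("stm"))
        last = model.head.layers[-1]
        last.W[:] = 0.0
        last.b[:] = 0.0
        out = model.forward(rng.standard_normal((5, 7)))
        np.testing.assert_allclose(out["suicide"], 0.5)

    def test_outputs_in_unit_interval(self, rng):
        model = build_mtm(_toy_config())
        out = model.forward(rng.standard_normal((20, 7)) * 10)
        assert np.all(out["suicide"] > 0) and np.all(out["suicide"] < 1)

    def test_mtm_output_shapes(self, rng):
        model = build_mtm(_toy_config())
        out = model.forward(rng.standard_normal((5, 7)))
        assert out["personality"].shape == (5, 5)
        assert out["psychosocial"].shape == (5, 4)
        assert out["psychiatric"].shape == (5, 2)
        assert out["suicide"].shape == (5, 1)

    def test_zeroed_trunk_isolates_mediation_chain(self, rng):
        """With the shared trunk forced to zero, the psychosocial output
        depends on the input only through the personality subnetwork."""
        model = build_mtm(_toy_config())
        trunk_out = model.shared.layers[-1]
        trunk_out.W[:] = 0.0
        trunk_out.b[:] = 0.0
        X = rng.standard_normal((4, 7))
        base = model.forward(X)
        # force identical personality outputs by zeroing that subnetwork
        pers_out = model.subnets["personality"].layers[-1]
        pers_out.W[:] = 0.0
        pers_out.b[:] = 0.0
        out = model.forward(X)
        # distinct inputs now produce identical psychosocial activations
        assert np.allclose(out["psychosocial"],
                           out["psychosocial"][0:1, :])
        assert not np.allclose(base["psychosocial"],
                               base["psychosocial"][0:1, :])

    @pytest.mark.parametrize("variant,aux_dim", [
        ("partial-personality", 5),
        ("partial-psychosocial", 4),
        ("partial-psychiatric", 2),
    ])
    def test_partial_variant_shapes(self, variant, aux_dim, rng):
        model = build_partial_model(_toy_config(variant))
        out = model.forward(rng.standard_normal((3, 7)))
        layer = variant.removeprefix("partial-")
        assert out[layer].shape == (3, aux_dim)
        assert out["suicide"].shape == (3, 1)

    def test_builders_enforce_variant(self):
        with pytest.raises(ValueError):
            build_stm(_toy_config("mtm"))
        with pytest.raises(ValueError):
            build_mtm(_toy_config("stm"))
        with pytest.raises(ValueError):
            build_partial_model(_toy_config("mtm"))

    def test_dimension_mismatch_rejected(self, rng):
        model = build_mtm(_toy_config())
        with pytest.raises(ValueError, match="dimension"):
            model.forward(rng.standard_normal((3, 9)))


class TestCompositeLoss:
    def test_reduces_to_stm_loss_without_aux_weights(self, rng):
        X, y, aux = _toy_batch(rng)
        model = build_mtm(_toy_config())
        out = model.forward(X)
        weights = {"suicide": 1.0, "personality": 0.0, "psychosocial": 0.0,
                   "psychiatric": 0.0}
        total = composite_loss(out, {"suicide": y, **aux}, weights)
        bce, _ = bce_with_logits(out["logit"], y)
        assert total == pytest.approx(bce)

    def test_perfect_auxiliary_predictions_add_nothing(self, rng):
        X, y, _ = _toy_batch(rng)
        model = build_mtm(_toy_config())
        out = model.forward(X)
        aux_truth = {k: out[k] for k in AUX_DIMS}
        weights = {k: 1.0 for k in ("suicide", *AUX_DIMS)}
        total = composite_loss(out, {"suicide": y, **aux_truth}, weights)
        bce, _ = bce_with_logits(out["logit"], y)
        assert total == pytest.approx(bce)

    def test_hand_computed_single_example(self):
        out = {"logit": np.array([[0.0]]),
               "psychiatric": np.array([[1.0, -1.0]])}
        targets = {"suicide": np.array([1.0]),
                   "psychiatric": np.array([[0.0, 0.0]])}
        weights = {"suicide": 2.0, "psychiatric": 0.5}
        # BCE at logit 0 is log 2; MSE of (1, -1) vs 0 is 1
        expected = 2.0 * np.log(2.0) + 0.5 * 1.0
        assert composite_loss(out, targets, weights) == \
            pytest.approx(expected)

    def test_gradient_check_against_finite_differences(self, rng):
        """Analytic gradients of the composite loss match central
        differences to < 1e-4 relative error on a 3-example batch."""
        for variant in ("mtm", "partial-psychiatric", "stm"):
            model = build_model(_toy_config(variant))
            X, y, aux = _toy_batch(rng)
            model.loss_and_backward(X, y, aux, train=False)
            grads = [g.copy() for _, g in model.params()]
            eps = 1e-6
            for (p, _), g in zip(model.params(), grads):
                ix = tuple(rng.integers(0, s) for s in p.shape)
                orig = p[ix]
                p[ix] = orig + eps
                lp = model.loss_and_backward(X, y, aux, train=False)
                p[ix] = orig - eps
                lm = model.loss_and_backward(X, y, aux, train=False)
                p[ix] = orig
                fd = (lp - lm) / (2 * eps)
                rel = abs(fd - g[ix]) / max(abs(fd) + abs(g[ix]), 1e-8)
                assert rel < 1e-4, (variant, ix)

    def test_mse_gradient_shape(self, rng):
        pred = rng.standard_normal((4, 3))
        loss, grad = mse_loss(pred, np.zeros((4, 3)))
        assert loss == pytest.approx((pred ** 2).mean())
        np.testing.assert_allclose(grad, 2 * pred / pred.size)


class TestTraining:
    def _mediated_data(self, signal, seed=0, n=300, d=24):
        cal = default_calibration(signal_strength=signal)
        cohort = generate_cohort(cal, n, seed=seed, mode="oracle",
                                 embed_dim=d)
        X, y = cohort.embeddings, cohort.labels("general").astype(float)
        stats = fit_auxiliary_stats(cohort.scores[:200])
        aux = assemble_auxiliary_targets(cohort.scores, stats).as_dict()
        return X, y, aux

    def test_separable_data_learned(self):
        X, y, aux = self._mediated_data(signal=5.0, n=400)
        cfg = ModelConfig(variant="stm", input_dim=X.shape[1],
                          max_epochs=40, patience=10, seed=0)
        trained = train(build_model(cfg), X[:300], y[:300], X[300:], y[300:])
        scores = trained.predict(X[:300])["suicide"].ravel()
        _, auc = roc_and_auc(scores, y[:300])
        assert auc > 0.95

    def test_null_data_stays_at_chance(self):
        X, y, aux = self._mediated_data(signal=0.0, n=400)
        cfg = ModelConfig(variant="stm", input_dim=X.shape[1],
                          max_epochs=15, patience=5, seed=0)
        trained = train(build_model(cfg), X[:300], y[:300], X[300:], y[300:])
        scores = trained.predict(X[300:])["suicide"].ravel()
        _, auc = roc_and_auc(scores, y[300:])
        assert abs(auc - 0.5) < 0.18   # 100 dev users: wide sampling band

    def test_training_deterministic(self):
        X, y, aux = self._mediated_data(signal=1.0)
        cfg = ModelConfig(variant="mtm", input_dim=X.shape[1],
                          max_epochs=8, patience=8, seed=5)
        runs = []
        for _ in range(2):
            trained = train(build_model(cfg), X[:200], y[:200], X[200:],
                            y[200:], aux_train={k: v[:200]
                                                for k, v in aux.items()})
            runs.append([h["dev_auc"] for h in trained.history])
        assert runs[0] == runs[1]

    def test_loss_decreases_on_noiseless_toy(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((64, 5))
        w = np.array([2.0, -1.0, 0.5, 0.0, 1.0])
        y = (X @ w > 0).astype(float)
        cfg = ModelConfig(variant="stm", input_dim=5, shared_layers=(8,),
                          dropout=0.0, learning_rate=1e-3, batch_size=64,
                          max_epochs=30, patience=30, seed=2)
        trained = train(build_model(cfg), X, y, X, y)
        losses = [h["train_loss"] for h in trained.history]
        diffs = np.diff(losses)
        assert losses[-1] < losses[0]
        assert np.all(diffs < 1e-3)   # full-batch: essentially monotone

    def test_mtm_requires_aux_targets(self):
        X, y, _ = self._mediated_data(signal=1.0)
        cfg = ModelConfig(variant="mtm", input_dim=X.shape[1])
        with pytest.raises(ValueError, match="auxiliary"):
            train(build_model(cfg), X[:200], y[:200], X[200:], y[200:])


class TestPredict:
    def test_duplicate_rows_duplicate_outputs(self, rng):
        model = build_mtm(_toy_config())
        x = rng.standard_normal((1, 7))
        out = predict(model, np.vstack([x, x, x]))
        assert np.allclose(out["suicide"], out["suicide"][0])

    def test_batch_partition_invariant(self, rng):
        model = build_mtm(_toy_config())
        X = rng.standard_normal((10, 7))
        full = predict(model, X)["suicide"]
        parts = np.vstack([predict(model, X[:4])["suicide"],
                           predict(model, X[4:])["suicide"]])
        np.testing.assert_allclose(full, parts, atol=1e-12)

    def test_probability_is_sigmoid_of_logit(self, rng):
        model = build_stm(_toy_config("stm"))
        out = predict(model, rng.standard_normal((6, 7)))
        np.testing.assert_allclose(
            out["suicide"], 1.0 / (1.0 + np.exp(-out["logit"])), atol=1e-6)


def test_checkpoint_round_trip(tmp_path, rng):
    X = rng.standard_normal((40, 7))
    y = (rng.random(40) > 0.6).astype(float)
    aux = {k: rng.standard_normal((40, d)) for k, d in AUX_DIMS.items()}
    cfg = _toy_config(max_epochs=3, patience=3)
    trained = train(build_model(cfg), X, y, X, y, aux_train=aux)
    path = tmp_path / "model.npz"
    save_model(trained, path)
    loaded = load_model(path)
    np.testing.assert_allclose(loaded.predict(X)["suicide"],
                               trained.predict(X)["suicide"], atol=1e-12)
    assert loaded.best_epoch == trained.best_epoch
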