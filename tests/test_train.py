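"""Loss closed forms, class weighting, optimizer behaviour, early stopping."""

import numpy as np
import pytest

from ordvit import (
    AugConfig,
    ModelConfig,
    SeverityParams,
    TrainConfig,
    class_weights,
    combined_loss,
    make_records,
    multi_seed_run,
    train_model,
)
from ordvit.autograd import Tensor
from ordvit.model import build_model, forward_batch
from ordvit.train import AdamW, batch_loss


class TestClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        np.testing.assert_allclose(class_weights([0, 1, 2, 3] * 5), np.ones(4))

    def test_inverse_frequency_closed_form(self):
        # counts (4,2,1,1), N=8 -> N/(4*n_c) = (0.5, 1, 2, 2)
        labels = [0] * 4 + [1] * 2 + [2, 3]
        np.testing.assert_allclose(class_weights(labels), [0.5, 1.0, 2.0, 2.0])

    def test_weights_average_to_one_under_class_frequencies(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 200)
        w = class_weights(labels)
        counts = np.bincount(labels, minlength=4)
        assert np.isclose((w * counts).sum() / len(labels), 1.0)

    def test_empty_class_raises_naming_it(self):
        with pytest.raises(ValueError, match="class 2"):
            class_weights([0, 1, 3])


class TestCombinedLoss:
    def test_perfect_prediction_is_zero(self):
        probs = np.array([0.0, 0.0, 0.0, 1.0])
        assert combined_loss(probs, risk_score=1.0, label=3) == 0.0

    def test_uniform_probs_pure_ce_is_ln4(self):
        probs = np.full(4, 0.25)
        loss = combined_loss(probs, risk_score=0.0, label=0, lambda_reg=0.0)
        assert np.isclose(loss, np.log(4.0))

    def test_mse_term_arithmetic(self):
        # label 3 (target 1), risk 0.5, lambda 1 -> adds (0.5 - 1)^2 = 0.25
        probs = np.array([0.0, 0.0, 0.0, 1.0])
        loss = combined_loss(probs, risk_score=0.5, label=3, lambda_reg=1.0)
        assert np.isclose(loss, 0.25)

    def test_zero_probability_clamped_not_raising(self):
        probs = np.array([1.0, 0.0, 0.0, 0.0])
        loss = combined_loss(probs, risk_score=0.0, label=1, lambda_reg=0.0)
        assert np.isclose(loss, -np.log(1e-12))

    def test_class_weight_scales_ce_only(self):
        probs = np.full(4, 0.25)
        a = combined_loss(probs, 0.5, label=0, lambda_reg=1.0, weight=2.0)
        assert np.isclose(a, 2.0 * np.log(4.0) + 0.25)

    def test_batch_loss_matches_probability_space_form(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(5, 4))
        risk = rng.random(5)
        labels = rng.integers(0, 4, 5)
        w = class_weights([0, 1, 2, 3])
        got = float(batch_loss(Tensor(logits), Tensor(risk), labels, 0.5, w).data)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        want = np.mean(
            [combined_loss(probs[i], risk[i], labels[i], 0.5, w[labels[i]]) for i in range(5)]
        )
        assert np.isclose(got, want)


class TestOptimization:
    def test_one_adamw_step_decreases_single_example_loss(self, micro_config):
        model = build_model(micro_config, seed=1)
        rng = np.random.default_rng(0)
        img = rng.random((1, 16, 16, 3))
        labels = np.array([2])
        w = np.ones(4)

        def loss():
            lo, ri = forward_batch(img, model, train_mode=False)
            return batch_loss(lo, ri, labels, 0.5, w)

        before = loss()
        model.zero_grad()
        before.backward()
        AdamW(model.parameters(), lr=1e-4, weight_decay=0.0).step()
        assert float(loss().data) < float(before.data)


@pytest.fixture(scope="module")
def nano_setup():
    """Very small dataset + model for training-loop contract tests."""
    params = SeverityParams(n_per_class=6, image_size=16, seed=2)
    recs = make_records(params)
    train = [r for i, r in enumerate(recs) if i % 3 != 2]
    val = [r for i, r in enumerate(recs) if i % 3 == 2]
    cfg = ModelConfig(
        image_size=16, patch_size=8, embed_dim=16, depth=1, n_heads=2,
        ffn_dim=24, sfl_heads=2, sfl_hidden=12, sfl_out=8,
    )
    tc = TrainConfig(max_epochs=4, batch_size=8, patience=2, augment=AugConfig(enabled=False))
    return cfg, tc, train, val


class TestTrainLoop:
    def test_fixed_seed_reproduces_history_exactly(self, nano_setup):
        cfg, tc, train, val = nano_setup
        _, h1 = train_model(cfg, tc, train, val, seed=5)
        _, h2 = train_model(cfg, tc, train, val, seed=5)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss
        assert h1.best_epoch == h2.best_epoch

    def test_best_epoch_attains_minimum_val_loss(self, nano_setup):
        cfg, tc, train, val = nano_setup
        _, hist = train_model(cfg, tc, train, val, seed=6)
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_early_stopping_halts_after_patience(self, nano_setup):
        cfg, _, train, val = nano_setup
        tc = TrainConfig(max_epochs=50, batch_size=8, patience=1,
                         lr=10.0, augment=AugConfig(enabled=False))
        # absurd lr forces non-improving validation quickly; loop must stop early
        _, hist = train_model(cfg, tc, train, val, seed=7)
        assert hist.stopped_early
        assert hist.n_epochs < 50
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_empty_split_rejected(self, nano_setup):
        cfg, tc, train, _ = nano_setup
        with pytest.raises(ValueError):
            train_model(cfg, tc, train, [], seed=0)


def test_lambda_grid_reports_all_candidates_and_best(nano_setup):
    from ordvit import lambda_grid

    cfg, tc, train, val = nano_setup
    out = lambda_grid(cfg, tc, train, val, lambdas=(0.1, 0.5), seed=1)
    assert set(out["val_accuracy"]) == {0.1, 0.5}
    assert out["best_lambda"] in (0.1, 0.5)
    assert out["val_accuracy"][out["best_lambda"]] == max(out["val_accuracy"].values())


class TestMultiSeed:
    def test_single_seed_mean_equals_that_run(self, nano_setup):
        cfg, tc, train, val = nano_setup
        out = multi_seed_run(cfg, tc, train, val, val, seeds=(3,))
        assert out["mean"]["accuracy"] == out["per_seed"][3]["accuracy"]
        assert not out["partial"]

    def test_mean_is_arithmetic_mean_of_seeds(self, nano_setup):
        cfg, tc, train, val = nano_setup
        out = multi_seed_run(cfg, tc, train, val, val, seeds=(3, 4))
        want = np.mean([out["per_seed"][s]["accuracy"] for s in (3, 4)])
        assert np.isclose(out["mean"]["accuracy"], want)
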