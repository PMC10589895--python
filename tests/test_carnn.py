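"""Network forward pass, loss, gradients and training-progress properties."""

import numpy as np
import pytest

from gridtorus import carnn
from gridtorus.carnn import (TrainConfig, decoding_error, forward, init_model,
                             kl_divergence, loss)
from gridtorus.placecode import encode_position, make_ensemble


def test_xavier_bounds_and_determinism():
    m1 = init_model(512, 4096, seed=0)
    m2 = init_model(512, 4096, seed=0)
    np.testing.assert_array_equal(m1.Wg, m2.Wg)
    bound = np.sqrt(6.0 / (2 * 4096))
    assert np.abs(m1.Wg).max() <= bound
    # empirical variance of We matches the uniform law var = 2/(fan_in+fan_out)
    expected = 2.0 / (512 + 4096)
    assert m1.We.var() == pytest.approx(expected, rel=0.05)


def test_forward_zero_weights_gives_uniform():
    m = init_model(8, 5, seed=1)
    m.We[:] = 0; m.Wg[:] = 0; m.Wv[:] = 0; m.Wd[:] = 0
    preds = forward(m, np.full((2, 8), 1 / 8), np.zeros((2, 4, 2)))
    np.testing.assert_allclose(preds, 1 / 8)


def test_forward_matches_hand_rolled_recurrence():
    # 2 units, 2 place cells, hand-checkable weights
    m = carnn.ModelParams(
        We=np.array([[1.0, 0.0], [0.0, 1.0]]),
        Wg=np.array([[0.5, 0.0], [0.0, -1.0]]),
        Wv=np.array([[1.0, 0.0], [0.0, 1.0]]),
        Wd=np.array([[1.0, 0.0], [0.0, 1.0]]),
    )
    p0 = np.array([[0.6, 0.4]])
    v = np.array([[[0.2, -0.1], [0.0, 0.3]]])
    preds, g, _ = forward(m, p0, v, return_states=True)
    # hand recurrence
    g0 = p0[0]
    g1 = np.maximum([0.5 * 0.6 + 0.2, -1.0 * 0.4 + (-0.1)], 0)
    g2 = np.maximum([0.5 * g1[0] + 0.0, -1.0 * g1[1] + 0.3], 0)
    np.testing.assert_allclose(g[0, 1], g1)
    np.testing.assert_allclose(g[0, 2], g2)
    ez = np.exp(g2 - g2.max())
    np.testing.assert_allclose(preds[0, 1], ez / ez.sum())


def test_relu_silences_inhibited_unit():
    m = init_model(4, 3, seed=2)
    m.We[:] = 0.0
    m.Wg[0, :] = -1.0        # unit 0: all-negative incoming recurrent weights
    m.Wv[0, :] = -1.0
    v = np.abs(np.random.default_rng(0).normal(size=(1, 6, 2)))
    _, g, _ = forward(m, np.full((1, 4), 0.25), v, return_states=True)
    assert np.all(g[0, 1:, 0] == 0)


def test_predictions_are_distributions(arena):
    ens = make_ensemble(arena, 16, seed=3)
    m = init_model(16, 32, seed=4)
    rng = np.random.default_rng(5)
    p0 = encode_position(rng.uniform(-1, 1, (7, 2)), ens)
    preds = forward(m, p0, rng.normal(0, 0.5, (7, 20, 2)))
    np.testing.assert_allclose(preds.sum(-1), 1.0, atol=1e-9)
    assert preds.min() >= 0


def test_loss_uniform_cross_entropy_and_penalty_scaling():
    n_place = 10
    uni = np.full((1, 3, n_place), 1 / n_place)
    Wg = np.random.default_rng(6).normal(size=(4, 4))
    base = loss(uni, uni, np.zeros((4, 4)), 1e-4)
    assert base == pytest.approx(np.log(n_place))
    l1 = loss(uni, uni, Wg, 1e-4) - base
    l2 = loss(uni, uni, 2 * Wg, 1e-4) - base
    assert l2 == pytest.approx(4 * l1)


def test_loss_hand_example():
    # 2 cells, 2 steps: L = -(1/2) sum_t sum_i p ln phat
    labels = np.array([[[0.7, 0.3], [0.2, 0.8]]])
    preds = np.array([[[0.6, 0.4], [0.5, 0.5]]])
    expected = -(0.7 * np.log(0.6) + 0.3 * np.log(0.4)
                 + 0.2 * np.log(0.5) + 0.8 * np.log(0.5)) / 2
    assert loss(preds, labels, np.zeros((2, 2)), 0.0) == pytest.approx(expected)


def test_kl_properties_and_hand_value():
    p = np.array([0.25, 0.25, 0.25, 0.25])
    q = np.array([0.85, 0.05, 0.05, 0.05])
    assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
    hand = np.sum(p * np.log(p / q))
    assert kl_divergence(p, q) == pytest.approx(hand)
    # decomposition: KL = cross-entropy - entropy
    ce = -np.sum(p * np.log(q))
    ent = -np.sum(p * np.log(p))
    assert kl_divergence(p, q) == pytest.approx(ce - ent)
    assert kl_divergence(p, q) >= 0


def test_gradients_match_finite_differences(arena):
    m = init_model(4, 6, seed=8)
    ens = make_ensemble(arena, 4, seed=9)
    rng = np.random.default_rng(10)
    p0 = encode_position(rng.uniform(-1, 1, (3, 2)), ens)
    v = rng.normal(0, 0.5, (3, 5, 2))
    labels = rng.dirichlet(np.ones(4), size=(3, 5))
    _, grads, _ = carnn._gradients(m, p0, v, labels, 1e-4)
    eps = 1e-6
    for name in ("We", "Wg", "Wv", "Wd"):
        W = getattr(m, name)
        for (i, j) in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
            orig = W[i, j]
            W[i, j] = orig + eps
            lp = loss(forward(m, p0, v), labels, m.Wg, 1e-4)
            W[i, j] = orig - eps
            lm = loss(forward(m, p0, v), labels, m.Wg, 1e-4)
            W[i, j] = orig
            assert grads[name][i, j] == pytest.approx((lp - lm) / (2 * eps),
                                                      abs=1e-5)


def test_decoding_error_shape_and_oracle(arena):
    ens = make_ensemble(arena, 16, seed=11)
    m = init_model(16, 8, seed=12)
    rng = np.random.default_rng(13)
    p0 = encode_position(rng.uniform(-1, 1, (5, 2)), ens)
    v = rng.normal(0, 0.5, (5, 20, 2))
    labels = forward(m, p0, v)       # oracle: labels equal the predictions
    err = decoding_error(m, p0, v, labels, ens)
    assert err.shape == (20,)
    np.testing.assert_allclose(err, 0.0, atol=1e-12)


def test_non_finite_state_aborts_with_step_index():
    m = init_model(4, 3, seed=14)
    m.Wg[:] = 1e200
    m.Wv[:] = 1e200
    with pytest.raises(FloatingPointError, match="step"):
        forward(m, np.full((1, 4), 0.25), np.ones((1, 5, 2)) * 1e200)


def test_training_reduces_kl_and_decoding_error(desk_training):
    """Scaled-down multi-environment training run: loss metrics improve."""
    log = desk_training["log"]
    assert log.kl[-1] < log.kl[0]
    # familiar-environment decoding error at t=T drops below untrained level
    assert np.mean(log.decode_err[-1]) < np.mean(log.decode_err[0])


def test_continual_schedule_runs_and_logs(arena, motion, environments):
    envs, _ = environments
    model = carnn.init_model(64, 32, seed=15)
    cfg = TrainConfig(learning_rate=1e-3, minibatches_per_env=5, n_envs=3,
                      schedule="continual", seed=16, log_every=5,
                      batch_size=20, eval_batch_size=20)
    model, log = carnn.train(model, cfg, envs, arena=arena, motion=motion)
    assert len(log.env_schedule) == 15
    # block structure: env 0 for the first 5 steps, env 2 for the last 5
    assert log.env_schedule[:5] == [0] * 5
    assert log.env_schedule[-5:] == [2] * 5
    assert np.isfinite(log.kl).all()
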