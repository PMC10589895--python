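"""Unit inactivation contracts and pruning-curve behaviour."""

import numpy as np
import pytest

from gridtorus import carnn
from gridtorus.placecode import encode_position, make_ensemble
from gridtorus.pruning import (PruningPlan, prune_units, pruning_curve,
                               pruning_time_course, select_top_grid)
from gridtorus.synthgrid import eval_grid_cell, sample_unit_cell


@pytest.fixture()
def small_model():
    return carnn.init_model(16, 24, seed=0)


@pytest.fixture()
def small_env(arena):
    return make_ensemble(arena, 16, seed=1)


def _batch(arena, env, n=20, T=10, seed=2):
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-1, 1, (n, 2))
    v = rng.normal(0, 0.5, (n, T, 2))
    return encode_position(x0, env), v


def test_pruned_unit_is_silent(small_model, arena, small_env):
    p0, v = _batch(arena, small_env)
    pruned = prune_units(small_model, [3, 7])
    _, g, _ = carnn.forward(pruned, p0, v, return_states=True)
    assert np.all(g[:, 1:, [3, 7]] == 0)
    # original model untouched
    assert np.any(small_model.Wg[3] != 0)


def test_prune_empty_is_identity_and_all_is_uniform(small_model, arena,
                                                    small_env):
    p0, v = _batch(arena, small_env)
    same = prune_units(small_model, [])
    np.testing.assert_array_equal(carnn.forward(same, p0, v),
                                  carnn.forward(small_model, p0, v))
    everything = prune_units(small_model, np.arange(24))
    preds = carnn.forward(everything, p0, v)
    np.testing.assert_allclose(preds, 1 / 16)


def test_prune_validates_indices(small_model):
    with pytest.raises(IndexError):
        prune_units(small_model, [99])
    with pytest.raises(ValueError):
        prune_units(small_model, [1, 1])


def test_select_top_grid_recovers_planted_grid_units(arena, monkeypatch):
    """Units 0-9 carry ideal hexagonal patterns among noise units; the
    cumulative grid-score ranking finds exactly them."""
    n_units, n_place = 30, 16
    env = make_ensemble(arena, n_place, seed=3)
    model = carnn.init_model(n_place, n_units, seed=4)
    rng = np.random.default_rng(5)
    phases = sample_unit_cell(1 / 0.838, 10, rng)

    def planted_activities(model_, ensembles, n_traj=2000, seed=0,
                           arena=None, motion=None):
        from gridtorus.trajectories import MotionParams, generate_batch_fast

        motion = motion or MotionParams()
        g_rng = np.random.default_rng(seed)
        for ens in ensembles:
            walk = generate_batch_fast(ens.arena, motion, n_traj, g_rng)
            g = g_rng.uniform(0, 0.3, size=(n_traj, motion.n_steps, n_units))
            for u in range(10):
                g[..., u] = eval_grid_cell(1 / 0.838, 0.2, phases[u],
                                           walk.positions)
            yield ens, walk, g

    import gridtorus.pruning as pruning_mod

    monkeypatch.setattr(pruning_mod, "unit_activities", planted_activities)
    top = select_top_grid(model, [env], n=10, n_traj=1500, seed=6)
    assert set(top) == set(range(10))


def test_pruning_curve_anchor_and_mad(small_model, arena, small_env):
    plan = PruningPlan(step=8, repeats=1, eval_timestep=5, batch_size=12,
                       seed=7)
    from gridtorus.trajectories import MotionParams

    motion = MotionParams(n_steps=5)
    curve = pruning_curve(small_model, plan, [small_env], motion=motion)
    assert curve.n_pruned[0] == 0
    assert np.all(curve.mad == 0)          # single repeat
    assert np.all(curve.median >= 0)
    # the n=0 anchor equals the unpruned model's error for the same batches
    curve2 = pruning_curve(small_model, plan, [small_env], motion=motion)
    assert curve.median[0] == pytest.approx(curve2.median[0])


def test_pruning_curve_truncates_to_target_set(small_model, arena, small_env):
    plan = PruningPlan(step=4, repeats=1, eval_timestep=3, batch_size=6,
                       seed=8)
    from gridtorus.trajectories import MotionParams

    curve = pruning_curve(small_model, plan, [small_env],
                          target_units=np.arange(9), strategy="ensemble",
                          motion=MotionParams(n_steps=3))
    assert curve.n_pruned[-1] == 8         # truncated below the set size


def test_time_course_shape_and_determinism(small_model, arena, small_env):
    from gridtorus.trajectories import MotionParams

    motion = MotionParams(n_steps=8)
    plan = PruningPlan(repeats=2, batch_size=12, seed=9)
    tc = pruning_time_course(small_model, plan, [small_env],
                             n_fixed=6, motion=motion)
    assert len(tc.median) == 8
    assert np.all(tc.median >= 0)
    tc2 = pruning_time_course(small_model, plan, [small_env],
                              n_fixed=6, motion=motion)
    np.testing.assert_allclose(tc.median, tc2.median)


def test_trained_model_anchor_shared_across_strategies(desk_training, motion):
    """The n=0 point of a pruning curve is the unpruned model's error and is
    identical whatever target set the strategy will draw from."""
    model = desk_training["model"]
    envs = desk_training["envs"]
    plan = PruningPlan(step=64, repeats=3, seed=10)
    rand = pruning_curve(model, plan, envs, strategy="random", motion=motion)
    subset = pruning_curve(model, plan, envs,
                           target_units=np.arange(128),
                           strategy="ensemble", motion=motion)
    np.testing.assert_allclose(rand.per_repeat[:, 0], subset.per_repeat[:, 0])
    assert np.isfinite(rand.median).all() and np.all(rand.median >= 0)
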