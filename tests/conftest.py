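"""Shared fixtures.

The expensive artifacts — the desk-scale trained network and its unit-type
analysis — are built once per session and shared by the training, pruning
and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from gridtorus import carnn
from gridtorus.placecode import make_ensemble, remap
from gridtorus.trajectories import ArenaSpec, MotionParams

# desk-scale study conditions: 256 recurrent units, 64 place cells, three
# environments, ~2000 minibatches total (667 per environment)
DESK_NG = 256
DESK_NP = 64
DESK_STEPS_PER_ENV = 667
DESK_LR = 3e-3


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture(scope="session")
def motion() -> MotionParams:
    return MotionParams()


@pytest.fixture(scope="session")
def environments(arena):
    """Three familiar place-cell ensembles plus one held-out novel one."""
    base = make_ensemble(arena, DESK_NP, seed=100)
    envs = [base,
            remap(base, seed=101, environment_id=1),
            remap(base, seed=102, environment_id=2)]
    novel = remap(base, seed=103, environment_id=3)
    return envs, novel


@pytest.fixture(scope="session")
def desk_training(arena, motion, environments):
    """Desk-scale model trained in three environments, with its log and the
    untrained twin for reference."""
    envs, novel = environments
    model = carnn.init_model(DESK_NP, DESK_NG, seed=7)
    untrained = model.copy()
    cfg = carnn.TrainConfig(learning_rate=DESK_LR,
                            minibatches_per_env=DESK_STEPS_PER_ENV,
                            n_envs=3, seed=11, log_every=500)
    model, log = carnn.train(model, cfg, envs, arena=arena, motion=motion,
                             novel_ensemble=novel)
    return {"model": model, "untrained": untrained, "log": log,
            "config": cfg, "envs": envs, "novel": novel}


@pytest.fixture(scope="session")
def desk_analysis(desk_training, arena, motion):
    """Ratemaps, rotational fingerprints, clustering and the torus ensemble
    of the trained desk model."""
    from gridtorus import ensembles as ens_mod
    from gridtorus.pruning import unit_activities
    from gridtorus.spatialmetrics import compute_ratemaps_stack

    model = desk_training["model"]
    envs = desk_training["envs"]
    per_env_maps = []
    for ens, walk, g in unit_activities(model, envs, n_traj=2000, seed=500,
                                        motion=motion):
        maps = compute_ratemaps_stack(g, walk.positions, arena, n_bins=32,
                                      t_slice=slice(10, None),
                                      environment_id=ens.environment_id)
        per_env_maps.append(np.stack([m.values for m in maps]))

    reasons = ens_mod.exclude_units(per_env_maps[0])
    included = np.array([u for u in range(model.n_units) if u not in reasons])
    rotacgs = np.stack([
        ens_mod.rotational_autocorrelogram(per_env_maps[0][u]).values
        for u in included])
    assignment = ens_mod.cluster_units(rotacgs, seed=42)
    band_labels = ens_mod.band_like_clusters(rotacgs, assignment.labels)
    torus_units = included[np.isin(assignment.labels, band_labels)]
    return {"per_env_maps": per_env_maps, "included": included,
            "rotacgs": rotacgs, "assignment": assignment,
            "band_labels": band_labels, "torus_units": torus_units,
            "excluded": reasons}
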