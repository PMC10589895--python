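"""End-to-end experiment orchestration.

``run_experiment`` chains the full study: simulate trajectories, encode them
with globally-remapping place-cell ensembles, train the path-integration
network, characterise the learned units (grid score), cluster them by
rotational symmetry, probe the population manifold with persistent homology,
and quantify ensemble contributions by pruning.  Every stage is seeded from
the experiment seed so a rerun with the same config reproduces the summary.

Two scale presets exist: ``paper`` (4096 units, 512 place cells, 1e5
minibatches per environment) and ``desk`` (256 units, 64 place cells, 2000
minibatches total) — the desk preset is what the test-suite and a laptop can
run; the paper preset is the full-scale configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import carnn, ensembles as ens_mod, pruning, stats
from .placecode import make_ensemble, remap
from .spatialmetrics import compute_ratemaps_stack, grid_score
from .trajectories import ArenaSpec, MotionParams

__all__ = ["ExperimentConfig", "run_experiment", "many_env_smoke",
           "DESK_PRESET", "PAPER_PRESET"]


@dataclass
class ExperimentConfig:
    preset: str = "desk"
    seed: int = 0
    n_envs: int = 3
    n_units: int = 256
    n_place: int = 64
    minibatches_per_env: int = 667     # ~2000 total at 3 envs
    learning_rate: float = 3e-3
    schedule: str = "multi_env"
    side_length: float = 2.2
    soft_margin: float = 0.03
    n_traj_ratemaps: int = 2000
    ratemap_bins: int = 32
    nperm: int = 300
    n_keep: int = 3000
    fuzzy_k: int = 200
    prune_step: int = 10
    prune_repeats: int = 5
    out_dir: str | None = None

    @classmethod
    def desk(cls, **kw) -> "ExperimentConfig":
        return cls(**kw)

    @classmethod
    def paper(cls, **kw) -> "ExperimentConfig":
        defaults = dict(preset="paper", n_units=4096, n_place=512,
                        minibatches_per_env=100_000, learning_rate=1e-4,
                        n_traj_ratemaps=10_000, nperm=500, n_keep=3000,
                        fuzzy_k=1000, prune_repeats=30)
        defaults.update(kw)
        return cls(**defaults)


DESK_PRESET = ExperimentConfig.desk
PAPER_PRESET = ExperimentConfig.paper


def _save(out_dir: Path | None, name: str, obj) -> None:
    if out_dir is None:
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / name, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_experiment(config: ExperimentConfig, train_model: bool = True) -> dict:
    """Execute the full pipeline; returns a machine-readable summary dict.

    With ``train_model=False`` the training stage is skipped and analyses
    run on the untrained network (useful as a fast structural smoke test).
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    summary: dict = {"config": asdict(config)}
    arena = ArenaSpec(config.side_length, config.soft_margin)
    motion = MotionParams()
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=16)

    stage = "environments"
    try:
        base = make_ensemble(arena, config.n_place, seed=int(seeds[0]),
                             environment_id=0)
        envs = [base]
        for e in range(1, config.n_envs):
            envs.append(remap(base, seed=int(seeds[e]), environment_id=e))
        novel = remap(base, seed=int(seeds[config.n_envs]),
                      environment_id=config.n_envs)

        stage = "train"
        model = carnn.init_model(config.n_place, config.n_units,
                                 seed=int(seeds[10]))
        untrained = model.copy()
        if train_model:
            tcfg = carnn.TrainConfig(
                learning_rate=config.learning_rate,
                minibatches_per_env=config.minibatches_per_env,
                schedule=config.schedule, n_envs=config.n_envs,
                seed=int(seeds[11]))
            model, log = carnn.train(model, tcfg, envs, arena=arena,
                                     motion=motion, novel_ensemble=novel)
            summary["training"] = {
                "kl_initial": log.kl[0], "kl_final": log.kl[-1],
                "decode_err_initial": log.decode_err[0],
                "decode_err_final": log.decode_err[-1],
                "decode_err_novel_final": log.decode_err_novel[-1],
            }
            if out_dir is not None:
                out_dir.mkdir(parents=True, exist_ok=True)
                log.to_csv(out_dir / "training_log.csv")
                carnn.save_model(out_dir / "model.npz", model, tcfg)

        stage = "ratemaps"
        per_env_maps = []        # (n_units, bins, bins) per environment
        per_env_pos = []
        for ens, walk, g in pruning.unit_activities(
                model, envs, n_traj=config.n_traj_ratemaps,
                seed=int(seeds[12]), motion=motion):
            maps = compute_ratemaps_stack(
                g, walk.positions, arena, n_bins=config.ratemap_bins,
                t_slice=slice(10, None), environment_id=ens.environment_id)
            per_env_maps.append(np.stack([m.values for m in maps]))
            per_env_pos.append(walk.positions)

        stage = "grid_scores"
        scores = np.zeros(config.n_units)
        for stack in per_env_maps:
            scores += np.nan_to_num(
                np.array([grid_score(m) for m in stack]))
        summary["grid_score"] = {
            "max_cumulative": float(scores.max()),
            "mean_cumulative": float(scores.mean()),
        }

        stage = "clustering"
        reasons = ens_mod.exclude_units(per_env_maps[0])
        included = np.array([u for u in range(config.n_units)
                             if u not in reasons])
        rotacgs = np.stack([
            ens_mod.rotational_autocorrelogram(per_env_maps[0][u]).values
            for u in included])
        assignment = ens_mod.cluster_units(rotacgs,
                                           seed=int(seeds[13]) % 2**31)
        labels = assignment.labels
        band_labels = ens_mod.band_like_clusters(rotacgs, labels)
        torus_units = included[np.isin(labels, band_labels)]
        summary["clustering"] = {
            "n_excluded": len(reasons),
            "n_clusters": int(len(set(labels) - {-1})),
            "band_like_clusters": band_labels,
            "torus_ensemble_size": int(len(torus_units)),
        }

        stage = "topology"
        cloud_units = torus_units if len(torus_units) >= 6 else included
        stack = per_env_maps[0][cloud_units]
        cloud = ens_mod.pca_project(stack.reshape(len(cloud_units), -1).T)
        keep = ens_mod.fuzzy_downsample(cloud, k=config.fuzzy_k,
                                        n_keep=config.n_keep)
        diagram = ens_mod.persistence(cloud[keep], nperm=config.nperm,
                                      simplex_budget=1e6)
        verdict = ens_mod.detect_torus(diagram)
        summary["topology"] = {
            "units_used": int(len(cloud_units)),
            "is_torus": bool(verdict["is_torus"]),
            "betti_counts": list(verdict["betti_counts"]),
        }
        if out_dir is not None:
            _save(out_dir, "persistence.json", diagram.to_json_obj())

        stage = "overlap"
        if len(torus_units):
            top_grid = pruning.select_top_grid(
                model, envs, n=len(torus_units), seed=int(seeds[14]))
            x = len(np.intersect1d(torus_units, top_grid))
            test = stats.overlap_test(config.n_units, len(torus_units),
                                      len(torus_units), x)
            summary["overlap"] = {
                "observed": x, "p_binomial": test.p_binomial,
                "p_hypergeometric": test.p_hypergeometric,
            }

        stage = "pruning"
        plan = pruning.PruningPlan(step=config.prune_step,
                                   repeats=config.prune_repeats,
                                   seed=int(seeds[15]))
        curves = {}
        curves["random"] = pruning.pruning_curve(
            model, plan, envs, strategy="random", motion=motion)
        if len(torus_units) >= plan.step:
            curves["torus"] = pruning.pruning_curve(
                model, plan, envs, target_units=torus_units,
                strategy="torus", motion=motion)
        summary["pruning"] = {
            name: {"n_pruned": c.n_pruned.tolist(),
                   "median": c.median.tolist(), "mad": c.mad.tolist()}
            for name, c in curves.items()}
        if out_dir is not None:
            for name, c in curves.items():
                c.to_csv(out_dir / f"pruning_{name}.csv")
    except Exception as err:        # persist partial results, name the stage
        summary["failed_stage"] = stage
        summary["error"] = repr(err)
        _save(out_dir, "summary.json", summary)
        raise
    _save(out_dir, "summary.json", summary)
    return summary


def many_env_smoke(n_envs_list=(1, 3), n_units: int = 128, n_place: int = 64,
                   total_minibatches: int = 900, seed: int = 0,
                   learning_rate: float = 1e-3, batch_size: int = 200) -> dict:
    """Scaled-down probe of capacity strain with growing environment count.

    Trains one model per environment count at a matched *total* optimisation
    budget and evaluates every model's final KL divergence on the shared
    first environment (identical across runs): with the same number of
    gradient steps, splitting capacity across more environments cannot help
    the first one, so its KL is expected to be non-decreasing in the
    environment count.
    """
    from .placecode import encode_position
    from .trajectories import MotionParams, generate_batch_fast

    arena = ArenaSpec()
    motion = MotionParams()
    out = {"n_envs": list(n_envs_list), "final_kl": [], "final_decode_err": []}
    for n_envs in n_envs_list:
        rng = np.random.default_rng(seed)
        seeds = rng.integers(2**31, size=8)
        base = make_ensemble(arena, n_place, seed=int(seeds[0]))
        envs = [base] + [remap(base, seed=int(seeds[e]), environment_id=e)
                         for e in range(1, n_envs)]
        model = carnn.init_model(n_place, n_units, seed=int(seeds[5]))
        per_env = max(total_minibatches // n_envs, 1)
        cfg = carnn.TrainConfig(learning_rate=learning_rate,
                                minibatches_per_env=per_env,
                                n_envs=n_envs, seed=int(seeds[6]),
                                batch_size=batch_size,
                                log_every=per_env * n_envs)
        model, _log = carnn.train(model, cfg, envs, arena=arena)
        # evaluate on the shared first environment with a common batch
        walk = generate_batch_fast(arena, motion, 500,
                                   np.random.default_rng(int(seeds[7])))
        p0 = encode_position(walk.x0, base)
        labels = encode_position(walk.positions, base)
        preds = carnn.forward(model, p0, walk.velocities)
        out["final_kl"].append(carnn.kl_divergence(labels, preds))
        out["final_decode_err"].append(float(carnn.decoding_error(
            model, p0, walk.velocities, labels, base)[-1]))
    return out
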