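"""Selective unit inactivation and its effect on path integration.

A recurrent unit is pruned by zeroing all of its incoming weights — its row
of the recurrent matrix and its row of the velocity-input matrix.  With no
biases its activity is then identically zero on any trajectory, while its
outgoing weights (and the encoder/decoder) are untouched, so pruning
isolates the causal contribution of the unit's activity.

Pruning curves remove units cumulatively, in random increments drawn without
replacement from a target set (all units, the top-grid-score set, or a
cluster ensemble), and measure the position decoding error at a fixed
trajectory timestep, aggregated over repeats as median +- median absolute
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .carnn import ModelParams, decoding_error, forward
from .placecode import PlaceCellEnsemble, encode_position
from .spatialmetrics import compute_ratemaps_stack, grid_score
from .trajectories import ArenaSpec, MotionParams, generate_batch_fast

__all__ = [
    "PruningPlan",
    "PruningCurve",
    "prune_units",
    "unit_activities",
    "select_top_grid",
    "pruning_curve",
    "pruning_time_course",
]


@dataclass
class PruningPlan:
    step: int = 10                 # units removed per increment
    max_units: int | None = None   # truncated to the target set size
    repeats: int = 30
    eval_timestep: int = 20        # 1-based trajectory step for the error
    batch_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step < 1 or self.repeats < 1:
            raise ValueError("step >= 1 and repeats >= 1 required")


@dataclass
class PruningCurve:
    n_pruned: np.ndarray
    median: np.ndarray
    mad: np.ndarray
    strategy: str = ""
    per_repeat: np.ndarray = None    # (repeats, len(n_pruned))

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["strategy", "n_pruned", "median", "mad"])
            for n, m, d in zip(self.n_pruned, self.median, self.mad):
                w.writerow([self.strategy, int(n), m, d])


def prune_units(model: ModelParams, indices) -> ModelParams:
    """Return a copy of the model with the given units inactivated."""
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= model.n_units):
        raise IndexError("unit index out of range")
    if len(np.unique(indices)) != len(indices):
        raise ValueError("duplicate unit indices")
    pruned = model.copy()
    pruned.Wg[indices, :] = 0.0
    pruned.Wv[indices, :] = 0.0
    return pruned


def unit_activities(model: ModelParams, ensembles: list[PlaceCellEnsemble],
                    n_traj: int = 5000, seed: int = 0,
                    arena: ArenaSpec | None = None,
                    motion: MotionParams | None = None):
    """Recurrent-unit activities along fresh trajectories, per environment.

    Yields (environment, trajectory batch, g (n_traj, T, Ng)) triples; the
    initial state is dropped so activities align with positions.
    """
    arena = arena or ensembles[0].arena
    motion = motion or MotionParams()
    rng = np.random.default_rng(seed)
    for ens in ensembles:
        walk = generate_batch_fast(arena, motion, n_traj, rng)
        p0 = encode_position(walk.x0, ens)
        _, g, _ = forward(model, p0, walk.velocities, return_states=True)
        yield ens, walk, g[:, 1:]


def select_top_grid(model: ModelParams, ensembles: list[PlaceCellEnsemble],
                    n: int, n_traj: int = 2000, n_bins: int = 32,
                    seed: int = 0) -> np.ndarray:
    """Indices of the ``n`` units with largest cumulative grid score.

    Grid scores are computed per environment from ratemaps of fresh
    trajectories and summed across environments (NaN scores contribute 0).
    """
    total = np.zeros(model.n_units)
    for ens, walk, g in unit_activities(model, ensembles, n_traj=n_traj,
                                        seed=seed):
        maps = compute_ratemaps_stack(g, walk.positions, ens.arena,
                                      n_bins=n_bins,
                                      environment_id=ens.environment_id)
        scores = np.array([grid_score(m) for m in maps])
        total += np.nan_to_num(scores)
    order = np.argsort(-total)
    return order[:n]


def _eval_error_at(model: ModelParams, batches, timestep: int) -> float:
    """Decoding error at a 1-based timestep, averaged over environments."""
    errs = []
    for p0, v, labels, ens in batches:
        errs.append(decoding_error(model, p0, v, labels, ens)[timestep - 1])
    return float(np.mean(errs))


def _make_eval_batches(ensembles, batch_size, rng, arena=None, motion=None):
    arena = arena or ensembles[0].arena
    motion = motion or MotionParams()
    counts = [batch_size // len(ensembles)] * len(ensembles)
    batches = []
    for ens, cnt in zip(ensembles, counts):
        walk = generate_batch_fast(arena, motion, max(cnt, 1), rng)
        batches.append((encode_position(walk.x0, ens), walk.velocities,
                        encode_position(walk.positions, ens), ens))
    return batches


def pruning_curve(model: ModelParams, plan: PruningPlan,
                  ensembles: list[PlaceCellEnsemble],
                  target_units: np.ndarray | None = None,
                  strategy: str = "random",
                  motion: MotionParams | None = None) -> PruningCurve:
    """Median +- MAD decoding error versus number of pruned units.

    Each repeat draws a fresh evaluation batch and a fresh random order of
    the target set (all units when ``target_units`` is None), pruning
    cumulatively without replacement in increments of ``plan.step``.
    """
    if target_units is None:
        target_units = np.arange(model.n_units)
    target_units = np.asarray(target_units, dtype=int)
    max_units = len(target_units) if plan.max_units is None else \
        min(plan.max_units, len(target_units))
    grid = np.arange(0, max_units + 1, plan.step)
    rng = np.random.default_rng(plan.seed)

    errors = np.empty((plan.repeats, len(grid)))
    for r in range(plan.repeats):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        batches = _make_eval_batches(ensembles, plan.batch_size, rep_rng,
                                     motion=motion)
        order = rep_rng.permutation(target_units)
        for gi, n_pruned in enumerate(grid):
            m = prune_units(model, order[:n_pruned])
            errors[r, gi] = _eval_error_at(m, batches, plan.eval_timestep)
    med = np.median(errors, axis=0)
    mad = np.median(np.abs(errors - med), axis=0)
    return PruningCurve(grid, med, mad, strategy=strategy, per_repeat=errors)


def pruning_time_course(model: ModelParams, plan: PruningPlan,
                        ensembles: list[PlaceCellEnsemble],
                        target_units: np.ndarray | None = None,
                        n_fixed: int = 100, strategy: str = "random",
                        motion: MotionParams | None = None) -> PruningCurve:
    """Median decoding error at every timestep with ``n_fixed`` units pruned."""
    if target_units is None:
        target_units = np.arange(model.n_units)
    target_units = np.asarray(target_units, dtype=int)
    n_fixed = min(n_fixed, len(target_units))
    rng = np.random.default_rng(plan.seed)

    curves = []
    for r in range(plan.repeats):
        rep_rng = np.random.default_rng(rng.integers(2**31))
        batches = _make_eval_batches(ensembles, plan.batch_size, rep_rng,
                                     motion=motion)
        chosen = rep_rng.choice(target_units, size=n_fixed, replace=False)
        m = prune_units(model, chosen)
        per_t = np.mean([decoding_error(m, p0, v, lab, ens)
                         for p0, v, lab, ens in batches], axis=0)
        curves.append(per_t)
    curves = np.asarray(curves)
    med = np.median(curves, axis=0)
    mad = np.median(np.abs(curves - med), axis=0)
    t_grid = np.arange(1, curves.shape[1] + 1)
    return PruningCurve(t_grid, med, mad, strategy=strategy, per_repeat=curves)
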