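"""Place-cell population code: difference-of-softmax fields, decoding, remapping.

Each of the ``Np`` place cells responds to position ``x`` as the difference of
two softmaxes over negative scaled squared distances to the field centers,

    p_i(x) = softmax_i(z^1) - softmax_i(z^2),   z^k_j = -||x - mu_j||^2 / (2 s_k^2),

with a narrow width ``s1`` and a broad width ``s2 = 2 s1`` shared by all
cells — a population-level Mexican-hat profile.  The raw difference sums to
zero across cells, so at every location the activity is shifted by the
magnitude of its minimum entry and renormalised to sum to one, making it a
valid probability vector for cross-entropy training.

Decoding is a top-3 center-of-mass: the mean of the centers of the three most
active cells.  Global remapping draws a fresh uniform set of centers while
keeping the tuning widths, making population activity statistically
independent across environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .trajectories import ArenaSpec

__all__ = [
    "PlaceCellEnsemble",
    "make_ensemble",
    "encode_position",
    "decode_position",
    "remap",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class PlaceCellEnsemble:
    centers: np.ndarray          # (Np, 2)
    s1: float = 0.12
    s2: float | None = None      # defaults to 2 * s1
    environment_id: int = 0
    arena: ArenaSpec = None

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.s2 is None:
            self.s2 = 2.0 * self.s1
        if not self.s2 > self.s1 > 0:
            raise ValueError("tuning widths must satisfy s2 > s1 > 0")
        if self.arena is None:
            self.arena = ArenaSpec()

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]


def make_ensemble(arena: ArenaSpec, n_cells: int = 512, seed: int = 0,
                  s1: float = 0.12, environment_id: int = 0,
                  ) -> PlaceCellEnsemble:
    """Uniformly scatter ``n_cells`` field centers in the arena."""
    if n_cells < 3:
        raise ValueError(
            "n_cells must be >= 3: the top-3 center-of-mass decoder needs "
            "at least three cells")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-arena.half, arena.half, size=(n_cells, 2))
    return PlaceCellEnsemble(centers, s1=s1, environment_id=environment_id,
                             arena=arena)


def encode_position(x: np.ndarray, ensemble: PlaceCellEnsemble) -> np.ndarray:
    """Population activity at position(s) ``x``.

    ``x`` may be (2,) or (..., 2); returns (..., Np), nonnegative and summing
    to one along the last axis.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    pts = np.atleast_2d(x)                                   # (n, 2)
    d2 = np.sum((pts[..., None, :] - ensemble.centers) ** 2, axis=-1)
    z1 = -d2 / (2.0 * ensemble.s1 ** 2)
    z2 = -d2 / (2.0 * ensemble.s2 ** 2)
    p = softmax(z1, axis=-1) - softmax(z2, axis=-1)
    # the difference sums to 0; shift by |min| and renormalise per location
    p = p + np.abs(p.min(axis=-1, keepdims=True))
    total = p.sum(axis=-1, keepdims=True)
    # degenerate (all-equal) activity falls back to the uniform distribution
    p = np.where(total > 0, p / np.where(total > 0, total, 1.0),
                 1.0 / ensemble.n_cells)
    return p[0] if squeeze else p.reshape(x.shape[:-1] + (ensemble.n_cells,))


def decode_position(p: np.ndarray, ensemble: PlaceCellEnsemble) -> np.ndarray:
    """Top-3 center-of-mass decode; ``p`` is (..., Np), returns (..., 2).

    Rank-3 ties resolve to the lowest cell index (argpartition order).
    """
    p = np.asarray(p)
    if p.shape[-1] < 3:
        raise ValueError("decoding needs at least 3 cells")
    top3 = np.argpartition(-p, 2, axis=-1)[..., :3]
    return ensemble.centers[top3].mean(axis=-2)


def remap(ensemble: PlaceCellEnsemble, seed: int,
          environment_id: int | None = None) -> PlaceCellEnsemble:
    """Globally remap: fresh uniform centers, same widths and cell count."""
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-ensemble.arena.half, ensemble.arena.half,
                          size=ensemble.centers.shape)
    new_id = (ensemble.environment_id + 1 if environment_id is None
              else environment_id)
    return PlaceCellEnsemble(centers, s1=ensemble.s1, s2=ensemble.s2,
                             environment_id=new_id, arena=ensemble.arena)


def save_ensemble(path, ensemble: PlaceCellEnsemble) -> None:
    np.savez(path, centers=ensemble.centers, s1=ensemble.s1, s2=ensemble.s2,
             environment_id=ensemble.environment_id,
             side_length=ensemble.arena.side_length,
             soft_margin=ensemble.arena.soft_margin)


def load_ensemble(path) -> PlaceCellEnsemble:
    with np.load(path) as f:
        return PlaceCellEnsemble(
            f["centers"], s1=float(f["s1"]), s2=float(f["s2"]),
            environment_id=int(f["environment_id"]),
            arena=ArenaSpec(float(f["side_length"]), float(f["soft_margin"])))
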