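"""Ideal grid cells from three-plane-wave interference, modules and remapping.

A grid cell with spatial frequency ``f``, orientation ``theta`` and phase
``x_i`` is

    g_i(x) = ReLU( sum_{j=1..3} cos(2 pi f R k_j . (x - x_i)) )

with unit wave vectors ``k_j`` at 0, 60 and 120 degrees and ``R`` the rotation
by ``theta``.  The real-space peak lattice of this pattern is hexagonal with
lattice constant (nearest-peak spacing) ``2 / (sqrt(3) f)``.

A module is a set of cells sharing ``f`` and ``theta`` with phases drawn
uniformly from one unit cell of the lattice (its hexagonal Wigner-Seitz
cell).  Remapping scenarios transform a module into its counterpart in a
second environment:

    identity            — unchanged
    coherent_phase      — all phases shifted by a common offset
    coherent_rotation   — the shared orientation rotated by a common angle
    incoherent_phase    — phases independently resampled in the unit cell
    incoherent_rotation — each cell rotated by an independent uniform angle

Coherent scenarios produce unimodal phase/orientation-shift histograms;
incoherent ones produce near-uniform histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DEFAULT_FREQUENCY",
    "SyntheticModule",
    "lattice_constant",
    "eval_grid_cell",
    "make_module",
    "apply_scenario",
    "module_ratemaps",
    "module_population_pointcloud",
]

DEFAULT_FREQUENCY = 1.0 / 0.838

_K = np.stack([[np.cos(a), np.sin(a)]
               for a in (0.0, np.pi / 3, 2 * np.pi / 3)])  # unit wave vectors


def lattice_constant(f: float) -> float:
    """Nearest-peak spacing of the interference pattern: 2 / (sqrt(3) f)."""
    return 2.0 / (np.sqrt(3.0) * f)


@dataclass
class SyntheticModule:
    frequency: float = DEFAULT_FREQUENCY
    orientation: float = 0.0            # radians, shared across the module
    phases: np.ndarray = None           # (n_cells, 2)
    cell_orientations: np.ndarray = None  # per-cell override (incoherent rotation)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        self.phases = np.atleast_2d(np.asarray(self.phases, dtype=float))

    @property
    def n_cells(self) -> int:
        return self.phases.shape[0]

    def orientation_of(self, i: int) -> float:
        if self.cell_orientations is not None:
            return float(self.cell_orientations[i])
        return float(self.orientation)


def _rotation(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def eval_grid_cell(f: float, theta: float, phase: np.ndarray,
                   positions: np.ndarray) -> np.ndarray:
    """Evaluate one ideal grid cell at ``positions`` (..., 2)."""
    pos = np.asarray(positions, dtype=float)
    rel = pos - np.asarray(phase, dtype=float)
    k_rot = _K @ _rotation(theta).T            # rows: R k_j
    args = 2 * np.pi * f * (rel @ k_rot.T)     # (..., 3)
    return np.maximum(np.cos(args).sum(axis=-1), 0.0)


def sample_unit_cell(f: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform samples from the hexagonal Wigner-Seitz unit cell.

    For orientation 0 the peak lattice has nearest-neighbor directions at
    30 + 60k degrees, so the cell is a regular hexagon with vertices at
    0 + 60k degrees, inradius a/2 and circumradius a/sqrt(3), where
    a = lattice_constant(f).  Rejection sampling from the bounding box.
    """
    a = lattice_constant(f)
    r_out = a / np.sqrt(3.0)
    out = np.empty((0, 2))
    while len(out) < n:
        cand = rng.uniform(-r_out, r_out, size=(2 * (n - len(out)) + 8, 2))
        x, y = np.abs(cand[:, 0]), np.abs(cand[:, 1])
        inside = (y <= a / 2.0) & (np.sqrt(3.0) * x + y <= a)
        out = np.concatenate([out, cand[inside]])
    return out[:n]


def make_module(n_cells: int = 50, f: float = DEFAULT_FREQUENCY,
                theta: float = 0.0,
                rng: np.random.Generator | int = 0) -> SyntheticModule:
    """Module with shared frequency/orientation, phases uniform in the unit cell."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    phases = sample_unit_cell(f, n_cells, rng) @ _rotation(theta).T
    return SyntheticModule(frequency=f, orientation=theta, phases=phases)


def apply_scenario(module: SyntheticModule, scenario: str,
                   rng: np.random.Generator | int = 0,
                   delta: tuple[float, float] = (-0.2, -0.2),
                   alpha_deg: float = -5.0) -> SyntheticModule:
    """Remap a module into a second environment under one of five scenarios."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if scenario == "identity":
        return replace(module, phases=module.phases.copy())
    if scenario == "coherent_phase":
        return replace(module, phases=module.phases + np.asarray(delta))
    if scenario == "coherent_rotation":
        return replace(module, phases=module.phases.copy(),
                       orientation=module.orientation + np.deg2rad(alpha_deg))
    if scenario == "incoherent_phase":
        phases = (sample_unit_cell(module.frequency, module.n_cells, rng)
                  @ _rotation(module.orientation).T)
        return replace(module, phases=phases)
    if scenario == "incoherent_rotation":
        angles = rng.uniform(-np.pi, np.pi, size=module.n_cells)
        return replace(module, phases=module.phases.copy(),
                       cell_orientations=module.orientation + angles)
    raise ValueError(f"unknown scenario {scenario!r}")


def _grid_positions(side: float, n_bins: int) -> np.ndarray:
    """Bin-center positions of an n_bins x n_bins raster over the box."""
    edges = np.linspace(-side / 2, side / 2, n_bins + 1)
    c = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(c, c, indexing="xy")
    return np.stack([gx, gy], axis=-1)        # (n_bins, n_bins, 2); [row=y, col=x]


def module_ratemaps(module: SyntheticModule, side: float = 2.2,
                    n_bins: int = 64) -> np.ndarray:
    """Dense rasterisation of every cell: (n_cells, n_bins, n_bins).

    Row index increases with y, column index with x (bin-center evaluation).
    """
    pos = _grid_positions(side, n_bins)
    maps = np.empty((module.n_cells, n_bins, n_bins))
    for i in range(module.n_cells):
        maps[i] = eval_grid_cell(module.frequency, module.orientation_of(i),
                                 module.phases[i], pos)
    return maps


def module_population_pointcloud(module: SyntheticModule, side: float = 2.2,
                                 n_bins: int = 64) -> np.ndarray:
    """Population activity vectors: (n_bins^2, n_cells) point cloud.

    Each row is the module's joint activity at one spatial bin; for >= 3
    cells with spread phases this cloud lies on a 2-torus.
    """
    if module.n_cells < 3:
        raise ValueError("need >= 3 cells for a meaningful point cloud")
    maps = module_ratemaps(module, side=side, n_bins=n_bins)
    return maps.reshape(module.n_cells, -1).T
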