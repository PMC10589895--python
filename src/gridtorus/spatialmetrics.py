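"""Ratemaps and single-cell spatial statistics.

Conventions
-----------
Ratemaps are ``(Ns, Ns)`` arrays over the square arena with row index
increasing with the y coordinate and column index with x; bins never visited
are NaN ("missing", never zero).  Autocorrelograms and cross-correlograms are
``(2 Ns - 1, 2 Ns - 1)`` arrays of per-lag Pearson correlations (computed
over the overlapping valid bins of the two shifted maps, missing bins
excluded pairwise, lags with fewer than ``min_overlap`` overlapping bins
masked).  The center element is lag zero.

The statistics follow standard open-field practice: the grid score is the
difference between the annulus-masked autocorrelogram's correlation with its
60/120-degree rotations and its 30/90/150-degree rotations, maximised over a
sweep of annulus radii; phase shift is the cross-correlogram local peak
nearest the center; orientation shift is the argmax over one-degree rotations
of the correlation between autocorrelograms on their largest common disk;
spacing is the median center distance of the innermost isodistant ring of
autocorrelogram peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage, signal
from scipy.stats import gaussian_kde

from .trajectories import ArenaSpec

__all__ = [
    "Ratemap",
    "compute_ratemap",
    "compute_ratemaps_stack",
    "autocorrelogram",
    "cross_correlogram",
    "grid_score",
    "phase_shift",
    "orientation_shift",
    "wrap_orientation",
    "grid_spacing",
    "shift_density",
    "find_peaks_2d",
]

DEFAULT_MIN_OVERLAP = 20


@dataclass
class Ratemap:
    values: np.ndarray          # (Ns, Ns), NaN where unvisited
    occupancy: np.ndarray       # (Ns, Ns) visit counts
    bin_size: float
    unit_id: int = -1
    environment_id: int = -1

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def _bin_indices(positions: np.ndarray, arena: ArenaSpec, n_bins: int):
    half = arena.half
    scaled = (positions + half) / arena.side_length * n_bins
    idx = np.clip(scaled.astype(int), 0, n_bins - 1)
    return idx[..., 1], idx[..., 0]          # (row=y, col=x)


def compute_ratemap(activities: np.ndarray, positions: np.ndarray,
                    arena: ArenaSpec, n_bins: int = 64,
                    t_slice: slice | None = None,
                    unit_id: int = -1, environment_id: int = -1) -> Ratemap:
    """Mean activity per spatial bin for one unit.

    ``activities``: (..., T); ``positions``: (..., T, 2); ``t_slice``
    restricts to a window of trajectory timesteps (e.g. the final 10 steps
    to avoid transient initial network states).
    """
    act = np.asarray(activities, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if t_slice is not None:
        act = act[..., t_slice]
        pos = pos[..., t_slice, :]
    iy, ix = _bin_indices(pos.reshape(-1, 2), arena, n_bins)
    flat = iy * n_bins + ix
    counts = np.bincount(flat, minlength=n_bins * n_bins)
    sums = np.bincount(flat, weights=act.ravel(), minlength=n_bins * n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = sums / counts
    values[counts == 0] = np.nan
    return Ratemap(values.reshape(n_bins, n_bins),
                   counts.reshape(n_bins, n_bins),
                   arena.side_length / n_bins, unit_id, environment_id)


def compute_ratemaps_stack(activities: np.ndarray, positions: np.ndarray,
                           arena: ArenaSpec, n_bins: int = 64,
                           t_slice: slice | None = None,
                           environment_id: int = -1) -> list[Ratemap]:
    """Ratemaps for many units sharing the same trajectories.

    ``activities``: (n_traj, T, n_units); one bincount pass per unit.
    """
    act = np.asarray(activities, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if t_slice is not None:
        act = act[:, t_slice]
        pos = pos[:, t_slice]
    iy, ix = _bin_indices(pos.reshape(-1, 2), arena, n_bins)
    flat = iy * n_bins + ix
    counts = np.bincount(flat, minlength=n_bins * n_bins)
    occ = counts.reshape(n_bins, n_bins)
    bin_size = arena.side_length / n_bins
    out = []
    n_units = act.shape[-1]
    flat_act = act.reshape(-1, n_units)
    for u in range(n_units):
        sums = np.bincount(flat, weights=flat_act[:, u],
                           minlength=n_bins * n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = sums / counts
        values[counts == 0] = np.nan
        out.append(Ratemap(values.reshape(n_bins, n_bins), occ, bin_size,
                           unit_id=u, environment_id=environment_id))
    return out


def _xcorr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """C[l] = sum_x a(x) b(x + l), full lag range, via FFT."""
    return signal.fftconvolve(b, a[::-1, ::-1], mode="full")


def cross_correlogram(map_a: np.ndarray, map_b: np.ndarray,
                      min_overlap: int = DEFAULT_MIN_OVERLAP) -> np.ndarray:
    """Per-lag Pearson correlation between two maps (NaN-aware).

    Element ``[Ns-1+dy, Ns-1+dx]`` correlates ``a(x)`` with ``b(x + (dx,dy))``.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    ma = np.isfinite(a).astype(float)
    mb = np.isfinite(b).astype(float)
    az = np.where(np.isfinite(a), a, 0.0)
    bz = np.where(np.isfinite(b), b, 0.0)

    n = _xcorr(ma, mb)
    sa = _xcorr(az, mb)
    sb = _xcorr(ma, bz)
    saa = _xcorr(az * az, mb)
    sbb = _xcorr(ma, bz * bz)
    sab = _xcorr(az, bz)

    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sab - sa * sb
        var_a = n * saa - sa ** 2
        var_b = n * sbb - sb ** 2
        corr = cov / np.sqrt(var_a * var_b)
    bad = (n < min_overlap) | (var_a <= 0) | (var_b <= 0)
    corr[bad] = np.nan
    return np.clip(corr, -1.0, 1.0)


def autocorrelogram(ratemap: Ratemap | np.ndarray,
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> np.ndarray:
    """Spatial autocorrelogram: cross-correlogram of a map with itself."""
    values = ratemap.values if isinstance(ratemap, Ratemap) else ratemap
    finite = values[np.isfinite(values)]
    if finite.size < 2 or np.allclose(finite, finite.flat[0]):
        raise ValueError("autocorrelogram undefined for constant/empty map")
    return cross_correlogram(values, values, min_overlap=min_overlap)


# ---------------------------------------------------------------------------
# rotation machinery (shared by grid score, orientation shift, rotational ACG)

@lru_cache(maxsize=32)
def _disk_pixels(size: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
    return yy[mask].astype(float), xx[mask].astype(float)


@lru_cache(maxsize=8)
def _rotated_coords(size: int, radius: float, angles_key: tuple) -> np.ndarray:
    """Source sampling coords (n_angles, 2, n_pix) rotating the pattern CCW.

    Row index is y; a CCW rotation by alpha of the pattern samples the source
    at R(-alpha) applied to the destination offset.
    """
    angles = np.deg2rad(np.array(angles_key))
    yy, xx = _disk_pixels(size, radius)
    c = (size - 1) / 2.0
    dy, dx = yy - c, xx - c
    cos, sin = np.cos(angles)[:, None], np.sin(angles)[:, None]
    src_x = c + cos * dx + sin * dy
    src_y = c - sin * dx + cos * dy
    return np.stack([src_y, src_x], axis=1)


def rotate_disk_samples(image: np.ndarray, angles_deg: np.ndarray,
                        radius: float | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples of ``image`` rotated by each angle, on a center disk.

    Returns (rotated (n_angles, n_pix), unrotated (n_pix,)).  NaNs in the
    image are replaced by 0 before interpolation.
    """
    img = np.asarray(image, dtype=float)
    size = img.shape[0]
    if radius is None:
        radius = (size - 1) / 2.0
    filled = np.where(np.isfinite(img), img, 0.0)
    key = tuple(float(a) for a in np.atleast_1d(angles_deg))
    coords = _rotated_coords(size, float(radius), key)
    n_angles, _, n_pix = coords.shape
    flat = coords.transpose(1, 0, 2).reshape(2, -1)
    rotated = ndimage.map_coordinates(filled, flat, order=1, mode="constant",
                                      cval=0.0).reshape(n_angles, n_pix)
    yy, xx = _disk_pixels(size, float(radius))
    unrotated = filled[yy.astype(int), xx.astype(int)]
    return rotated, unrotated


def _pearson_rows(rows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``rows`` with ``ref``."""
    rows = rows - rows.mean(axis=1, keepdims=True)
    ref = ref - ref.mean()
    denom = np.sqrt((rows ** 2).sum(axis=1) * (ref ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rows @ ref) / denom


# ---------------------------------------------------------------------------
# grid score

_SCORE_ANGLES = (30.0, 45.0, 60.0, 90.0, 120.0, 135.0, 150.0)


def grid_score(ratemap: Ratemap | np.ndarray,
               acg: np.ndarray | None = None) -> float:
    """Hexagonality score of a ratemap.

    min(correlation at 60, 120 deg) - max(correlation at 30, 90, 150 deg) of
    the annulus-masked autocorrelogram with its rotations, maximised over a
    sweep of annulus outer radii (inner radius 20% of the half-size, masking
    the central peak).  NaN for degenerate maps.
    """
    try:
        if acg is None:
            acg = autocorrelogram(ratemap)
    except ValueError:
        return np.nan
    size = acg.shape[0]
    half = (size - 1) / 2.0
    filled = np.where(np.isfinite(acg), acg, 0.0)
    rotated, _ = rotate_disk_samples(filled, np.array(_SCORE_ANGLES))
    yy, xx = _disk_pixels(size, half)
    base = filled[yy.astype(int), xx.astype(int)]
    r = np.hypot(yy - half, xx - half)

    inner = 0.2 * half
    best = -np.inf
    for outer in np.linspace(0.4 * half, half, 10):
        ring = (r >= inner) & (r <= outer)
        if ring.sum() < 10:
            continue
        ref = base[ring]
        if np.allclose(ref, ref[0]):
            continue
        corrs = _pearson_rows(rotated[:, ring], ref)
        by_angle = dict(zip(_SCORE_ANGLES, corrs))
        score = (min(by_angle[60.0], by_angle[120.0])
                 - max(by_angle[30.0], by_angle[90.0], by_angle[150.0]))
        best = max(best, score)
    return float(best) if np.isfinite(best) else np.nan


# ---------------------------------------------------------------------------
# peaks, phase shift, spacing

def find_peaks_2d(corr: np.ndarray, smooth_sd: float = 1.0) -> np.ndarray:
    """Local maxima (3x3 neighborhood) of a correlogram.

    Light Gaussian smoothing is applied for peak *detection only*; returned
    coordinates are (row, col) indices into the unsmoothed array.
    """
    filled = np.where(np.isfinite(corr), corr, np.nanmin(corr[np.isfinite(corr)])
                      if np.isfinite(corr).any() else 0.0)
    sm = ndimage.gaussian_filter(filled, smooth_sd)
    is_max = (sm == ndimage.maximum_filter(sm, size=3)) & np.isfinite(corr)
    # drop plateaus at the border of the valid region
    peaks = np.argwhere(is_max & (sm > np.nanmedian(sm)))
    return peaks


def phase_shift(map_a: Ratemap | np.ndarray, map_b: Ratemap | np.ndarray,
                bin_size: float | None = None) -> np.ndarray:
    """Translation (dx, dy) in box units taking pattern a onto pattern b.

    The cross-correlogram local peak nearest the center; for maps where
    b(x) = a(x - delta) the returned vector is delta (up to the lattice
    periodicity of the patterns).
    """
    if isinstance(map_a, Ratemap):
        bin_size = map_a.bin_size
        map_a = map_a.values
    if isinstance(map_b, Ratemap):
        map_b = map_b.values
    if bin_size is None:
        raise ValueError("bin_size required for raw arrays")
    corr = cross_correlogram(map_a, map_b)
    peaks = find_peaks_2d(corr)
    if len(peaks) == 0:
        return np.array([np.nan, np.nan])
    center = (np.array(corr.shape) - 1) / 2.0
    d2 = ((peaks - center) ** 2).sum(axis=1)
    row, col = peaks[np.argmin(d2)]
    return np.array([(col - center[1]) * bin_size,
                     (row - center[0]) * bin_size])


def grid_spacing(ratemap: Ratemap | np.ndarray,
                 acg: np.ndarray | None = None,
                 bin_size: float | None = None) -> float:
    """Spacing from the innermost isodistant ring of autocorrelogram peaks.

    Peak center-distances are sorted; the first difference exceeding
    mean + 2 sd of the differences marks the end of the isodistant ring, and
    the spacing is the median distance before that jump (all peaks if no
    jump).  NaN if fewer than two off-center peaks exist.
    """
    if isinstance(ratemap, Ratemap):
        bin_size = ratemap.bin_size
    if bin_size is None:
        raise ValueError("bin_size required for raw arrays")
    try:
        if acg is None:
            acg = autocorrelogram(ratemap)
    except ValueError:
        return np.nan
    peaks = find_peaks_2d(acg)
    center = (np.array(acg.shape) - 1) / 2.0
    dist = np.sqrt(((peaks - center) ** 2).sum(axis=1))
    dist = np.sort(dist[dist > 1.5])          # drop the central peak
    if len(dist) < 2:
        return np.nan
    diffs = np.diff(dist)
    cut = len(dist)
    if len(diffs) >= 2:
        jumps = np.nonzero(diffs > diffs.mean() + 2 * diffs.std())[0]
        if len(jumps):
            cut = jumps[0] + 1
    return float(np.median(dist[:cut]) * bin_size)


# ---------------------------------------------------------------------------
# orientation shift

def orientation_shift(map_a: Ratemap | np.ndarray, map_b: Ratemap | np.ndarray,
                      acg_a: np.ndarray | None = None,
                      acg_b: np.ndarray | None = None) -> float:
    """Rotation (degrees, in (-180, 180]) taking pattern a onto pattern b.

    Both autocorrelograms are normalised to sum one; a is rotated in
    one-degree increments and correlated with b on the largest disk
    contained in both squares; the argmax rotation is returned, ties
    resolving to the smallest absolute rotation.
    """
    if acg_a is None:
        acg_a = autocorrelogram(map_a.values if isinstance(map_a, Ratemap)
                                else map_a)
    if acg_b is None:
        acg_b = autocorrelogram(map_b.values if isinstance(map_b, Ratemap)
                                else map_b)
    a = np.where(np.isfinite(acg_a), acg_a, 0.0)
    b = np.where(np.isfinite(acg_b), acg_b, 0.0)
    for m in (a, b):
        s = abs(m.sum())        # |sum|: a negative total must not flip signs
        if s != 0:
            m /= s
    angles = np.arange(-179.0, 181.0)
    rotated, _ = rotate_disk_samples(a, angles)
    _, ref_b = rotate_disk_samples(b, np.array([0.0]))
    corrs = _pearson_rows(rotated, ref_b)
    best = np.nanmax(corrs)
    cand = angles[np.isclose(corrs, best, rtol=0, atol=1e-12)]
    return float(cand[np.argmin(np.abs(cand))])


def wrap_orientation(shift_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap an orientation shift into [-15, 15) (hexagonal 30-deg symmetry):
    shift by 15, take mod 30, recenter."""
    return np.mod(np.asarray(shift_deg) + 15.0, 30.0) - 15.0


# ---------------------------------------------------------------------------
# KDE of shift distributions

def shift_density(shifts: np.ndarray, grid: np.ndarray | None = None,
                  ) -> tuple[gaussian_kde, np.ndarray | None]:
    """Gaussian KDE (Scott bandwidth) of 2-d shift vectors.

    Returns the fitted KDE and, if ``grid`` (2, m) is given, its evaluation.
    Degenerate (singular-covariance) inputs get a small jitter.
    """
    pts = np.asarray(shifts, dtype=float).T        # (2, n)
    if pts.shape[1] < 2:
        raise ValueError("need at least 2 shift vectors")
    try:
        kde = gaussian_kde(pts)
    except np.linalg.LinAlgError:
        jitter = 1e-6 * np.random.default_rng(0).standard_normal(pts.shape)
        kde = gaussian_kde(pts + jitter)
    return kde, (kde(grid) if grid is not None else None)
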