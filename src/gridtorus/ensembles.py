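"""Unit-type discovery and toroidal-manifold detection.

Units are characterised by the rotational symmetry of their spatial firing:
the central disk of each 32x32 ratemap's spatial autocorrelogram is
z-scored and correlated with rotated copies of itself at 360 one-degree
rotations.  UMAP embeds the resulting rotational-autocorrelation vectors in
2-d and DBSCAN clusters them; grid-like units peak near +-60/+-120/180
degrees, band-like units only near 180.  Band-like clusters (three families at roughly 60 degrees to one
another) jointly form the torus ensemble, which K-means (k=3) splits back
into its orientation families from pairwise autocorrelogram correlations.

Population-level structure is read out by stacking ratemaps into an
(n_bins^2, n_units) activity matrix, projecting to six principal
components, downsampling to the points with strongest fuzzy neighborhood
membership (the first UMAP stage), and computing Vietoris-Rips persistence;
a torus shows the Betti signature (1, 2, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA

from ._persistence import (PersistenceDiagram, detect_torus,
                           greedy_permutation, rips_persistence)
from .spatialmetrics import Ratemap, autocorrelogram, rotate_disk_samples, \
    _pearson_rows

__all__ = [
    "RotationalACG",
    "ClusterAssignment",
    "rotational_autocorrelogram",
    "exclude_units",
    "cluster_units",
    "band_like_clusters",
    "refine_torus_ensemble",
    "pca_project",
    "fuzzy_downsample",
    "persistence",
    "detect_torus",
    "umap3d_view",
    "PersistenceDiagram",
]

N_THETA = 360
_ROT_ANGLES = np.arange(-180.0, 180.0)        # -pi .. pi in 1-degree steps


@dataclass
class RotationalACG:
    values: np.ndarray            # (360,) Pearson correlations
    rotations_deg: np.ndarray = field(
        default_factory=lambda: _ROT_ANGLES.copy())
    unit_id: int = -1


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # per included unit; -1 = noise
    included: np.ndarray          # indices into the full population
    excluded_reason: dict         # unit index -> "zero-activity" | "high-rate"
    embedding: np.ndarray = None  # (n_included, 2) UMAP coordinates


def rotational_autocorrelogram(ratemap: Ratemap | np.ndarray,
                               unit_id: int = -1,
                               radius: int = 16) -> RotationalACG:
    """360 Pearson correlations of a z-scored disk with its rotations.

    The disk (radius 16 bins for a 32x32 ratemap) is cut from the center of
    the map's *spatial autocorrelogram*, which is centered by construction,
    so the resulting vector is a phase-invariant rotational-symmetry
    fingerprint: an ideal grid peaks near +-60, +-120 and 180 degrees, a
    band (plane-wave) pattern only near 180.  Rotation uses bilinear
    interpolation.
    """
    values = ratemap.values if isinstance(ratemap, Ratemap) else np.asarray(ratemap)
    filled = np.where(np.isfinite(values), values, 0.0)
    if filled.std() == 0:
        raise ValueError("zero-variance map; exclude before clustering")
    acg = autocorrelogram(values)
    c = (acg.shape[0] - 1) // 2
    disk = acg[c - radius:c + radius + 1, c - radius:c + radius + 1]
    disk = np.where(np.isfinite(disk), disk, 0.0)
    sd = disk.std()
    if sd == 0:
        raise ValueError("zero-variance autocorrelogram disk")
    z = (disk - disk.mean()) / sd
    rotated, base = rotate_disk_samples(z, _ROT_ANGLES, radius=float(radius))
    corrs = _pearson_rows(rotated, base)
    return RotationalACG(np.nan_to_num(corrs), unit_id=unit_id)


def exclude_units(ratemaps: list[Ratemap] | np.ndarray,
                  high_rate_percentile: float = 99.75) -> dict:
    """Two-stage exclusion mask over a unit population.

    Stage 1 removes units with zero activity everywhere; stage 2 removes
    units whose mean spatial rate exceeds the given percentile, computed on
    the population remaining after stage 1.
    """
    if isinstance(ratemaps, np.ndarray):
        stack = ratemaps
    else:
        stack = np.stack([r.values for r in ratemaps])
    means = np.nanmean(np.where(np.isfinite(stack), stack, np.nan),
                       axis=(1, 2))
    means = np.nan_to_num(means)
    reasons: dict[int, str] = {}
    zero = np.all(np.nan_to_num(stack) == 0, axis=(1, 2))
    for i in np.nonzero(zero)[0]:
        reasons[int(i)] = "zero-activity"
    surviving = means[~zero]
    if len(surviving):
        cut = np.percentile(surviving, high_rate_percentile)
        for i in np.nonzero(~zero & (means > cut))[0]:
            reasons[int(i)] = "high-rate"
    return reasons


def cluster_units(rotacgs: list[RotationalACG] | np.ndarray,
                  n_neighbors: int = 20, min_dist: float = 0.05,
                  min_samples: int = 30, eps: float | str = "auto",
                  seed: int = 0) -> ClusterAssignment:
    """UMAP (2-d) then DBSCAN over rotational-autocorrelation vectors.

    ``eps="auto"`` sets the DBSCAN radius to the median distance to the
    ``min_samples``-th nearest neighbor in the embedding (the k-distance
    heuristic), which adapts to the embedding scale of the population size;
    a float fixes it explicitly.
    """
    import umap

    if isinstance(rotacgs, np.ndarray):
        X = rotacgs
        ids = np.arange(len(X))
    else:
        X = np.stack([r.values for r in rotacgs])
        ids = np.array([r.unit_id for r in rotacgs])
    if len(X) < min_samples:
        raise ValueError("fewer units than DBSCAN min_samples")
    reducer = umap.UMAP(n_components=2, n_neighbors=min(n_neighbors, len(X) - 1),
                        min_dist=min_dist, metric="euclidean", init="spectral",
                        random_state=seed)
    emb = reducer.fit_transform(X)
    if eps == "auto":
        from sklearn.neighbors import NearestNeighbors

        k = min(min_samples, len(X) - 1)
        dists, _ = NearestNeighbors(n_neighbors=k + 1).fit(emb).kneighbors(emb)
        eps = float(np.median(dists[:, -1]))
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    if np.all(labels == -1):
        import warnings

        warnings.warn("DBSCAN labelled every unit as noise")
    return ClusterAssignment(labels, ids, {}, embedding=emb)


def band_like_clusters(rotacgs: np.ndarray, labels: np.ndarray,
                       peak_prominence: float = 0.2) -> list[int]:
    """Clusters whose mean rotational ACG has 180-degree symmetry only.

    A band (single plane-wave-like) pattern correlates with itself at a 180
    degree rotation but not at 60/120; a grid also peaks near +-60/+-120.
    A cluster is band-like when, in its mean rotational ACG, the value at
    180 degrees is high while the 60- and 120-degree values stay low.
    """
    out = []
    ang = _ROT_ANGLES
    for lab in sorted(set(labels) - {-1}):
        mean_acg = rotacgs[labels == lab].mean(axis=0)

        def val_at(a):
            return mean_acg[np.argmin(np.abs(ang - a))]

        v180 = val_at(180 - 1)  # 180 is the wrap point; use 179
        v60 = max(val_at(60), val_at(-60))
        v120 = max(val_at(120), val_at(-120))
        if v180 > 0.5 and max(v60, v120) < v180 - peak_prominence:
            out.append(int(lab))
    return out


def refine_torus_ensemble(candidate_units: np.ndarray,
                          ratemaps: np.ndarray | list,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """K-means (k=3) split of the torus ensemble into orientation families.

    Features are rows of the pairwise Pearson-correlation matrix between the
    candidates' spatial autocorrelograms.  Returns (subcluster labels,
    candidate_units).
    """
    candidate_units = np.asarray(candidate_units)
    if len(candidate_units) < 3:
        raise ValueError("need at least 3 candidate units for a 3-way split")
    acgs = []
    for u in candidate_units:
        m = ratemaps[u] if not isinstance(ratemaps[u], Ratemap) else ratemaps[u].values
        acgs.append(np.nan_to_num(autocorrelogram(m)).ravel())
    acgs = np.stack(acgs)
    feat = np.corrcoef(acgs)
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(feat)
    return km.labels_, candidate_units


def pca_project(ratemap_stack: np.ndarray, n_components: int = 6) -> np.ndarray:
    """Project ensemble activity to principal components.

    ``ratemap_stack``: (n_bins^2, n_units) — rows are spatial bins, columns
    units.  Returns (n_bins^2, n_components).
    """
    X = np.nan_to_num(np.asarray(ratemap_stack, dtype=float))
    n_comp = min(n_components, X.shape[1])
    pca = PCA(n_components=n_comp)
    out = pca.fit_transform(X)
    if out.shape[1] < n_components:
        import warnings

        warnings.warn(f"only {out.shape[1]} non-degenerate components")
    return out


def fuzzy_downsample(points: np.ndarray, k: int = 1000, n_keep: int = 3000,
                     tol: float = 1e-5) -> np.ndarray:
    """Keep the ``n_keep`` points with strongest fuzzy neighborhood membership.

    For each point the similarity to its k nearest neighbors (cosine
    distance) is a_ij = exp(-d_ij / sigma_i) with sigma_i calibrated by
    bisection so that sum_j a_ij = log2(k); memberships are symmetrised as
    m_ij = a_ij + a_ji - a_ij a_ji and points ranked by their mean
    membership.  Returns indices of the kept points.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n_keep >= n:
        return np.arange(n)
    if k >= n:
        import warnings

        warnings.warn(f"k={k} clamped to {n - 1}")
        k = n - 1
    D = cdist(pts, pts, metric="cosine")
    np.fill_diagonal(D, np.inf)
    nn_idx = np.argpartition(D, k - 1, axis=1)[:, :k]
    nn_d = np.take_along_axis(D, nn_idx, axis=1)

    target = np.log2(k)
    lo = np.full(n, 1e-12)
    hi = np.full(n, 1e3)
    for _ in range(200):
        sigma = 0.5 * (lo + hi)
        s = np.exp(-nn_d / sigma[:, None]).sum(axis=1)
        hi = np.where(s > target, sigma, hi)
        lo = np.where(s <= target, sigma, lo)
        if np.max(np.abs(s - target)) < tol:
            break
    sigma = 0.5 * (lo + hi)
    a = np.exp(-nn_d / sigma[:, None])

    # symmetrised membership m_ij = a_ij + a_ji - a_ij a_ji; each point is
    # scored by the mean membership over its own k nearest neighbors
    a_mat = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    a_mat[rows, nn_idx.ravel()] = a.ravel()
    m = a_mat + a_mat.T - a_mat * a_mat.T
    mean_m = np.take_along_axis(m, nn_idx, axis=1).mean(axis=1)
    return np.argsort(-mean_m)[:n_keep]


def persistence(points: np.ndarray, field_char: int = 47, nperm: int = 500,
                maxdim: int = 2, threshold: float | None = None,
                simplex_budget: float = 2.5e6) -> PersistenceDiagram:
    """Vietoris-Rips persistence of a point cloud after greedy-permutation
    subsampling to ``nperm`` landmarks (Euclidean metric)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    return rips_persistence(pts, maxdim=maxdim, field_char=field_char,
                            n_landmarks=nperm, threshold=threshold,
                            simplex_budget=simplex_budget)


def umap3d_view(points: np.ndarray, n_neighbors: int = 4000,
                min_dist: float = 0.8, seed: int = 0) -> np.ndarray:
    """Visualisation-only 3-d UMAP embedding (never used quantitatively)."""
    import umap

    pts = np.asarray(points, dtype=float)
    reducer = umap.UMAP(n_components=3, min_dist=min_dist,
                        n_neighbors=min(n_neighbors, len(pts) - 1),
                        metric="euclidean", init="spectral", random_state=seed)
    return reducer.fit_transform(pts)
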