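"""Ratemaps, correlograms and the spatial remapping estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridtorus.spatialmetrics import (autocorrelogram, compute_ratemap,
                                      cross_correlogram, grid_score,
                                      grid_spacing, orientation_shift,
                                      phase_shift, shift_density,
                                      wrap_orientation)
from gridtorus.synthgrid import (apply_scenario, eval_grid_cell,
                                 lattice_constant, make_module,
                                 module_ratemaps)
from gridtorus.trajectories import ArenaSpec

BIN = 2.2 / 64


@pytest.fixture(scope="module")
def ideal_maps():
    mod = make_module(6, rng=0)
    return mod, module_ratemaps(mod, n_bins=64)


@pytest.fixture(scope="module")
def band_map():
    g = np.linspace(-1.1, 1.1, 64)
    gx, _ = np.meshgrid(g, g)
    return np.maximum(np.cos(2 * np.pi * 1.2 * gx), 0)


def test_ratemap_mean_and_missing_bins(arena):
    # two visits to one location with activities 1 and 3 average to 2
    pos = np.array([[[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]])
    act = np.array([[1.0, 3.0, 5.0]])
    rm = compute_ratemap(act, pos, arena, n_bins=4)
    assert rm.values[2, 2] == pytest.approx(2.0)
    assert rm.values[3, 3] == pytest.approx(5.0)
    assert np.isnan(rm.values[0, 0])       # unvisited -> missing, not zero
    assert rm.occupancy.sum() == 3


def test_ratemap_t_slice(arena):
    pos = np.zeros((1, 4, 2))
    act = np.array([[10.0, 10.0, 1.0, 3.0]])
    rm = compute_ratemap(act, pos, arena, n_bins=4, t_slice=slice(2, None))
    assert rm.values[2, 2] == pytest.approx(2.0)


def test_ratemap_matches_dense_evaluation(arena, motion=None):
    # grid cell sampled along trajectories correlates >0.99 with the formula
    from gridtorus.trajectories import MotionParams, generate_batch_fast

    walk = generate_batch_fast(arena, MotionParams(), 4000, rng=1)
    act = eval_grid_cell(1 / 0.838, 0.4, np.array([0.1, -0.2]),
                         walk.positions)
    rm = compute_ratemap(act, walk.positions, arena, n_bins=32)
    g = np.linspace(-1.1 + 2.2 / 64, 1.1 - 2.2 / 64, 32)
    gx, gy = np.meshgrid(g, g)
    dense = eval_grid_cell(1 / 0.838, 0.4, np.array([0.1, -0.2]),
                           np.stack([gx, gy], -1))
    ok = np.isfinite(rm.values)
    r = np.corrcoef(rm.values[ok], dense[ok])[0, 1]
    assert r > 0.99


def test_autocorrelogram_center_symmetry_and_hexagonality(ideal_maps):
    _, maps = ideal_maps
    acg = autocorrelogram(maps[0])
    c = (acg.shape[0] - 1) // 2
    assert acg[c, c] == pytest.approx(1.0)
    ok = np.isfinite(acg) & np.isfinite(acg[::-1, ::-1])
    np.testing.assert_allclose(acg[ok], acg[::-1, ::-1][ok], atol=1e-6)
    with pytest.raises(ValueError):
        autocorrelogram(np.ones((16, 16)))


def test_cross_correlogram_matches_brute_force():
    rng = np.random.default_rng(2)
    a = rng.normal(size=(8, 8))
    b = rng.normal(size=(8, 8))
    corr = cross_correlogram(a, b, min_overlap=4)
    # brute-force Pearson at a couple of lags
    for (dy, dx) in [(0, 0), (1, -2), (-3, 2)]:
        pairs_a, pairs_b = [], []
        for y in range(8):
            for x in range(8):
                yy, xx = y + dy, x + dx
                if 0 <= yy < 8 and 0 <= xx < 8:
                    pairs_a.append(a[y, x])
                    pairs_b.append(b[yy, xx])
        expected = np.corrcoef(pairs_a, pairs_b)[0, 1]
        assert corr[7 + dy, 7 + dx] == pytest.approx(expected, abs=1e-9)


def test_grid_score_ideal_band_and_rotation_invariance(ideal_maps, band_map):
    _, maps = ideal_maps
    assert grid_score(maps[0]) > 1.0
    assert grid_score(band_map) < 0.3
    # rotating the pattern leaves the score roughly unchanged
    mod = make_module(1, rng=3)
    m0 = module_ratemaps(mod, n_bins=64)[0]
    rot = apply_scenario(mod, "coherent_rotation", alpha_deg=17.0)
    m1 = module_ratemaps(rot, n_bins=64)[0]
    assert grid_score(m1) == pytest.approx(grid_score(m0), abs=0.25)
    assert np.isnan(grid_score(np.ones((64, 64))))


def test_phase_shift_identity_and_constructed_displacement(ideal_maps):
    _, maps = ideal_maps
    np.testing.assert_allclose(phase_shift(maps[0], maps[0], bin_size=BIN),
                               [0.0, 0.0], atol=1e-12)
    # shift by exactly 2 bins in x: roll columns
    shifted = np.roll(maps[0], 2, axis=1)
    dx, dy = phase_shift(maps[0], shifted, bin_size=BIN)
    assert dx == pytest.approx(2 * BIN, abs=1e-9)
    assert dy == pytest.approx(0.0, abs=1e-9)


def test_phase_shift_antisymmetry(ideal_maps):
    mod, maps = ideal_maps
    shifted = apply_scenario(mod, "coherent_phase", delta=(0.11, -0.07))
    maps_b = module_ratemaps(shifted, n_bins=64)
    ab = phase_shift(maps[0], maps_b[0], bin_size=BIN)
    ba = phase_shift(maps_b[0], maps[0], bin_size=BIN)
    np.testing.assert_allclose(ab, -ba, atol=BIN)


def test_orientation_shift_identity_and_constructed(ideal_maps):
    mod, maps = ideal_maps
    acg0 = autocorrelogram(maps[0])
    assert orientation_shift(None, None, acg_a=acg0, acg_b=acg0) == 0.0
    rot = apply_scenario(mod, "coherent_rotation", alpha_deg=10.0)
    maps_b = module_ratemaps(rot, n_bins=64)
    shift = orientation_shift(maps[0], maps_b[0])
    assert shift == pytest.approx(10.0, abs=1.0)


def test_grid_spacing_analytic_and_scaling():
    for f in (0.8, 1.19, 2.0):
        m = module_ratemaps(make_module(1, f=f, rng=4), n_bins=64)[0]
        assert grid_spacing(m, bin_size=BIN) == pytest.approx(
            lattice_constant(f), abs=BIN)
    # doubling f halves the estimate
    s1 = grid_spacing(module_ratemaps(make_module(1, f=1.0, rng=5),
                                      n_bins=64)[0], bin_size=BIN)
    s2 = grid_spacing(module_ratemaps(make_module(1, f=2.0, rng=5),
                                      n_bins=64)[0], bin_size=BIN)
    assert s2 == pytest.approx(s1 / 2, abs=BIN)


def test_metric_triangle_reconstruction():
    """Estimated spacing, orientation and phase re-synthesise the pattern."""
    mod = make_module(1, f=1.19, theta=0.15, rng=6)
    m = module_ratemaps(mod, n_bins=64)[0]
    spacing = grid_spacing(m, bin_size=BIN)
    f_hat = 2.0 / (np.sqrt(3) * spacing)
    # orientation relative to an unrotated reference of the same frequency
    ref_mod = make_module(1, f=f_hat, theta=0.0, rng=7)
    ref_mod.phases[0] = mod.phases[0]
    ref = module_ratemaps(ref_mod, n_bins=64)[0]
    dtheta = np.deg2rad(orientation_shift(ref, m))
    resynth = eval_grid_cell(f_hat, dtheta, mod.phases[0],
                             _grid_positions())
    r = np.corrcoef(resynth.ravel(), m.ravel())[0, 1]
    assert r > 0.95


def _grid_positions():
    edges = np.linspace(-1.1, 1.1, 65)
    c = 0.5 * (edges[:-1] + edges[1:])
    gx, gy = np.meshgrid(c, c)
    return np.stack([gx, gy], -1)


@settings(deadline=None, max_examples=50)
@given(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False))
def test_wrap_orientation_law(shift):
    w = float(wrap_orientation(shift))
    assert -15.0 <= w < 15.0
    assert (shift - w) % 30.0 == pytest.approx(0.0, abs=1e-6) or \
        (shift - w) % 30.0 == pytest.approx(30.0, abs=1e-6)


def test_shift_density_coherence_contrast():
    rng = np.random.default_rng(8)
    coherent = np.full((200, 2), -0.2) + 0.01 * rng.standard_normal((200, 2))
    flat = rng.uniform(-0.5, 0.5, (200, 2))
    kde_c, _ = shift_density(coherent)
    kde_f, _ = shift_density(flat)
    assert kde_c([[-0.2], [-0.2]])[0] > 10 * kde_f([[0.0], [0.0]])[0]
    # normalization over a wide grid
    g = np.linspace(-1.5, 1.5, 61)
    gx, gy = np.meshgrid(g, g)
    vals = kde_f(np.stack([gx.ravel(), gy.ravel()]))
    integral = vals.sum() * (g[1] - g[0]) ** 2
    assert integral == pytest.approx(1.0, abs=0.05)
    with pytest.raises(ValueError):
        shift_density(np.zeros((1, 2)))
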