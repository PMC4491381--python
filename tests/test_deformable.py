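"""Force terms and contour evolution of the deformable model."""

import numpy as np
import pytest

from cinelv.core import polygon_area, rasterize
from cinelv.deformable import (
    DeformConfig,
    ForceWeights,
    _weights_allow_zero,
    coupling_forces,
    curvature_force,
    deform,
    edge_force_field,
    reparameterize_equidistant,
)
from cinelv.evaluation import dice

from conftest import circle_nodes


# ---------------------------------------------------------------------------
# edge force field
# ---------------------------------------------------------------------------

def test_edge_force_points_toward_step_edge():
    img = np.zeros((1, 1, 32, 32))
    img[..., :, 16:] = 100.0
    field = edge_force_field(img)
    fx = field[0, 0, 16, :, 0]
    # left of the edge: force points right (+x); right of it: left (-x)
    assert fx[12] > 0
    assert fx[19] < 0


def test_edge_force_zero_on_constant_image():
    img = np.full((1, 1, 16, 16), 55.0)
    field = edge_force_field(img)
    assert np.allclose(field, 0.0)


def test_edge_force_matches_finite_difference_oracle():
    rng = np.random.default_rng(0)
    img = rng.normal(100, 20, (1, 1, 24, 24))
    sigma = 1.5
    field = edge_force_field(img, sigma_px=sigma)
    # oracle: same pipeline with independent gradient implementation
    from scipy import ndimage as ndi

    g = ndi.gaussian_filter(img[0, 0], sigma)
    gx = ndi.gaussian_filter(img[0, 0], sigma, order=(0, 1))
    gy = ndi.gaussian_filter(img[0, 0], sigma, order=(1, 0))
    mag = np.hypot(gx, gy)
    oy = np.empty_like(mag)
    ox = np.empty_like(mag)
    ox[:, 1:-1] = (mag[:, 2:] - mag[:, :-2]) / 2
    ox[:, 0] = mag[:, 1] - mag[:, 0]
    ox[:, -1] = mag[:, -1] - mag[:, -2]
    oy[1:-1, :] = (mag[2:, :] - mag[:-2, :]) / 2
    oy[0, :] = mag[1, :] - mag[0, :]
    oy[-1, :] = mag[-1, :] - mag[-2, :]
    peak = max(np.abs(ox).max(), np.abs(oy).max())
    np.testing.assert_allclose(field[0, 0, ..., 0], ox / peak, atol=1e-6)
    np.testing.assert_allclose(field[0, 0, ..., 1], oy / peak, atol=1e-6)


# ---------------------------------------------------------------------------
# curvature force
# ---------------------------------------------------------------------------

def test_curvature_zero_on_straight_segment():
    nodes = np.column_stack([np.linspace(0, 10, 12), np.zeros(12)])
    force = curvature_force(nodes)
    # interior nodes of the straight run have zero force
    assert np.allclose(force[2:-2], 0.0, atol=1e-12)


def test_curvature_inward_on_polygon_scales_with_spacing():
    # fixed node spacing h: second difference ~ h^2 / r, inward
    h = 1.0
    for r in (10.0, 20.0):
        n = int(round(2 * np.pi * r / h))
        nodes = circle_nodes(0, 0, r, n)
        force = curvature_force(nodes)
        radial = -np.sum(force * (nodes / r), axis=1)  # inward positive
        assert np.all(radial > 0)
        assert np.mean(radial) == pytest.approx(h**2 / r, rel=0.05)


def test_curvature_matches_bruteforce_second_difference(rng):
    nodes = rng.normal(0, 5, (20, 2))
    force = curvature_force(nodes)
    n = len(nodes)
    oracle = np.array([
        nodes[(i + 1) % n] + nodes[(i - 1) % n] - 2 * nodes[i] for i in range(n)
    ])
    np.testing.assert_array_equal(force, oracle)


# ---------------------------------------------------------------------------
# coupling forces
# ---------------------------------------------------------------------------

def _state(radii_by_slice_frame):
    s, f = len(radii_by_slice_frame), len(radii_by_slice_frame[0])
    pos = np.zeros((s, f, 16, 2))
    for si in range(s):
        for fi in range(f):
            pos[si, fi] = circle_nodes(0, 0, radii_by_slice_frame[si][fi], 16)
    return pos


def test_coupling_zero_for_identical_contours():
    pos = _state([[10, 10, 10]] * 3)
    inter, temporal = coupling_forces(pos, np.ones((3, 3), dtype=bool))
    assert np.allclose(inter, 0.0)
    assert np.allclose(temporal, 0.0)


def test_temporal_force_restores_displaced_frame():
    pos = _state([[10, 12, 10, 10]])
    _, temporal = coupling_forces(pos, np.ones((1, 4), dtype=bool))
    # displaced frame 1 is pulled inward, proportional to the displacement
    radial = np.sum(temporal[0, 1] * pos[0, 1] / 12, axis=1)
    assert np.all(radial < 0)
    assert np.mean(radial) == pytest.approx(-4.0, rel=1e-6)  # 2*(10-12)


def test_interslice_force_zero_for_linear_taper_middle():
    pos = _state([[10], [12], [14]])
    inter, _ = coupling_forces(pos, np.ones((3, 1), dtype=bool))
    assert np.allclose(inter[1], 0.0, atol=1e-12)
    # edge slices get no inter-slice pull (single neighbour)
    assert np.allclose(inter[0], 0.0)
    assert np.allclose(inter[2], 0.0)


def test_single_slice_stack_has_zero_interslice():
    pos = _state([[10, 11]])
    inter, _ = coupling_forces(pos, np.ones((1, 2), dtype=bool))
    assert np.allclose(inter, 0.0)


# ---------------------------------------------------------------------------
# reparameterization
# ---------------------------------------------------------------------------

def test_reparameterize_idempotent_on_circle():
    nodes = circle_nodes(5, 5, 4, 64)
    out = reparameterize_equidistant(nodes)
    np.testing.assert_allclose(out, nodes, atol=1e-9)


def test_reparameterize_square_clustered_nodes():
    # clustered nodes plus the true corners (so the chain is the square)
    t = np.sort(np.concatenate([
        np.linspace(0, 0.1, 29, endpoint=False), [0.25, 0.5, 0.75]
    ]))
    # param the unit square boundary by t in [0,1)
    def sq(u):
        u = u % 1.0
        if u < 0.25:
            return (4 * u, 0.0)
        if u < 0.5:
            return (1.0, 4 * (u - 0.25))
        if u < 0.75:
            return (1 - 4 * (u - 0.5), 1.0)
        return (0.0, 1 - 4 * (u - 0.75))

    nodes = np.array([sq(u) for u in t]) * 10
    out = reparameterize_equidistant(nodes)
    seg = np.linalg.norm(np.diff(np.vstack([out, out[:1]]), axis=0), axis=1)
    assert seg.max() / seg.min() <= 1.01


# ---------------------------------------------------------------------------
# deform
# ---------------------------------------------------------------------------

def _disk_balloon(rows, cols, cx, cy, r):
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(xx - cx, yy - cy)
    return np.clip((r - d), -1, 1)[None, None]


def test_deform_recovers_bright_disk():
    """Half-radius circular init converges onto an analytic disk."""
    rows = cols = 64
    cx = cy = 32.0
    r = 14.0
    bal = _disk_balloon(rows, cols, cx, cy, r)
    init = circle_nodes(cx, cy, r / 2, 80)[None, None]
    present = np.ones((1, 1), dtype=bool)
    weights = ForceWeights(w_balloon=1.0, w_edge=0.0, w_curv_inplane=0.5,
                           w_curv_interslice=0.0, w_temporal=0.0, w_damping=1.0)
    final, report = deform(init, present, bal, None, weights)
    mask = rasterize(final[0, 0], (rows, cols))
    yy, xx = np.mgrid[0:rows, 0:cols]
    truth = np.hypot(xx - cx, yy - cy) <= r
    assert dice(mask, truth) >= 0.97


def test_deform_identity_with_only_damping():
    init = circle_nodes(20, 20, 8, 40)[None, None]
    weights = _weights_allow_zero(w_damping=1.0)
    final, report = deform(
        init, np.ones((1, 1), dtype=bool), np.zeros((1, 1, 40, 40)), None, weights
    )
    np.testing.assert_allclose(final, init, atol=1e-6)
    assert report.converged


def test_deform_uniform_balloon_expands_to_image_bounds():
    init = circle_nodes(20, 20, 5, 40)[None, None]
    weights = _weights_allow_zero(w_balloon=1.0, w_damping=1.0)
    bal = np.ones((1, 1, 41, 41))
    final, report = deform(
        init, np.ones((1, 1), dtype=bool), bal, None, weights,
        DeformConfig(max_iter=200, smooth_sigma_px=0.0),
    )
    assert abs(polygon_area(final[0, 0])) > abs(polygon_area(init[0, 0]))
    # expansion only stops at the image-bound clamp
    assert final[0, 0, :, 0].max() > 38.0
    assert final[0, 0, :, 0].min() < 2.0


def test_deform_keeps_nodes_equidistant():
    rows = cols = 64
    bal = _disk_balloon(rows, cols, 32, 32, 12)
    init = circle_nodes(32, 32, 6, 60)[None, None]
    weights = ForceWeights(w_balloon=1.0, w_curv_inplane=0.3, w_damping=1.0)
    final, _ = deform(init, np.ones((1, 1), dtype=bool), bal, None, weights)
    seg = np.linalg.norm(
        np.diff(np.vstack([final[0, 0], final[0, 0, :1]]), axis=0), axis=1
    )
    assert seg.max() / seg.min() <= 1.05


def test_deform_collapse_flagged():
    # uniformly negative balloon shrinks the contour to nothing
    init = circle_nodes(20, 20, 8, 40)[None, None]
    weights = _weights_allow_zero(w_balloon=1.0, w_damping=0.5)
    bal = -np.ones((1, 1, 41, 41))
    final, report = deform(
        init, np.ones((1, 1), dtype=bool), bal, None, weights,
        DeformConfig(max_iter=300, smooth_sigma_px=0.0),
    )
    assert report.collapsed[0, 0]


def test_force_weights_validate():
    with pytest.raises(ValueError):
        ForceWeights(w_balloon=-1.0)
    with pytest.raises(ValueError):
        ForceWeights(w_balloon=0.0, w_edge=0.0)
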