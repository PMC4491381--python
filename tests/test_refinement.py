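"""Papillary exclusion and outflow/long-axis detection."""

import math

import numpy as np
import pytest

from cinelv.core import CineStack, N_SECTORS, polygon_area, rasterize
from cinelv.deformable import ForceWeights
from cinelv.intensity import BalloonImage
from cinelv.refinement import (
    OutflowResult,
    _circular_runs,
    build_sector_grid,
    detect_outflow,
    exclude_attached_papillaries,
    exclude_detached_papillaries,
    papillary_sector_volumes,
)

from conftest import circle_nodes


def _stack(img4, spacing=(1.0, 1.0), dz=8.0):
    return CineStack(
        intensities=np.asarray(img4, dtype=float),
        pixel_spacing_mm=spacing,
        slice_spacing_mm=dz,
        frame_duration_ms=33.0,
        heart_rate_bpm=60.0,
    )


# ---------------------------------------------------------------------------
# Step 6: detached papillaries
# ---------------------------------------------------------------------------

def _cavity_with_blob(rows=64, cols=64, r_cav=18, blob_at=(40, 32), r_blob=3):
    """Balloon positive inside a disk cavity except for a papillary blob."""
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(xx - 32, yy - 32)
    bal = np.clip(r_cav - d, -1, 1)
    blob = np.hypot(xx - blob_at[0], yy - blob_at[1]) <= r_blob
    bal[blob] = -1.0
    return bal[None, None], blob


def test_detached_blob_included_after_hull_refinement():
    bal, blob = _cavity_with_blob()
    balloon = BalloonImage(values=bal, border="endo")
    # converged endo contour dents inward around the blob: emulate with the
    # actual deformable model
    from cinelv.deformable import deform

    weights = ForceWeights(w_balloon=1.0, w_curv_inplane=0.3, w_damping=1.0)
    init = circle_nodes(32, 32, 9, 80)[None, None]
    present = np.ones((1, 1), dtype=bool)
    dented, _ = deform(init, present, bal, None, weights)
    pre_mask = rasterize(dented[0, 0], (64, 64))
    refined, bal_mod, _ = exclude_detached_papillaries(
        dented, present, balloon, None, weights
    )
    post_mask = rasterize(refined[0, 0], (64, 64))
    assert (blob & post_mask).sum() == blob.sum()       # blob inside endo
    assert post_mask.sum() >= pre_mask.sum()            # volume grew
    # no negative balloon remains inside the hull
    hull_mask = rasterize(refined[0, 0], (64, 64))
    assert np.all(bal_mod[0, 0][hull_mask & blob] >= 0.0)


def test_detached_refinement_fixed_point_without_papillaries():
    bal, _ = _cavity_with_blob(r_blob=0)
    bal[0, 0] = np.clip(bal[0, 0], -1, 1)
    balloon = BalloonImage(values=bal, border="endo")
    from cinelv.deformable import deform

    weights = ForceWeights(w_balloon=1.0, w_curv_inplane=0.3, w_damping=1.0)
    init = circle_nodes(32, 32, 9, 80)[None, None]
    present = np.ones((1, 1), dtype=bool)
    converged, _ = deform(init, present, bal, None, weights)
    refined, bal_mod, _ = exclude_detached_papillaries(
        converged, present, balloon, None, weights
    )
    a = rasterize(converged[0, 0], (64, 64))
    b = rasterize(refined[0, 0], (64, 64))
    assert (a ^ b).sum() <= 0.02 * a.sum()


# ---------------------------------------------------------------------------
# Step 7: sector grid
# ---------------------------------------------------------------------------

def test_sector_grid_concentric_circles_uniform_thickness():
    img = np.full((1, 1, 64, 64), 150.0)
    stack = _stack(img, spacing=(1.0, 1.0))
    endo = circle_nodes(32, 32, 20, 80)[None, None]
    epi = circle_nodes(32, 32, 25, 80)[None, None]
    present = np.ones((1, 1), dtype=bool)
    grid = build_sector_grid(endo, epi, present, stack)
    assert np.allclose(grid.thickness_mm[0, 0], 5.0, atol=0.15)
    assert grid.valid[0, 0].all()
    assert np.allclose(grid.intensity[0, 0], 150.0)


def test_sector_grid_zero_thickness_flagged_invalid():
    img = np.full((1, 1, 64, 64), 150.0)
    stack = _stack(img)
    endo = circle_nodes(32, 32, 20, 80)[None, None]
    grid = build_sector_grid(endo, endo.copy(), np.ones((1, 1), bool), stack)
    assert np.allclose(grid.thickness_mm[0, 0], 0.0, atol=1e-6)
    assert not grid.valid[0, 0].any()


def test_sector_intensity_matches_bruteforce_binning(rng):
    img = rng.uniform(50, 250, (1, 1, 64, 64))
    stack = _stack(img)
    endo = circle_nodes(31.7, 32.2, 14, 80)[None, None]
    epi = circle_nodes(31.7, 32.2, 22, 80)[None, None]
    present = np.ones((1, 1), dtype=bool)
    origin = math.pi
    grid = build_sector_grid(endo, epi, present, stack, origin_angle=origin)
    wall = rasterize(epi[0, 0], (64, 64)) & ~rasterize(endo[0, 0], (64, 64))
    ys, xs = np.nonzero(wall)
    centroid = endo[0, 0].mean(axis=0)
    ang = np.arctan2(ys - centroid[1], xs - centroid[0])
    sector = np.floor(np.mod(ang - origin, 2 * np.pi)
                      / (2 * np.pi / N_SECTORS)).astype(int) % N_SECTORS
    for k in range(N_SECTORS):
        sel = sector == k
        if sel.any():
            assert grid.intensity[0, 0, k] == pytest.approx(
                img[0, 0, ys[sel], xs[sel]].mean(), rel=1e-9
            )


# ---------------------------------------------------------------------------
# Step 7: outflow detection on constructed grids
# ---------------------------------------------------------------------------

def _annulus_stack(n_slices, n_frames, rows=64, cols=64, wall_val=150.0,
                   arc_sectors=(), arc_val=300.0, origin=math.pi):
    """Wall annulus with optional blood-bright sectors in every slice."""
    img = np.full((n_slices, n_frames, rows, cols), 80.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(xx - 32, yy - 32)
    ring = (d >= 14) & (d <= 22)
    ang = np.arctan2(yy - 32, xx - 32)
    sector = np.floor(np.mod(ang - origin, 2 * np.pi)
                      / (2 * np.pi / N_SECTORS)).astype(int) % N_SECTORS
    for s in range(n_slices):
        for f in range(n_frames):
            frame = img[s, f]
            frame[ring] = wall_val
            frame[d < 14] = 300.0
            if s < 2:  # arc only in the two most basal slices
                for k in arc_sectors:
                    frame[ring & (sector == k)] = arc_val
    return _stack(img)


def _grid_and_contours(stack):
    s, f = stack.intensities.shape[:2]
    endo = np.broadcast_to(circle_nodes(32, 32, 14, 80), (s, f, 80, 2)).copy()
    epi = np.broadcast_to(circle_nodes(32, 32, 22, 80), (s, f, 80, 2)).copy()
    present = np.ones((s, f), dtype=bool)
    grid = build_sector_grid(endo, epi, present, stack)
    return grid, endo, epi, present


def test_outflow_blood_arc_flagged_and_chord_drawn():
    stack = _annulus_stack(5, 4, arc_sectors=(2, 3, 4, 5))
    grid, endo, epi, present = _grid_and_contours(stack)
    out = detect_outflow(grid, stack, endo, epi, present, ed_frame=0)
    # the bright sectors are flagged in the basal slices
    assert out.flags[0, 0, 3]
    assert out.flags[1, 0, 3]
    assert not out.flags[2:].any()  # arc absent below the basal band
    # adjusted contour: smaller area, contains a straight chord
    a_before = abs(polygon_area(endo[0, 0]))
    a_after = abs(polygon_area(out.endo_nodes[0, 0]))
    assert a_after < a_before
    # collinearity of the adjusted nodes inside the arc
    adj = out.endo_nodes[0, 0]
    moved = np.linalg.norm(adj - endo[0, 0], axis=1) > 0.5
    assert moved.sum() >= 3
    pts = adj[moved]
    d = pts[-1] - pts[0]
    rel = pts - pts[0]
    cross = np.abs(d[0] * rel[:, 1] - d[1] * rel[:, 0]) / np.linalg.norm(d)
    assert np.max(cross) < 0.5


def test_outflow_no_flags_on_uniform_wall():
    stack = _annulus_stack(5, 4)
    grid, endo, epi, present = _grid_and_contours(stack)
    out = detect_outflow(grid, stack, endo, epi, present, ed_frame=0)
    assert not out.flags.any()
    assert np.all(out.longaxis_displacement == 0)


def test_outflow_isolated_nonbasal_flag_blocked():
    # a bright arc only in a NON-basal slice must not be flagged
    stack = _annulus_stack(5, 4)
    yy, xx = np.mgrid[0:64, 0:64]
    d = np.hypot(xx - 32, yy - 32)
    ring = (d >= 14) & (d <= 22)
    ang = np.arctan2(yy - 32, xx - 32)
    sector = np.floor(np.mod(ang - math.pi, 2 * np.pi)
                      / (2 * np.pi / N_SECTORS)).astype(int) % N_SECTORS
    img = stack.intensities.copy()
    img[3, :, ring & np.isin(sector, (2, 3, 4))] = 300.0
    stack2 = _stack(img)
    grid, endo, epi, present = _grid_and_contours(stack2)
    out = detect_outflow(grid, stack2, endo, epi, present, ed_frame=0)
    assert not out.flags[3].any()


def test_outflow_flags_form_single_contiguous_arc(outflow_run):
    _, _, result, _ = outflow_run
    for s in range(result.n_slices):
        for f in range(result.n_frames):
            flags = result.outflow_flags[s, f]
            if flags.any() and not flags.all():
                assert len(_circular_runs(flags)) == 1


def test_outflow_monotone_basal_propagation(outflow_run):
    _, _, result, _ = outflow_run
    flags = result.outflow_flags
    for s in range(1, result.n_slices):
        for f in range(result.n_frames):
            # any flagged sector must also be flagged one slice more basally
            assert not np.any(flags[s, f] & ~flags[s - 1, f])


# ---------------------------------------------------------------------------
# Step 8: attached papillaries
# ---------------------------------------------------------------------------

def _attached_setup():
    """Three slices, two frames; papillary volume deficit in frame 1."""
    rows = cols = 64
    n_s, n_f = 3, 2
    img = np.full((n_s, n_f, rows, cols), 150.0)
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(xx - 32, yy - 32)
    img[:, :, d < 14] = 300.0
    stack = _stack(img)
    bal = np.where(img > 220, 1.0, -1.0)
    endo = np.broadcast_to(circle_nodes(32, 32, 14, 80), (n_s, n_f, 80, 2)).copy()
    epi = np.broadcast_to(circle_nodes(32, 32, 22, 80), (n_s, n_f, 80, 2)).copy()
    present = np.ones((n_s, n_f), dtype=bool)
    # ED (frame 0): the segmentation bulges outward in one sector, holding
    # papillary (negative-balloon) volume; frame 1 lost that bulge
    origin = math.pi
    ang = np.arctan2(endo[0, 0, :, 1] - 32, endo[0, 0, :, 0] - 32)
    in_sector = np.floor(np.mod(ang - origin, 2 * np.pi)
                         / (2 * np.pi / N_SECTORS)).astype(int) == 6
    bulge = endo[1, 0].copy()
    unit = (bulge - [32, 32]) / np.linalg.norm(bulge - [32, 32], axis=1,
                                               keepdims=True)
    bulge[in_sector] += 3.0 * unit[in_sector]  # within the expansion cap
    endo[1, 0] = bulge
    outflow = OutflowResult(
        flags=np.zeros((n_s, n_f, N_SECTORS), dtype=bool),
        longaxis_displacement=np.zeros(n_f, dtype=int),
        endo_nodes=endo, epi_nodes=epi, present=present, n_basal=1,
    )
    return stack, bal, endo, epi, present, outflow, origin


def test_attached_expansion_restores_sector_volume():
    stack, bal, endo, epi, present, outflow, origin = _attached_setup()
    vols_before = papillary_sector_volumes(endo, present, bal, stack, origin)
    assert vols_before[1, 0, 6] > 60.0       # ED reference exists
    assert vols_before[1, 1, 6] < 10.0       # systolic deficit
    adj, clamped = exclude_attached_papillaries(
        endo, epi, present, bal, stack, origin, outflow, ed_frame=0,
    )
    vols_after = papillary_sector_volumes(adj, present, bal, stack, origin)
    assert vols_after[1, 1, 6] >= 0.85 * vols_before[1, 0, 6]


def test_attached_ed_frame_unchanged():
    stack, bal, endo, epi, present, outflow, origin = _attached_setup()
    adj, _ = exclude_attached_papillaries(
        endo, epi, present, bal, stack, origin, outflow, ed_frame=0,
    )
    np.testing.assert_array_equal(adj[:, 0], endo[:, 0])


def test_attached_basal_outflow_slices_untouched():
    stack, bal, endo, epi, present, outflow, origin = _attached_setup()
    # create a deficit in the basal slice 0 too: it must not be expanded
    adj, _ = exclude_attached_papillaries(
        endo, epi, present, bal, stack, origin, outflow, ed_frame=0,
    )
    np.testing.assert_array_equal(adj[0], endo[0])


def test_attached_never_decreases_area_or_moves_other_sectors():
    stack, bal, endo, epi, present, outflow, origin = _attached_setup()
    adj, _ = exclude_attached_papillaries(
        endo, epi, present, bal, stack, origin, outflow, ed_frame=0,
    )
    for s in range(3):
        for f in range(2):
            assert abs(polygon_area(adj[s, f])) >= abs(
                polygon_area(endo[s, f])
            ) - 1e-9
    # frame 1 slice 1: only sector-6 nodes (and the deficit sector band)
    moved = np.linalg.norm(adj[1, 1] - endo[1, 1], axis=1) > 1e-9
    ang = np.arctan2(endo[1, 1, moved, 1] - 32, endo[1, 1, moved, 0] - 32)
    sector = np.floor(np.mod(ang - origin, 2 * np.pi)
                      / (2 * np.pi / N_SECTORS)).astype(int)
    assert set(sector.tolist()) <= {5, 6, 7}
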