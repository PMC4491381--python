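"""Post-processing of the deformable-model output: papillary-muscle
exclusion and outflow-tract / long-axis-motion detection.

Papillary muscles have myocardial intensity but are excluded from the wall
by clinical convention. Detached papillaries (surrounded by blood) are
recovered by taking the convex hull of the endocardial contour, zeroing the
negative balloon force inside it, and re-running the deformable model.
Attached papillaries are recovered by assuming their volume is constant
over the cycle and expanding sectors whose papillary volume dropped below
the end-diastolic reference.

The outflow tract and the through-plane long-axis motion are detected on a
24-sector circumferential grid in the basal slices: sectors whose wall is
too bright (blood where wall should be) or thinner than 2 mm are removed,
and the removed arc is closed with a straight chord, giving the
characteristic D-shaped basal contour. A basal slice whose entire
circumference is removed has left the imaging plane; counting such slices
per frame (relative to end-diastole) yields the long-axis displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .core import (
    CineStack,
    N_SECTORS,
    anchor_start,
    ensure_ccw,
    rasterize,
    resample_closed,
)
from .deformable import DeformConfig, ForceWeights, deform
from .intensity import BalloonImage

SECTOR_WIDTH = 2.0 * math.pi / N_SECTORS


@dataclass
class SectorGrid:
    """Per-sector wall statistics on the 24-sector circumferential grid.

    Sector 0 starts at ``origin_angle`` (the septal direction, pointing
    from the LV centroid toward the RV blood pool) and sectors advance
    counter-clockwise in (x, y).
    """

    intensity: np.ndarray       # (S, F, 24) mean wall intensity
    thickness_mm: np.ndarray    # (S, F, 24) mean radial wall thickness
    valid: np.ndarray           # (S, F, 24) sector has wall pixels
    origin_angle: float = math.pi
    remove: np.ndarray | None = None


@dataclass
class OutflowResult:
    flags: np.ndarray                 # (S, F, 24) bool
    longaxis_displacement: np.ndarray  # (F,) int
    endo_nodes: np.ndarray
    epi_nodes: np.ndarray
    present: np.ndarray               # (S, F) after removal of empty slices
    n_basal: int = 0
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _polar_radius(nodes_mm: np.ndarray, centroid_mm: np.ndarray,
                  angles: np.ndarray) -> np.ndarray:
    """Radius of a closed chain at given angles around a centroid.

    Linear interpolation in angle between node samples; valid for
    star-shaped contours (which deformable-model outputs are in practice).
    """
    rel = nodes_mm - centroid_mm
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    r = np.hypot(rel[:, 0], rel[:, 1])
    order = np.argsort(ang)
    ang_s = ang[order]
    r_s = r[order]
    ang_ext = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
    r_ext = np.concatenate([r_s, r_s, r_s])
    q = np.mod(angles + np.pi, 2 * np.pi) - np.pi
    return np.interp(q, ang_ext, r_ext)


def _sector_of(angles: np.ndarray, origin: float) -> np.ndarray:
    return (np.floor(np.mod(angles - origin, 2 * np.pi) / SECTOR_WIDTH)
            .astype(np.int64) % N_SECTORS)


def _to_mm(nodes: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    sr, sc = spacing
    return nodes * np.asarray([sc, sr])


def _circular_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True on a circular 24-vector as (start, length)."""
    n = flags.size
    if flags.all():
        return [(0, n)]
    if not flags.any():
        return []
    # rotate so position 0 is False, then find linear runs
    start0 = int(np.argmin(flags))
    rolled = np.roll(flags, -start0)
    runs = []
    in_run = False
    for i in range(n):
        if rolled[i] and not in_run:
            in_run = True
            run_start = i
        elif not rolled[i] and in_run:
            in_run = False
            runs.append(((run_start + start0) % n, i - run_start))
    if in_run:
        runs.append(((run_start + start0) % n, n - run_start))
    return runs


# ---------------------------------------------------------------------------
# Step 6: detached papillaries
# ---------------------------------------------------------------------------

def exclude_detached_papillaries(
    endo_nodes: np.ndarray,
    present: np.ndarray,
    balloon: BalloonImage,
    edge_field: np.ndarray | None,
    weights: ForceWeights,
    config: DeformConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, object]:
    """Convex-hull the endocardial contours, zero the negative balloon
    force inside each hull, and re-run the deformable model.

    Detached papillary blobs (negative balloon inside the hull) stop
    repelling the contour and end up inside the refined segmentation.
    Returns (refined nodes, modified balloon values, deform report).
    """
    s, f = present.shape
    grid_shape = balloon.values.shape[2:]
    hulled = np.array(endo_nodes, copy=True)
    bal_mod = np.array(balloon.values, copy=True)
    for si in range(s):
        for fi in range(f):
            if not present[si, fi]:
                continue
            nodes = endo_nodes[si, fi]
            try:
                hull = ConvexHull(nodes)
                verts = ensure_ccw(nodes[hull.vertices])
            except Exception:
                verts = nodes
            hulled[si, fi] = anchor_start(
                resample_closed(verts, nodes.shape[0])
            )
            mask = rasterize(hulled[si, fi], grid_shape)
            inside_neg = mask & (bal_mod[si, fi] < 0)
            bal_mod[si, fi][inside_neg] = 0.0
    refined, report = deform(
        hulled, present, bal_mod, edge_field, weights, config
    )
    return refined, bal_mod, report


# ---------------------------------------------------------------------------
# Step 7: sector grid and outflow detection
# ---------------------------------------------------------------------------

def build_sector_grid(
    endo_nodes: np.ndarray,
    epi_nodes: np.ndarray,
    present: np.ndarray,
    stack: CineStack,
    origin_angle: float = math.pi,
    rays_per_sector: int = 10,
) -> SectorGrid:
    """Per-sector mean wall intensity and mean radial wall thickness.

    The wall is the region between the endo and epi contours; intensity is
    averaged over wall pixels binned by angle around the endo centroid,
    thickness over radial rays (all geometry in mm). Sectors without wall
    pixels are marked invalid and get thickness 0.
    """
    s, f = present.shape
    spacing = stack.pixel_spacing_mm
    sr, sc = spacing
    grid_shape = stack.grid_shape
    intensity = np.full((s, f, N_SECTORS), np.nan)
    thickness = np.zeros((s, f, N_SECTORS))
    valid = np.zeros((s, f, N_SECTORS), dtype=bool)
    slice0 = stack.analyzed_slice_range[0]
    n_rays = N_SECTORS * rays_per_sector
    ray_angles = origin_angle + (np.arange(n_rays) + 0.5) * (2 * np.pi / n_rays)
    ray_sector = np.repeat(np.arange(N_SECTORS), rays_per_sector)
    for si in range(s):
        for fi in range(f):
            if not present[si, fi]:
                continue
            endo_mm = _to_mm(endo_nodes[si, fi], spacing)
            epi_mm = _to_mm(epi_nodes[si, fi], spacing)
            centroid = endo_mm.mean(axis=0)
            r_endo = _polar_radius(endo_mm, centroid, ray_angles)
            r_epi = _polar_radius(epi_mm, centroid, ray_angles)
            gap = np.maximum(r_epi - r_endo, 0.0)
            for k in range(N_SECTORS):
                thickness[si, fi, k] = gap[ray_sector == k].mean()
            try:
                epi_mask = rasterize(epi_nodes[si, fi], grid_shape)
                endo_mask = rasterize(endo_nodes[si, fi], grid_shape)
            except Exception:
                continue
            wall = epi_mask & ~endo_mask
            ys, xs = np.nonzero(wall)
            if ys.size == 0:
                continue
            px_mm = np.column_stack([xs * sc, ys * sr])
            ang = np.arctan2(px_mm[:, 1] - centroid[1], px_mm[:, 0] - centroid[0])
            sectors = _sector_of(ang, origin_angle)
            vals = stack.intensities[si + slice0, fi, ys, xs]
            for k in range(N_SECTORS):
                sel = sectors == k
                if sel.any():
                    intensity[si, fi, k] = vals[sel].mean()
                    valid[si, fi, k] = True
    return SectorGrid(
        intensity=intensity,
        thickness_mm=thickness,
        valid=valid,
        origin_angle=origin_angle,
    )


def _majority_circular(flags: np.ndarray, axis: int) -> np.ndarray:
    """3-tap majority filter with cyclic wrap along the given axis."""
    a = flags.astype(np.int8)
    total = a + np.roll(a, 1, axis=axis) + np.roll(a, -1, axis=axis)
    return total >= 2


def _open_sectors(flags: np.ndarray) -> np.ndarray:
    """Morphological opening with a 2-sector structuring element (cyclic)."""
    eroded = flags & np.roll(flags, -1, axis=-1)
    return eroded | np.roll(eroded, 1, axis=-1)


def _enforce_basal_propagation(flags: np.ndarray) -> np.ndarray:
    """A sector may only be removed if it is also removed more basally.

    The most basal analyzed slice is exempt; below it the flags are
    intersected cumulatively with the adjacent more basal slice.
    """
    out = flags.copy()
    for si in range(1, out.shape[0]):
        out[si] &= out[si - 1]
    return out


def detect_outflow(
    grid: SectorGrid,
    stack: CineStack,
    endo_nodes: np.ndarray,
    epi_nodes: np.ndarray,
    present: np.ndarray,
    ed_frame: int,
    basal_fraction: float = 0.4,
    intensity_sd_mult: float = 2.0,
    thickness_min_mm: float = 2.0,
) -> OutflowResult:
    """Flag basal outflow/through-plane sectors and adjust the contours.

    Basal slices are the most basal 40% of the end-diastolic ventricular
    length (slice-count reading). A basal sector is flagged when its mean
    wall intensity is more than 2 SD above the mean of all wall sectors
    pooled over every analyzed slice and frame, or when its mean wall
    thickness falls below 2 mm. Flags must be supported by the adjacent
    more basal slice, are smoothed circumferentially and over time
    (3-tap majority filters), opened with a 2-sector element, and reduced
    to a single contiguous arc capped at 180 degrees. The flagged arc is
    replaced on both contours by the straight chord connecting its
    endpoints; a slice/frame whose full circumference is flagged is
    removed, and the per-frame count of removed basal slices relative to
    end-diastole is the long-axis displacement.
    """
    s, f = present.shape
    n_basal = math.ceil(basal_fraction * s)
    pooled = grid.intensity[grid.valid & present[..., None]]
    mu = float(np.nanmean(pooled)) if pooled.size else 0.0
    sd = float(np.nanstd(pooled)) if pooled.size else 0.0
    raw = np.zeros((s, f, N_SECTORS), dtype=bool)
    basal = np.arange(s) < n_basal
    with np.errstate(invalid="ignore"):
        too_bright = grid.intensity > mu + intensity_sd_mult * sd
    too_bright = np.where(np.isnan(grid.intensity), False, too_bright)
    too_thin = grid.thickness_mm < thickness_min_mm
    raw = (too_bright | too_thin) & basal[:, None, None] & present[..., None]
    flags = _enforce_basal_propagation(raw)
    flags = _majority_circular(flags, axis=-1)             # circumferential
    flags = np.moveaxis(
        _majority_circular(np.moveaxis(flags, 1, -1), axis=-1), -1, 1
    )                                                       # temporal
    flags = _open_sectors(flags)
    flags = _enforce_basal_propagation(flags)
    flags &= basal[:, None, None] & present[..., None]

    warnings: list[str] = []
    endo_adj = np.array(endo_nodes, copy=True)
    epi_adj = np.array(epi_nodes, copy=True)
    present_adj = np.array(present, copy=True)
    spacing = stack.pixel_spacing_mm
    scale = np.asarray([spacing[1], spacing[0]])
    for si in range(s):
        for fi in range(f):
            if not present[si, fi] or not flags[si, fi].any():
                continue
            runs = _circular_runs(flags[si, fi])
            if len(runs) > 1:
                runs.sort(key=lambda r: -r[1])
                flags[si, fi] = False
                start, length = runs[0]
                idx = (start + np.arange(length)) % N_SECTORS
                flags[si, fi][idx] = True
            start, length = _circular_runs(flags[si, fi])[0]
            if length >= N_SECTORS:
                present_adj[si, fi] = False
                continue
            if length > N_SECTORS // 2:
                warnings.append(
                    f"slice {si} frame {fi}: flagged arc {length * 15} deg "
                    "capped at 180 deg"
                )
                drop = length - N_SECTORS // 2
                idx = (start + length - 1 - np.arange(drop)) % N_SECTORS
                flags[si, fi][idx] = False
                length = N_SECTORS // 2
            theta_a = grid.origin_angle + start * SECTOR_WIDTH
            theta_b = theta_a + length * SECTOR_WIDTH
            endo_mm = _to_mm(endo_nodes[si, fi], spacing)
            centroid = endo_mm.mean(axis=0)
            for nodes_adj, nodes in (
                (endo_adj, endo_nodes),
                (epi_adj, epi_nodes),
            ):
                mm = _to_mm(nodes[si, fi], spacing)
                rel = mm - centroid
                ang = np.arctan2(rel[:, 1], rel[:, 0])
                off = np.mod(ang - theta_a, 2 * np.pi)
                span = theta_b - theta_a
                in_arc = off < span
                r_a = _polar_radius(mm, centroid, np.asarray([theta_a]))[0]
                r_b = _polar_radius(mm, centroid, np.asarray([theta_b]))[0]
                pa = centroid + r_a * np.asarray([np.cos(theta_a), np.sin(theta_a)])
                pb = centroid + r_b * np.asarray([np.cos(theta_b), np.sin(theta_b)])
                frac = (off[in_arc] / span)[:, None]
                chord = pa[None, :] + frac * (pb - pa)[None, :]
                new_mm = mm.copy()
                new_mm[in_arc] = chord
                nodes_adj[si, fi] = new_mm / scale

    removed_basal = (~present_adj & present)[:n_basal]
    removed_count = removed_basal.sum(axis=0)  # (F,)
    displacement = np.maximum(removed_count - removed_count[ed_frame], 0)
    return OutflowResult(
        flags=flags,
        longaxis_displacement=displacement.astype(np.int64),
        endo_nodes=endo_adj,
        epi_nodes=epi_adj,
        present=present_adj,
        n_basal=n_basal,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Step 8: attached papillaries
# ---------------------------------------------------------------------------

def papillary_sector_volumes(
    endo_nodes: np.ndarray,
    present: np.ndarray,
    balloon_values: np.ndarray,
    stack: CineStack,
    origin_angle: float,
) -> np.ndarray:
    """Volume (mm^3) of negative-balloon pixels inside the endocardial
    contour, per 24-sector bin around the endo centroid.

    Uses the *original* endocardial balloon (before any papillary zeroing)
    so papillary tissue keeps its negative signature.
    """
    s, f = present.shape
    spacing = stack.pixel_spacing_mm
    sr, sc = spacing
    voxel = stack.pixel_area_mm2 * stack.slice_spacing_mm
    vols = np.zeros((s, f, N_SECTORS))
    for si in range(s):
        for fi in range(f):
            if not present[si, fi]:
                continue
            try:
                mask = rasterize(endo_nodes[si, fi], stack.grid_shape)
            except Exception:
                continue
            neg = mask & (balloon_values[si, fi] < 0)
            ys, xs = np.nonzero(neg)
            if ys.size == 0:
                continue
            endo_mm = _to_mm(endo_nodes[si, fi], spacing)
            centroid = endo_mm.mean(axis=0)
            ang = np.arctan2(ys * sr - centroid[1], xs * sc - centroid[0])
            sectors = _sector_of(ang, origin_angle)
            counts = np.bincount(sectors, minlength=N_SECTORS)
            vols[si, fi] = counts * voxel
    return vols


def exclude_attached_papillaries(
    endo_nodes: np.ndarray,
    epi_nodes: np.ndarray,
    present: np.ndarray,
    balloon_values: np.ndarray,
    stack: CineStack,
    origin_angle: float,
    outflow: OutflowResult,
    ed_frame: int,
    volume_tol: float = 0.10,
    step_mm: float = 0.25,
    cap_mm: float = 3.0,
    min_reference_mm3: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand sectors whose papillary volume dropped below end-diastole.

    For every slice below the outflow region, the per-sector volume of
    negative-balloon tissue inside the endocardium is compared to the
    end-diastolic reference of the corresponding slice (mapped through the
    long-axis displacement). Deficit sectors are expanded outward in small
    radial steps (capped) until the volumes match within tolerance; the
    expansion is clamped half a pixel inside the epicardium. Returns the
    adjusted endo nodes and a (S, F) bool array of clamped slice/frames.
    """
    s, f = present.shape
    spacing = stack.pixel_spacing_mm
    sr, sc = spacing
    scale = np.asarray([sc, sr])
    vols = papillary_sector_volumes(
        endo_nodes, present, balloon_values, stack, origin_angle
    )
    disp = outflow.longaxis_displacement
    n_basal = outflow.n_basal
    endo_adj = np.array(endo_nodes, copy=True)
    clamped = np.zeros((s, f), dtype=bool)
    max_steps = int(round(cap_mm / step_mm))
    for fi in range(f):
        if fi == ed_frame:
            continue
        for si in range(n_basal, s):
            if not present[si, fi]:
                continue
            s_ed = si - int(disp[fi])
            if not (0 <= s_ed < s) or not present[s_ed, ed_frame]:
                continue
            ref = vols[s_ed, ed_frame]
            cur = vols[si, fi].copy()
            deficit = (ref > min_reference_mm3) & (cur < (1 - volume_tol) * ref)
            if not deficit.any():
                continue
            nodes_mm = _to_mm(endo_adj[si, fi], spacing)
            centroid = nodes_mm.mean(axis=0)
            rel = nodes_mm - centroid
            ang = np.arctan2(rel[:, 1], rel[:, 0])
            node_sector = _sector_of(ang, origin_angle)
            epi_mm = _to_mm(epi_nodes[si, fi], spacing)
            r_epi = _polar_radius(epi_mm, centroid, ang)
            r_cap = r_epi - 0.5 * min(sr, sc)
            r = np.hypot(rel[:, 0], rel[:, 1])
            unit = rel / np.maximum(r[:, None], 1e-9)
            for _ in range(max_steps):
                todo = deficit & (cur < (1 - volume_tol) * ref)
                if not todo.any():
                    break
                move = todo[node_sector]
                if not move.any():
                    break
                r_new = np.where(move, np.minimum(r + step_mm, r_cap), r)
                if np.all(r_new <= r + 1e-12):
                    clamped[si, fi] = True
                    break
                r = r_new
                nodes_mm = centroid + unit * r[:, None]
                endo_adj[si, fi] = nodes_mm / scale
                cur = papillary_sector_volumes(
                    endo_adj[si : si + 1, fi : fi + 1],
                    present[si : si + 1, fi : fi + 1],
                    balloon_values[si : si + 1, fi : fi + 1],
                    stack,
                    origin_angle,
                )[0, 0]
            if np.any(r >= r_cap - 1e-9):
                clamped[si, fi] |= bool(
                    np.any((r >= r_cap - 1e-9) & deficit[node_sector])
                )
    return endo_adj, clamped
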