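"""Initialization of the deformable model from the endocardial balloon.

The endocardial balloon image thresholded at zero yields blood-like
regions. The connected region around the LV center is the blood pool; its
convex hull approximates the endocardial border with papillaries excluded.
Expanding the hull by half the estimated wall thickness gives the
endocardial (midmural) initialization, by a full wall thickness the
epicardial initialization. Wall thickness itself comes from the distance
between the hull and the right-ventricular blood pool across the septum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .core import (
    DEFAULT_NODE_COUNT,
    anchor_start,
    ensure_ccw,
    resample_closed,
    outward_normals,
)
from .errors import StageError
from .intensity import BalloonImage

WALL_FALLBACK_MM = 8.0
WALL_CAP_MM = (2.0, 25.0)


@dataclass
class WallThicknessEstimate:
    """Per-frame wall thickness in mm, capped to a physiologic range."""

    thickness_mm: np.ndarray  # (n_frames,)
    fallback_used: bool = False

    def __post_init__(self):
        t = np.asarray(self.thickness_mm, dtype=np.float64)
        self.thickness_mm = np.clip(t, *WALL_CAP_MM)


def blood_pool_mask(
    balloon: BalloonImage,
    lv_center: tuple[float, float],
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
    search_radius_mm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Connected component of {balloon > 0} containing the LV center.

    If the center pixel itself is non-positive (a papillary can sit right
    on it) the positive component nearest to the center within the search
    radius is used instead.

    Returns ``(masks, empty_flags)`` with masks shaped like the balloon and
    a per-(slice, frame) flag for slice/frames with no positive region.
    """
    values = balloon.values
    s, f = values.shape[:2]
    x0, y0 = lv_center
    masks = np.zeros_like(values, dtype=bool)
    empty = np.zeros((s, f), dtype=bool)
    sr, sc = pixel_spacing_mm
    for si in range(s):
        for fi in range(f):
            pos = values[si, fi] > 0
            if not pos.any():
                empty[si, fi] = True
                continue
            labels, _ = ndimage.label(pos)
            lab = labels[int(round(y0)), int(round(x0))]
            if lab == 0:
                ys, xs = np.nonzero(pos)
                d2 = ((xs - x0) * sc) ** 2 + ((ys - y0) * sr) ** 2
                k = int(np.argmin(d2))
                if d2[k] > search_radius_mm**2:
                    empty[si, fi] = True
                    continue
                lab = labels[ys[k], xs[k]]
            masks[si, fi] = labels == lab
    return masks, empty


def initial_endo_estimate(
    mask: np.ndarray, n_nodes: int = DEFAULT_NODE_COUNT
) -> np.ndarray:
    """Convex hull of the blood-pool pixel centers as a closed node chain.

    Returns an ``(n_nodes, 2)`` CCW chain resampled to equal arc length,
    anchored at the +x direction from the hull centroid.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size < 4:
        raise StageError("initialization", f"blood pool has {xs.size} pixels (< 4)")
    pts = np.column_stack([xs, ys]).astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except Exception as exc:  # collinear pixel sets
        raise StageError("initialization", f"degenerate blood pool: {exc}") from exc
    verts = ensure_ccw(pts[hull.vertices])
    return anchor_start(resample_closed(verts, n_nodes))


def estimate_wall_thickness(
    endo_estimates: np.ndarray,
    present: np.ndarray,
    balloon: BalloonImage,
    lv_pool_masks: np.ndarray,
    lv_center: tuple[float, float],
    pixel_spacing_mm: tuple[float, float],
    fallback_mm: float = WALL_FALLBACK_MM,
    facing_max_mm: float = 25.0,
) -> WallThicknessEstimate:
    """Wall thickness per frame from the distance to the RV blood pool.

    Per frame the largest positive-balloon component to the image-left of
    the LV (excluding the LV pool itself) is taken as the RV pool on the
    mid-ventricular slice. Each node of the initial endocardial curve is
    assigned its distance to the nearest RV-pool pixel; the thickness is
    the mean over the septal (RV-facing) nodes — those within 3 mm of the
    closest approach. An RV further than ``facing_max_mm`` from the curve
    does not count; frames (or whole stacks) without a usable RV fall back
    to a fixed thickness and set ``fallback_used``.
    """
    s, f = present.shape
    sr, sc = pixel_spacing_mm
    x0, _ = lv_center
    mid = s // 2
    out = np.full(f, np.nan)
    for fi in range(f):
        if not present[mid, fi]:
            continue
        pos = (balloon.values[mid, fi] > 0) & ~lv_pool_masks[mid, fi]
        labels, n = ndimage.label(pos)
        best_lab, best_area = 0, 0
        for lab in range(1, n + 1):
            comp = labels == lab
            area = int(comp.sum())
            if area < 10:
                continue
            cy, cx = ndimage.center_of_mass(comp)
            if cx < x0 and area > best_area:
                best_lab, best_area = lab, area
        if best_lab == 0:
            continue
        ys, xs = np.nonzero(labels == best_lab)
        nodes = endo_estimates[mid, fi]
        nodes_mm = nodes * np.asarray([sc, sr])
        pix_mm = np.column_stack([xs * sc, ys * sr])
        # per curve node: distance to the nearest RV-pool pixel
        d = np.min(
            np.linalg.norm(pix_mm[None, :, :] - nodes_mm[:, None, :], axis=-1), axis=1
        )
        min_d = float(d.min())
        if min_d > facing_max_mm:
            continue
        facing = d <= min_d + 3.0
        out[fi] = float(d[facing].mean())
    fallback = bool(np.isnan(out).any())
    out = np.where(np.isnan(out), fallback_mm, out)
    return WallThicknessEstimate(thickness_mm=out, fallback_used=fallback)


def offset_contour(
    nodes: np.ndarray,
    offset_mm: float,
    pixel_spacing_mm: tuple[float, float],
    grid_shape: tuple[int, int],
    reconvexify: bool = True,
) -> np.ndarray:
    """Outward-normal offset of a closed chain by a metric distance.

    The offset is applied in mm space (so anisotropic pixels offset
    correctly), the result is re-convexified to resolve any
    self-intersection of the offset polygon, resampled, and clipped to the
    image bounds.
    """
    if offset_mm == 0.0:
        return np.array(nodes, dtype=np.float64, copy=True)
    sr, sc = pixel_spacing_mm
    scale = np.asarray([sc, sr])
    mm = nodes * scale
    normals = outward_normals(mm)
    moved = (mm + offset_mm * normals) / scale
    if reconvexify:
        try:
            hull = ConvexHull(moved)
            moved = ensure_ccw(moved[hull.vertices])
        except Exception:
            pass
    moved = anchor_start(resample_closed(moved, nodes.shape[0]))
    rows, cols = grid_shape
    moved[..., 0] = np.clip(moved[..., 0], 0.0, cols - 1.0)
    moved[..., 1] = np.clip(moved[..., 1], 0.0, rows - 1.0)
    return moved


def build_initial_contours(
    endo_estimates: np.ndarray,
    present: np.ndarray,
    thickness: WallThicknessEstimate,
    pixel_spacing_mm: tuple[float, float],
    grid_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Endo (hull + t/2) and epi (hull + t) initializations, (S, F, N, 2)."""
    s, f = present.shape
    endo_init = np.array(endo_estimates, dtype=np.float64, copy=True)
    epi_init = np.array(endo_estimates, dtype=np.float64, copy=True)
    for fi in range(f):
        t = float(thickness.thickness_mm[fi])
        for si in range(s):
            if not present[si, fi]:
                continue
            base = endo_estimates[si, fi]
            endo_init[si, fi] = offset_contour(
                base, t / 2.0, pixel_spacing_mm, grid_shape
            )
            epi_init[si, fi] = offset_contour(base, t, pixel_spacing_mm, grid_shape)
    return endo_init, epi_init
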