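"""Validation measures: clinical parameters, Dice, point-to-curve distance,
regional slice splits, and paired bias statistics.

Volumes use summation of disks: in-plane contour area times the
center-to-center slice distance, summed over the analyzed slices, with no
inter-slice interpolation. Myocardial mass assumes a density of
1.05 g/mL. The Dice coefficient is computed volumetrically per phase (all
analyzed slices of one frame pooled); point-to-curve resamples each border
to 80 points spaced every 4.5 degrees on rays from its centroid and
averages the symmetric point-to-polygon distance in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from shapely.geometry import LinearRing, Point

from .core import CineStack, SegmentationResult, polygon_area, rasterize

MYOCARDIAL_DENSITY_G_PER_ML = 1.05
P2C_POINTS = 80
P2C_STEP_DEG = 360.0 / P2C_POINTS  # 4.5 degrees


@dataclass
class ClinicalParams:
    """Global LV function parameters derived from one segmentation."""

    edv_ml: float
    esv_ml: float
    ef_percent: float
    lvm_g: float
    sv_ml: float
    co_l_min: float
    ed_frame: int
    es_frame: int

    def __post_init__(self):
        if not (0.0 <= self.ef_percent <= 100.0):
            raise ValueError(f"EF out of range: {self.ef_percent}")


def cavity_volume_curve(result: SegmentationResult, stack: CineStack,
                        border: str = "endo") -> np.ndarray:
    """Per-frame cavity (or epicardial) volume in mL by disk summation."""
    nodes = result.endo_nodes if border == "endo" else result.epi_nodes
    s, f = result.present.shape
    area_scale = stack.pixel_area_mm2  # px^2 -> mm^2
    vol = np.zeros(f)
    for fi in range(f):
        total = 0.0
        for si in range(s):
            if result.present[si, fi]:
                total += abs(polygon_area(nodes[si, fi])) * area_scale
        vol[fi] = total * stack.slice_spacing_mm / 1000.0
    return vol


def clinical_parameters(result: SegmentationResult, stack: CineStack) -> ClinicalParams:
    """EDV, ESV, EF, LVM, SV, CO from a segmentation result.

    ED is the frame of maximal cavity volume, ES the minimal. LVM is the
    epi-minus-endo volume times myocardial density, averaged over ED and
    ES. Raises when a frame has no contours at all.
    """
    missing = [fi for fi in range(result.n_frames)
               if not result.present[:, fi].any()]
    if missing:
        raise ValueError(f"frames without any contour: {missing}")
    endo_vol = cavity_volume_curve(result, stack, "endo")
    epi_vol = cavity_volume_curve(result, stack, "epi")
    ed = int(np.argmax(endo_vol))
    es = int(np.argmin(endo_vol))
    edv, esv = float(endo_vol[ed]), float(endo_vol[es])
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else 0.0
    lvm = (
        MYOCARDIAL_DENSITY_G_PER_ML
        * 0.5
        * ((epi_vol[ed] - endo_vol[ed]) + (epi_vol[es] - endo_vol[es]))
    )
    co = sv * stack.heart_rate_bpm / 1000.0
    return ClinicalParams(
        edv_ml=edv, esv_ml=esv, ef_percent=ef, lvm_g=float(lvm),
        sv_ml=sv, co_l_min=co, ed_frame=ed, es_frame=es,
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) for binary masks.

    1 for perfect overlap, 0 for disjoint regions; undefined (error) when
    both masks are empty.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def result_masks(result: SegmentationResult, stack: CineStack, frame: int,
                 border: str = "endo") -> np.ndarray:
    """3D boolean mask (analyzed slices, rows, cols) for one frame."""
    nodes = result.endo_nodes if border == "endo" else result.epi_nodes
    s = result.n_slices
    out = np.zeros((s,) + tuple(stack.grid_shape), dtype=bool)
    for si in range(s):
        if result.present[si, frame]:
            out[si] = rasterize(nodes[si, frame], stack.grid_shape)
    return out


def _resample_80(nodes_mm: np.ndarray) -> tuple[np.ndarray, bool]:
    """80 boundary samples on rays from the centroid at 4.5-degree spacing.

    Falls back to nearest-node sampling (flagged) when a ray has no
    well-defined intersection, which can happen for non-star-shaped
    contours.
    """
    centroid = nodes_mm.mean(axis=0)
    angles = np.deg2rad(np.arange(P2C_POINTS) * P2C_STEP_DEG)
    rel = nodes_mm - centroid
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(ang)
    ang_s = ang[order]
    monotone = np.all(np.diff(ang_s) >= 0)  # star-shapedness proxy
    fallback = False
    if monotone:
        r_s = np.hypot(rel[order, 0], rel[order, 1])
        ang_ext = np.concatenate([ang_s - 2 * np.pi, ang_s, ang_s + 2 * np.pi])
        r_ext = np.concatenate([r_s, r_s, r_s])
        q = np.mod(angles + np.pi, 2 * np.pi) - np.pi
        r = np.interp(q, ang_ext, r_ext)
        pts = centroid + np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    else:
        # nearest node per ray direction
        fallback = True
        d = np.abs(np.angle(np.exp(1j * (ang[None, :] - angles[:, None]))))
        nearest = np.argmin(d, axis=1)
        pts = nodes_mm[nearest]
    return pts, fallback


def point_to_curve(
    nodes_a: np.ndarray,
    nodes_b: np.ndarray,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Symmetric mean point-to-curve distance between two borders, in mm.

    Each border is resampled to 80 points at 4.5-degree spacing around its
    own centroid; the mean distance from each sample set to the other
    border's polygon is averaged symmetrically.
    """
    sr, sc = pixel_spacing_mm
    scale = np.asarray([sc, sr])
    a_mm = np.asarray(nodes_a, dtype=np.float64) * scale
    b_mm = np.asarray(nodes_b, dtype=np.float64) * scale
    pts_a, _ = _resample_80(a_mm)
    pts_b, _ = _resample_80(b_mm)
    ring_a = LinearRing(a_mm)
    ring_b = LinearRing(b_mm)
    d_ab = float(np.mean([ring_b.distance(Point(p)) for p in pts_a]))
    d_ba = float(np.mean([ring_a.distance(Point(p)) for p in pts_b]))
    return 0.5 * (d_ab + d_ba)


def regional_split(n_slices: int) -> dict[str, list[int]]:
    """Split slice indices 0..n-1 into basal/mid/apical thirds.

    Sizes differ by at most one slice; remainders go basal first, then
    midventricular. Computed separately for each phase by the caller (the
    end-systolic stack may be shorter after long-axis removal).
    """
    if n_slices < 3:
        raise ValueError(f"need >= 3 slices for a regional split; got {n_slices}")
    base = n_slices // 3
    rem = n_slices % 3
    sizes = [base + (rem >= 1), base + (rem >= 2), base]
    idx = np.arange(n_slices)
    out = {}
    start = 0
    for name, size in zip(("basal", "mid", "apical"), sizes):
        out[name] = idx[start : start + size].tolist()
        start += size
    return out


def bias_report(values_a, values_b) -> dict:
    """Paired bias statistics for two matched measurement series.

    Returns the mean and SD of the differences (a - b), the two-sided
    paired t-test p-value, and the linear-regression correlation R. With
    zero variance of the differences the p-value is undefined (NaN).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1D and of equal length")
    if a.size < 3:
        raise ValueError(f"need >= 3 pairs; got {a.size}")
    diff = a - b
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        p = math.nan
        t = math.nan
    else:
        t, p = stats.ttest_rel(a, b)
        t, p = float(t), float(p)
    if np.std(a) == 0 or np.std(b) == 0:
        r = math.nan
    else:
        r = float(stats.linregress(b, a).rvalue)
    return {"mean": mean, "sd": sd, "t": t, "p": p, "r": r, "n": int(a.size)}
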