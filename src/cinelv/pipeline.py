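"""End-to-end segmentation pipeline and evaluation reports.

``run_segment`` executes the eight stages in order — LV center, balloon
images, initialization, endocardial deformation, epicardial deformation,
detached-papillary exclusion, outflow/long-axis detection, and
attached-papillary exclusion — and returns the segmentation result
together with a per-stage report (timings, convergence, flags). Each
stage failure is re-raised as a :class:`~cinelv.errors.StageError` naming
the stage.
"""

from __future__ import annotations

import math
import time

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import CineStack, SegmentationResult, rasterize, signed_areas
from .deformable import deform, edge_force_field
from .errors import CineLVError, LVNotFoundError, StageError
from .evaluation import (
    cavity_volume_curve,
    clinical_parameters,
    dice,
    point_to_curve,
    regional_split,
    result_masks,
)
from .initialization import (
    WallThicknessEstimate,
    blood_pool_mask,
    build_initial_contours,
    initial_endo_estimate,
)
from .intensity import (
    endo_balloon,
    epi_balloon,
    fit_mixture,
    init_blood_stats,
    locate_lv_center,
)
from .refinement import (
    build_sector_grid,
    detect_outflow,
    exclude_attached_papillaries,
    exclude_detached_papillaries,
)

from scipy import ndimage


def _clamp_endo_inside_epi(endo, epi, present, spacing):
    """Push epicardial nodes outward where the endocardium crosses them.

    The balloon zeroing makes containment implicit, not guaranteed; a
    half-pixel clamp removes residual crossings.
    """
    sr, sc = spacing
    scale = np.asarray([sc, sr])
    margin = 0.5 * min(sr, sc)
    s, f = present.shape
    for si in range(s):
        for fi in range(f):
            if not present[si, fi]:
                continue
            e_mm = endo[si, fi] * scale
            p_mm = epi[si, fi] * scale
            centroid = e_mm.mean(axis=0)
            rel_p = p_mm - centroid
            ang_p = np.arctan2(rel_p[:, 1], rel_p[:, 0])
            r_p = np.hypot(rel_p[:, 0], rel_p[:, 1])
            from .refinement import _polar_radius
            r_e = _polar_radius(e_mm, centroid, ang_p)
            low = r_e + margin
            bad = r_p < low
            if bad.any():
                unit = rel_p / np.maximum(r_p[:, None], 1e-9)
                r_new = np.where(bad, low, r_p)
                epi[si, fi] = (centroid + unit * r_new[:, None]) / scale
    return epi


def run_segment(
    stack: CineStack, config: RunConfig | None = None
) -> tuple[SegmentationResult, dict]:
    """Run the full automatic segmentation on one cine stack.

    The only user input consumed is ``stack.analyzed_slice_range`` (most
    basal to most apical slice containing myocardium). Deterministic: two
    runs on the same stack and config produce identical contours.
    """
    config = config or RunConfig()
    report: dict = {"stages": {}}
    t_all = time.perf_counter()

    def stage(name):
        report["stages"][name] = {"t_start": time.perf_counter() - t_all}

    def stage_done(name, **info):
        entry = report["stages"][name]
        entry["seconds"] = time.perf_counter() - t_all - entry.pop("t_start")
        entry.update(info)

    b, a = stack.analyzed_slice_range
    sub = stack.intensities[b : a + 1]
    s_n, f_n = sub.shape[:2]

    # Step 1 — LV center -----------------------------------------------------
    stage("locate_lv_center")
    try:
        lv_center = locate_lv_center(
            stack,
            smooth_sigma_mm=config.center.smooth_sigma_mm,
            min_area_mm2=config.center.min_area_mm2,
        )
    except LVNotFoundError:
        raise
    except CineLVError as exc:
        raise StageError("locate_lv_center", str(exc)) from exc
    stage_done("locate_lv_center", lv_center=lv_center)

    # Step 2 — EM mixture and balloon images --------------------------------
    stage("balloon")
    blood_stats = init_blood_stats(
        stack, lv_center,
        radius_mm=config.blood_init.radius_mm,
        min_pixels=config.blood_init.min_pixels,
    )
    mixture = fit_mixture(
        stack, blood_stats,
        n_components=config.em.n_components,
        tol=config.em.tol,
        max_iter=config.em.max_iter,
        sd_floor_frac=config.em.sd_floor_frac,
        n_bins=config.em.n_bins,
        lv_center=lv_center,
        roi_radius_mm=config.em.roi_radius_mm,
    )
    bal_endo_full = endo_balloon(stack, mixture)
    # work on the analyzed sub-stack from here on
    bal_endo = type(bal_endo_full)(
        values=bal_endo_full.values[b : a + 1], border="endo"
    )
    stage_done(
        "balloon",
        mixture={c.label: (c.mean, c.sd, c.weight) for c in mixture.components},
        em_converged=mixture.converged,
        em_degenerate=mixture.degenerate,
    )

    # Step 3 — initialization ------------------------------------------------
    stage("initialization")
    pools, empty = blood_pool_mask(
        bal_endo, lv_center, stack.pixel_spacing_mm,
        search_radius_mm=config.init.pool_search_radius_mm,
    )
    present = ~empty
    n_nodes = config.init.node_count
    estimates = np.zeros((s_n, f_n, n_nodes, 2))
    for si in range(s_n):
        for fi in range(f_n):
            if not present[si, fi]:
                continue
            try:
                estimates[si, fi] = initial_endo_estimate(pools[si, fi], n_nodes)
            except CineLVError:
                present[si, fi] = False
    if not present.any():
        raise StageError("initialization", "no usable blood pool in any slice/frame")
    thickness = _estimate_thickness(
        estimates, present, bal_endo, pools, lv_center, stack, config
    )
    endo_init, epi_init = build_initial_contours(
        estimates, present, thickness, stack.pixel_spacing_mm, stack.grid_shape
    )
    # septal reference direction for the sector grid
    origin_angle = _septal_angle(bal_endo, pools, present, lv_center)
    stage_done(
        "initialization",
        wall_thickness_mm=thickness.thickness_mm.tolist(),
        wall_fallback=thickness.fallback_used,
        origin_angle=origin_angle,
    )

    # Step 4 — endocardial segmentation -------------------------------------
    stage("deform_endo")
    edge = edge_force_field(sub, sigma_px=config.edge.sigma_px)
    endo_nodes, rep_endo = deform(
        endo_init, present, bal_endo, edge,
        config.deform.endo_weights, config.deform.numerics,
    )
    stage_done("deform_endo", iterations=rep_endo.iterations,
               converged=rep_endo.converged,
               collapsed=int(rep_endo.collapsed.sum()))

    # Step 5 — epicardial segmentation --------------------------------------
    stage("deform_epi")
    endo_masks = np.zeros(sub.shape, dtype=bool)
    for si in range(s_n):
        for fi in range(f_n):
            if present[si, fi]:
                try:
                    endo_masks[si, fi] = rasterize(
                        endo_nodes[si, fi], stack.grid_shape
                    )
                except CineLVError:
                    pass
    bal_epi_full = epi_balloon(stack, mixture)
    bal_epi_vals = bal_epi_full.values[b : a + 1].copy()
    bal_epi_vals[endo_masks] = 0.0
    epi_nodes, rep_epi = deform(
        epi_init, present, bal_epi_vals, edge,
        config.deform.epi_weights, config.deform.numerics,
    )
    epi_nodes = _clamp_endo_inside_epi(
        endo_nodes, epi_nodes, present, stack.pixel_spacing_mm
    )
    stage_done("deform_epi", iterations=rep_epi.iterations,
               converged=rep_epi.converged,
               collapsed=int(rep_epi.collapsed.sum()))

    # Step 6 — detached papillaries -----------------------------------------
    stage("detached_papillaries")
    endo_nodes, bal_mod, rep_ref = exclude_detached_papillaries(
        endo_nodes, present, bal_endo, edge,
        config.deform.endo_weights, config.deform.numerics,
    )
    epi_nodes = _clamp_endo_inside_epi(
        endo_nodes, epi_nodes, present, stack.pixel_spacing_mm
    )
    stage_done("detached_papillaries", iterations=rep_ref.iterations)

    # Step 7 — outflow tract and long-axis motion ---------------------------
    stage("outflow")
    sub_stack = CineStack(
        intensities=sub,
        pixel_spacing_mm=stack.pixel_spacing_mm,
        slice_spacing_mm=stack.slice_spacing_mm,
        frame_duration_ms=stack.frame_duration_ms,
        heart_rate_bpm=stack.heart_rate_bpm,
    )
    grid = build_sector_grid(
        endo_nodes, epi_nodes, present, sub_stack, origin_angle
    )
    areas = np.abs(signed_areas(endo_nodes)) * present
    ed_frame = int(np.argmax(areas.sum(axis=0)))
    outflow = detect_outflow(
        grid, sub_stack, endo_nodes, epi_nodes, present, ed_frame,
        basal_fraction=config.outflow.basal_fraction,
        intensity_sd_mult=config.outflow.intensity_sd_mult,
        thickness_min_mm=config.outflow.thickness_min_mm,
    )
    endo_nodes, epi_nodes = outflow.endo_nodes, outflow.epi_nodes
    present = outflow.present
    stage_done("outflow", n_basal=outflow.n_basal,
               n_flagged=int(outflow.flags.sum()),
               displacement=outflow.longaxis_displacement.tolist(),
               warnings=outflow.warnings)

    # Step 8 — attached papillaries -----------------------------------------
    stage("attached_papillaries")
    endo_nodes, clamped = exclude_attached_papillaries(
        endo_nodes, epi_nodes, present, bal_endo.values, sub_stack,
        origin_angle, outflow, ed_frame,
        volume_tol=config.papillary.volume_tol,
        step_mm=config.papillary.step_mm,
        cap_mm=config.papillary.cap_mm,
        min_reference_mm3=config.papillary.min_reference_mm3,
    )
    stage_done("attached_papillaries", clamped=int(clamped.sum()))

    vols = np.abs(signed_areas(endo_nodes)) * present
    per_frame = vols.sum(axis=0)
    es_frame = int(np.argmin(per_frame))
    result = SegmentationResult(
        endo_nodes=endo_nodes,
        epi_nodes=epi_nodes,
        present=present,
        outflow_flags=outflow.flags,
        longaxis_displacement=outflow.longaxis_displacement,
        slice_offset=b,
        ed_frame=ed_frame,
        es_frame=es_frame,
    )
    report["seconds_total"] = time.perf_counter() - t_all
    return result, report


def _estimate_thickness(estimates, present, bal_endo, pools, lv_center,
                        stack, config) -> WallThicknessEstimate:
    from .initialization import estimate_wall_thickness

    return estimate_wall_thickness(
        estimates, present, bal_endo, pools, lv_center,
        stack.pixel_spacing_mm, fallback_mm=config.init.wall_fallback_mm,
    )


def _septal_angle(bal_endo, lv_pools, present, lv_center) -> float:
    """Angle from the LV center toward the RV blood pool (sector origin).

    Falls back to pointing image-left when no RV candidate exists.
    """
    s_n = lv_pools.shape[0]
    mid = s_n // 2
    x0, y0 = lv_center
    for fi in range(lv_pools.shape[1]):
        if not present[mid, fi]:
            continue
        pos = (bal_endo.values[mid, fi] > 0) & ~lv_pools[mid, fi]
        labels, n = ndimage.label(pos)
        best = None
        for lab in range(1, n + 1):
            comp = labels == lab
            area = int(comp.sum())
            if area < 10:
                continue
            cy, cx = ndimage.center_of_mass(comp)
            if cx < x0 and (best is None or area > best[0]):
                best = (area, cx, cy)
        if best is not None:
            return float(math.atan2(best[2] - y0, best[1] - x0))
    return math.pi


def run_evaluate(
    auto: SegmentationResult, reference: SegmentationResult, stack: CineStack
) -> pd.DataFrame:
    """Compare a segmentation against a reference on one stack.

    Returns a one-row-per-metric table: Dice and point-to-curve distance
    (overall, per phase, per region) for both borders, plus clinical
    parameter differences (auto - reference). Phases are end-diastole and
    end-systole of the *reference*.
    """
    if auto.present.shape != reference.present.shape:
        raise ValueError("segmentations cover different slice/frame grids")
    both = auto.present & reference.present
    if not both.any():
        raise ValueError("no slice/frame covered by both segmentations")
    ref_vol = cavity_volume_curve(reference, stack, "endo")
    ed, es = int(np.argmax(ref_vol)), int(np.argmin(ref_vol))
    rows = []

    def add(metric, border, region, value):
        rows.append({"metric": metric, "border": border,
                     "region": region, "value": value})

    for border in ("endo", "epi"):
        phase_dsc = {}
        for phase, frame in (("ED", ed), ("ES", es)):
            m_auto = result_masks(auto, stack, frame, border)
            m_ref = result_masks(reference, stack, frame, border)
            phase_dsc[phase] = dice(m_auto, m_ref)
            add("dsc", border, phase, phase_dsc[phase])
        add("dsc", border, "overall", 0.5 * (phase_dsc["ED"] + phase_dsc["ES"]))

        p2c_all = []
        for phase, frame in (("ED", ed), ("ES", es)):
            vals = [
                point_to_curve(
                    (auto.endo_nodes if border == "endo" else auto.epi_nodes)[si, frame],
                    (reference.endo_nodes if border == "endo"
                     else reference.epi_nodes)[si, frame],
                    stack.pixel_spacing_mm,
                )
                for si in range(auto.n_slices)
                if both[si, frame]
            ]
            add("p2c_mm", border, phase, float(np.mean(vals)))
            p2c_all.extend(vals)
        add("p2c_mm", border, "overall", float(np.mean(p2c_all)))

        # regional split per phase on the slices both cover
        for phase, frame in (("ED", ed), ("ES", es)):
            covered = [si for si in range(auto.n_slices) if both[si, frame]]
            if len(covered) < 3:
                continue
            split = regional_split(len(covered))
            for region, idx in split.items():
                slices = [covered[i] for i in idx]
                vals = [
                    point_to_curve(
                        (auto.endo_nodes if border == "endo"
                         else auto.epi_nodes)[si, frame],
                        (reference.endo_nodes if border == "endo"
                         else reference.epi_nodes)[si, frame],
                        stack.pixel_spacing_mm,
                    )
                    for si in slices
                ]
                add("p2c_mm", border, f"{phase}_{region}", float(np.mean(vals)))

    cp_auto = clinical_parameters(auto, stack)
    cp_ref = clinical_parameters(reference, stack)
    for name in ("edv_ml", "esv_ml", "ef_percent", "lvm_g", "sv_ml", "co_l_min"):
        add(name, "", "diff", getattr(cp_auto, name) - getattr(cp_ref, name))
        add(name, "", "auto", getattr(cp_auto, name))
        add(name, "", "reference", getattr(cp_ref, name))
    return pd.DataFrame(rows)
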