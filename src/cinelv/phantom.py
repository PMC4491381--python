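"""Synthetic short-axis cine phantom with analytic ground truth.

The phantom renders a truncated half-ellipsoid left ventricle inside a
heterogeneous background, emulating bright-blood cine imaging at the
resolution the method targets (1.4 x 1.4 mm in plane, 8 mm slices, 30
frames per cardiac cycle). The cavity volume follows a smooth
diastole-systole-diastole curve hitting configured EDV/EF targets; the
atrioventricular plane can translate along the long axis so basal slices
lose their myocardium during systole; an outflow-tract arc can replace the
basal wall with blood over a configurable angle; papillary muscles are
rendered as constant-volume myocardium-intensity spheres, either detached
in the cavity or attached to the wall; an optional right-ventricular blood
crescent hugs the septal side. All geometry is analytic, so every truth
quantity (contours, masks, volumes, long-axis displacement, outflow
sectors) is available exactly.

What it does not emulate: MR physics (k-space truncation, banding,
surface-coil shading), through-plane partial volume at the valve plane
(slices lose their wall as a whole), and trabeculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CineStack, N_SECTORS, SegmentationResult
from .errors import CineLVError

DEFAULT_NODE_COUNT = 80


@dataclass
class PapillarySpec:
    """One papillary muscle: a constant-volume sphere.

    ``kind`` is 'detached' (floats in the cavity, tracking the contraction)
    or 'attached' (fixed in space at the end-diastolic endocardial border,
    so systolic wall thickening absorbs it). ``angle_deg`` is measured from
    the septal reference direction; ``z_mm`` is the depth below the
    end-diastolic base.
    """

    kind: str = "detached"
    angle_deg: float = 135.0
    radius_mm: float = 5.0
    z_mm: float = 36.0

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius_mm**3 / 1000.0


@dataclass
class PhantomSpec:
    """Parametric description of one synthetic cine stack."""

    name: str = "baseline"
    rows: int = 112
    cols: int = 112
    n_slices: int = 8
    n_frames: int = 30
    pixel_spacing_mm: tuple[float, float] = (1.4, 1.4)
    slice_spacing_mm: float = 8.0
    heart_rate_bpm: float = 60.0
    edv_target_ml: float = 150.0
    ef_target_percent: float = 60.0
    wall_thickness_ed_mm: float = 10.0
    wall_thickness_es_mm: float = 14.0
    av_plane_displacement_mm: float = 0.0
    es_phase: float = 0.4  # end-systole at 40% of the cycle
    outflow_arc_deg: float = 0.0
    outflow_basal_slices: int = 0
    outflow_center_deg: float = 45.0  # from the septal reference direction
    papillaries: list[PapillarySpec] = field(default_factory=list)
    blood_mean: float = 300.0
    blood_sd: float = 20.0
    myo_mean: float = 150.0
    myo_sd: float = 15.0
    surround_mean: float = 80.0
    surround_sd: float = 30.0
    noise_sd: float = 0.0
    rv_present: bool = True
    rv_thickness_mm: float = 10.0
    rv_half_angle_deg: float = 60.0
    lv_center_frac: tuple[float, float] = (0.58, 0.5)  # (col, row) fraction
    seed: int = 0

    def __post_init__(self):
        for name in (
            "edv_target_ml", "ef_target_percent", "wall_thickness_ed_mm",
            "wall_thickness_es_mm", "heart_rate_bpm", "slice_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise CineLVError(f"{name} must be positive")
        if not (0 < self.ef_target_percent < 100):
            raise CineLVError("ef_target_percent must be in (0, 100)")
        if self.outflow_arc_deg > 180:
            raise CineLVError("outflow arc must not exceed 180 degrees")
        if self.av_plane_displacement_mm < 0:
            raise CineLVError("av_plane_displacement_mm must be >= 0")

    # --- derived geometry -------------------------------------------------

    @property
    def cavity_length_mm(self) -> float:
        """Base-to-apex cavity length; the apex closes at the far edge of
        the most apical analyzed slice."""
        return self.n_slices * self.slice_spacing_mm

    @property
    def esv_target_ml(self) -> float:
        return self.edv_target_ml * (1.0 - self.ef_target_percent / 100.0)

    @property
    def lv_center_px(self) -> tuple[float, float]:
        return (self.lv_center_frac[0] * (self.cols - 1),
                self.lv_center_frac[1] * (self.rows - 1))

    @property
    def origin_angle(self) -> float:
        """Septal reference direction (toward the RV, i.e. image left)."""
        return math.pi

    def contraction_phase(self, frame: int) -> float:
        """0 at end-diastole, 1 at end-systole, cyclically smooth."""
        t = frame / self.n_frames
        if t <= self.es_phase:
            return 0.5 * (1.0 - math.cos(math.pi * t / self.es_phase))
        return 0.5 * (1.0 + math.cos(math.pi * (t - self.es_phase)
                                     / (1.0 - self.es_phase)))


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying one rendered stack."""

    endo_nodes: np.ndarray          # (S, F, N, 2) px
    epi_nodes: np.ndarray
    present: np.ndarray             # (S, F)
    cavity_masks: np.ndarray        # (S, F, R, C) blood pool (papillaries cut out)
    papillary_masks: np.ndarray     # (S, F, R, C) papillary spheres
    outflow_masks: np.ndarray       # (S, F, R, C) outflow arc region
    outflow_flags: np.ndarray       # (S, F, 24)
    longaxis_displacement: np.ndarray  # (F,)
    edv_ml: float
    esv_ml: float
    ef_percent: float
    lvm_g: float
    ed_frame: int
    es_frame: int
    lv_center_px: tuple[float, float]
    origin_angle: float

    def as_result(self) -> SegmentationResult:
        """Truth contours wrapped as a segmentation result for evaluation."""
        return SegmentationResult(
            endo_nodes=self.endo_nodes,
            epi_nodes=self.epi_nodes,
            present=self.present,
            outflow_flags=self.outflow_flags,
            longaxis_displacement=self.longaxis_displacement,
            ed_frame=self.ed_frame,
            es_frame=self.es_frame,
        )


def _volume_integral(l_mm: float, z_lo: float, z_hi: float) -> float:
    """Integral of (1 - z^2/L^2) dz over [z_lo, z_hi], clipped to [0, L]."""
    z_lo = min(max(z_lo, 0.0), l_mm)
    z_hi = min(max(z_hi, 0.0), l_mm)
    if z_hi <= z_lo:
        return 0.0
    def antideriv(z):
        return z - z**3 / (3.0 * l_mm**2)
    return antideriv(z_hi) - antideriv(z_lo)


def generate(spec: PhantomSpec) -> tuple[CineStack, PhantomTruth]:
    """Render a cine stack and its analytic ground truth.

    Deterministic given ``spec.seed``: the same spec produces bit-identical
    stacks.
    """
    rng = np.random.default_rng(spec.seed)
    sr, sc = spec.pixel_spacing_mm
    rows, cols, s_n, f_n = spec.rows, spec.cols, spec.n_slices, spec.n_frames
    dz = spec.slice_spacing_mm
    l_mm = spec.cavity_length_mm
    cx, cy = spec.lv_center_px

    # base cavity radius from the EDV target (full cavity, AV plane at z=0)
    i_full = _volume_integral(l_mm, 0.0, l_mm)
    b0 = math.sqrt(spec.edv_target_ml * 1000.0 / (math.pi * i_full))

    # feasibility: epi plus RV crescent must stay inside the grid
    max_epi = b0 + spec.wall_thickness_es_mm
    margin_left = cx * sc - (max_epi + (spec.rv_thickness_mm if spec.rv_present else 0))
    margin_right = (cols - 1 - cx) * sc - max_epi
    margin_v = min(cy, rows - 1 - cy) * sr - max_epi
    if min(margin_left, margin_right, margin_v) < 2.0:
        raise CineLVError(
            f"phantom geometry exceeds the grid: epi radius {max_epi:.1f} mm "
            f"does not fit a {rows}x{cols} grid at {sr}x{sc} mm"
        )

    # per-frame cavity scale and AV-plane depth
    phases = np.array([spec.contraction_phase(f) for f in range(f_n)])
    volumes = spec.edv_target_ml - (spec.edv_target_ml - spec.esv_target_ml) * phases
    av_depth = spec.av_plane_displacement_mm * phases
    b_f = np.empty(f_n)
    for f in range(f_n):
        integ = _volume_integral(l_mm, av_depth[f], l_mm)
        b_f[f] = math.sqrt(volumes[f] * 1000.0 / (math.pi * integ))
    wall_f = (spec.wall_thickness_ed_mm
              + (spec.wall_thickness_es_mm - spec.wall_thickness_ed_mm) * phases)

    z_centers = (np.arange(s_n) + 0.5) * dz
    shape_factor = np.sqrt(np.clip(1.0 - (z_centers / l_mm) ** 2, 0.0, None))
    present = z_centers[:, None] > av_depth[None, :]  # (S, F)

    # coordinate grids in mm relative to the LV center
    yy, xx = np.mgrid[0:rows, 0:cols]
    x_mm = (xx - cx) * sc
    y_mm = (yy - cy) * sr
    r_mm = np.hypot(x_mm, y_mm)
    theta = np.arctan2(y_mm, x_mm)
    aa = 0.5 * (sr + sc)  # antialias width ~ one pixel

    def cov(edge_r, radius):
        return np.clip((radius - edge_r) / aa + 0.5, 0.0, 1.0)

    # static heterogeneous background: smooth field at half the surround SD
    if spec.surround_sd > 0:
        raw = rng.standard_normal((rows, cols))
        smooth = ndimage.gaussian_filter(raw, sigma=20.0 / aa)
        smooth /= max(smooth.std(), 1e-9)
        surround_field = spec.surround_mean + 0.5 * spec.surround_sd * smooth
        surround_pix_sd = math.sqrt(max(spec.surround_sd**2
                                        - (0.5 * spec.surround_sd) ** 2, 0.0))
    else:
        surround_field = np.full((rows, cols), spec.surround_mean)
        surround_pix_sd = 0.0

    # precompute papillary absolute positions
    pap_centers = []
    for pap in spec.papillaries:
        ang = spec.origin_angle + math.radians(pap.angle_deg)
        pap_centers.append((pap, ang))

    arc_half = math.radians(spec.outflow_arc_deg) / 2.0
    arc_center = spec.origin_angle + math.radians(spec.outflow_center_deg)

    n_nodes = DEFAULT_NODE_COUNT
    node_angles = 2.0 * math.pi * np.arange(n_nodes) / n_nodes

    intens = np.zeros((s_n, f_n, rows, cols), dtype=np.float64)
    endo_nodes = np.zeros((s_n, f_n, n_nodes, 2))
    epi_nodes = np.zeros((s_n, f_n, n_nodes, 2))
    cavity_masks = np.zeros((s_n, f_n, rows, cols), dtype=bool)
    papillary_masks = np.zeros((s_n, f_n, rows, cols), dtype=bool)
    outflow_masks = np.zeros((s_n, f_n, rows, cols), dtype=bool)
    outflow_flags = np.zeros((s_n, f_n, N_SECTORS), dtype=bool)

    sector_centers = (spec.origin_angle
                      + (np.arange(N_SECTORS) + 0.5) * 2 * math.pi / N_SECTORS)

    for f in range(f_n):
        beta = b_f[f] / b0
        for s in range(s_n):
            if present[s, f]:
                r_endo = b_f[f] * shape_factor[s]
                r_epi = r_endo + wall_f[f]
                c_cav = cov(r_mm, r_endo)
                c_epi = cov(r_mm, r_epi)
            else:
                # slice above the AV plane: atrial/outflow blood, no wall
                r_endo = b_f[f] * math.sqrt(
                    max(1.0 - (av_depth[f] / l_mm) ** 2, 0.0)
                )
                r_epi = r_endo
                c_cav = cov(r_mm, r_endo)
                c_epi = c_cav
            c_wall = np.clip(c_epi - c_cav, 0.0, 1.0)

            # outflow arc: wall replaced by blood over an angular window
            if (spec.outflow_arc_deg > 0 and present[s, f]
                    and s < spec.outflow_basal_slices):
                darc = np.abs(np.angle(np.exp(1j * (theta - arc_center))))
                in_arc = darc <= arc_half
                moved = c_wall * in_arc
                c_cav = c_cav + moved
                c_wall = c_wall - moved
                outflow_masks[s, f] = in_arc & (c_wall + moved > 0.5) & (
                    r_mm > r_endo - aa
                )
                d_sect = np.abs(np.angle(np.exp(1j * (sector_centers - arc_center))))
                outflow_flags[s, f] = d_sect <= arc_half
            if not present[s, f]:
                outflow_flags[s, f] = True

            # papillaries: myocardium intensity carved out of the cavity
            c_pap = np.zeros((rows, cols))
            z_s = z_centers[s]
            for pap, ang in pap_centers:
                if pap.kind == "detached":
                    z_factor = math.sqrt(max(1.0 - (pap.z_mm / l_mm) ** 2, 0.0))
                    dist = 0.5 * b_f[f] * z_factor
                else:
                    z_factor = math.sqrt(max(1.0 - (pap.z_mm / l_mm) ** 2, 0.0))
                    dist = b0 * z_factor - 1.5  # fixed at the ED endo border
                dzp = z_s - pap.z_mm
                if abs(dzp) >= pap.radius_mm:
                    continue
                rho = math.sqrt(pap.radius_mm**2 - dzp**2)
                px = dist * math.cos(ang)
                py = dist * math.sin(ang)
                d_pap = np.hypot(x_mm - px, y_mm - py)
                c_this = cov(d_pap, rho)
                c_pap = np.maximum(c_pap, c_this)
                papillary_masks[s, f] |= d_pap <= rho
            # papillary tissue displaces blood only (wall is already muscle)
            pap_in_cav = np.minimum(c_pap, c_cav)
            c_blood = c_cav - pap_in_cav
            c_myo = c_wall + pap_in_cav

            # RV crescent on the septal (image-left) side
            if spec.rv_present and present[s, f]:
                d_ang = np.abs(np.angle(np.exp(1j * (theta - math.pi))))
                ring = (cov(r_mm, r_epi + spec.rv_thickness_mm)
                        - cov(r_mm, r_epi))
                rv = np.clip(ring, 0.0, 1.0) * (
                    d_ang <= math.radians(spec.rv_half_angle_deg)
                )
                c_blood = np.clip(c_blood + rv, 0.0, 1.0)
                c_myo = np.clip(c_myo - rv, 0.0, None)

            c_surr = np.clip(1.0 - c_blood - c_myo, 0.0, 1.0)
            img = (spec.blood_mean * c_blood + spec.myo_mean * c_myo
                   + surround_field * c_surr)
            pix_sd = np.sqrt(
                c_blood * spec.blood_sd**2 + c_myo * spec.myo_sd**2
                + c_surr * surround_pix_sd**2 + spec.noise_sd**2
            )
            if pix_sd.max() > 0:
                img = img + pix_sd * rng.standard_normal((rows, cols))
            intens[s, f] = np.clip(img, 0.0, None)

            cavity_masks[s, f] = (c_cav - pap_in_cav) > 0.5
            if present[s, f]:
                ex = cx + (r_endo / sc) * np.cos(node_angles)
                ey = cy + (r_endo / sr) * np.sin(node_angles)
                px_ = cx + (r_epi / sc) * np.cos(node_angles)
                py_ = cy + (r_epi / sr) * np.sin(node_angles)
                endo_nodes[s, f] = np.column_stack([ex, ey])
                epi_nodes[s, f] = np.column_stack([px_, py_])

    # truth volumes by the same disk summation the evaluation uses
    endo_area = np.where(present, (b_f[None, :] * shape_factor[:, None]) ** 2, 0.0)
    endo_vol = math.pi * endo_area.sum(axis=0) * dz / 1000.0  # (F,) mL
    ed = int(np.argmax(endo_vol))
    es = int(np.argmin(endo_vol))
    epi_area = np.where(
        present,
        (b_f[None, :] * shape_factor[:, None] + wall_f[None, :]) ** 2,
        0.0,
    )
    epi_vol = math.pi * epi_area.sum(axis=0) * dz / 1000.0
    lvm = 1.05 * 0.5 * ((epi_vol[ed] - endo_vol[ed]) + (epi_vol[es] - endo_vol[es]))
    removed = (~present).sum(axis=0)
    displacement = removed - removed[ed]

    frame_duration = 60000.0 / (spec.heart_rate_bpm * f_n)
    stack = CineStack(
        intensities=intens,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_spacing_mm=dz,
        frame_duration_ms=frame_duration,
        heart_rate_bpm=spec.heart_rate_bpm,
        analyzed_slice_range=(0, s_n - 1),
    )
    truth = PhantomTruth(
        endo_nodes=endo_nodes,
        epi_nodes=epi_nodes,
        present=present,
        cavity_masks=cavity_masks,
        papillary_masks=papillary_masks,
        outflow_masks=outflow_masks,
        outflow_flags=outflow_flags,
        longaxis_displacement=displacement.astype(np.int64),
        edv_ml=float(endo_vol[ed]),
        esv_ml=float(endo_vol[es]),
        ef_percent=float(100.0 * (endo_vol[ed] - endo_vol[es]) / endo_vol[ed]),
        lvm_g=float(lvm),
        ed_frame=ed,
        es_frame=es,
        lv_center_px=(cx, cy),
        origin_angle=spec.origin_angle,
    )
    return stack, truth


def default_suite() -> list[PhantomSpec]:
    """The named phantom conditions used for end-to-end validation."""
    return [
        PhantomSpec(name="baseline", seed=11),
        PhantomSpec(
            name="detached_papillary",
            papillaries=[PapillarySpec(kind="detached", angle_deg=135.0,
                                       radius_mm=5.0, z_mm=36.0)],
            seed=12,
        ),
        PhantomSpec(
            name="attached_papillary",
            papillaries=[PapillarySpec(kind="attached", angle_deg=150.0,
                                       radius_mm=4.0, z_mm=36.0)],
            seed=13,
        ),
        PhantomSpec(
            name="outflow_longaxis",
            av_plane_displacement_mm=10.0,
            outflow_arc_deg=75.0,
            outflow_basal_slices=2,
            seed=14,
        ),
        PhantomSpec(name="low_snr", noise_sd=30.0, seed=15),
        PhantomSpec(name="no_rv", rv_present=False, seed=16),
    ]
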