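"""Deformable-contour evolution under balloon, edge, curvature, coupling,
and damping forces.

All contours of one border (every analyzed slice and time frame) evolve
simultaneously, which lets the inter-slice and temporal coupling forces act
on the current state of the neighbours. Each iteration:

1. sample the balloon force and the edge force field at the node positions,
2. add the in-slice curvature force (discrete second difference along the
   chain), the inter-slice force (pull toward the mean of corresponding
   nodes in adjacent slices), and the temporal acceleration (cyclic second
   difference across frames),
3. project the weighted total force onto the outward curve normal and
   normalize it (forces above unit magnitude are scaled down, never up),
4. take a damped explicit Euler step, capped per iteration,
5. re-space the nodes to equal arc length.

The iteration stops when the maximum node displacement falls below a
tolerance, when the displacement has stopped decreasing (oscillation
around the equilibrium), or at the iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import anchor_start, resample_closed, outward_normals, signed_areas
from .intensity import BalloonImage


@dataclass
class ForceWeights:
    """Non-negative force weights for one border's deformable model."""

    w_balloon: float = 1.0
    w_edge: float = 0.5
    w_curv_inplane: float = 0.5
    w_curv_interslice: float = 0.2
    w_temporal: float = 0.2
    w_damping: float = 1.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative; got {v}")
        if self.w_balloon == 0 and self.w_edge == 0:
            raise ValueError("at least one of w_balloon, w_edge must be > 0")

    def asdict(self) -> dict:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}

    @classmethod
    def fromdict(cls, d: dict) -> "ForceWeights":
        return cls(**{k: float(v) for k, v in d.items()})


# keep the constructor invariant out of the way for tuning/identity tests
def _weights_allow_zero(**kw) -> ForceWeights:
    w = ForceWeights.__new__(ForceWeights)
    defaults = {f: 0.0 for f in ForceWeights.__dataclass_fields__}
    defaults.update(kw)
    for k, v in defaults.items():
        object.__setattr__(w, k, float(v))
    return w


@dataclass
class DeformConfig:
    """Numerical parameters of the contour evolution."""

    step_px: float = 0.5        # per-iteration displacement cap
    tol_px: float = 0.05        # convergence: max node displacement
    max_iter: int = 500
    smooth_sigma_px: float = 1.0  # force-field smoothing inside the solver
    min_area_px: float = 4.0    # collapse threshold
    stall_window: int = 50      # oscillation guard


@dataclass
class DeformReport:
    iterations: int = 0
    converged: bool = False
    stalled: bool = False
    collapsed: np.ndarray | None = None  # (S, F) bool
    max_disp_history: list[float] = field(default_factory=list)


def edge_force_field(
    intensities: np.ndarray, sigma_px: float = 1.5
) -> np.ndarray:
    """Edge force: gradient of the gradient-of-Gaussian edge magnitude.

    ``intensities`` is (S, F, R, C); the returned field is (S, F, R, C, 2)
    with components (fx, fy), normalized to unit maximum magnitude per
    slice/frame. Vectors point uphill on the edge-magnitude map, i.e.
    toward intensity edges from both sides.
    """
    arr = np.asarray(intensities, dtype=np.float64)
    sig = (0, 0, sigma_px, sigma_px)
    gy = ndimage.gaussian_filter(arr, sigma=sig, order=(0, 0, 1, 0))
    gx = ndimage.gaussian_filter(arr, sigma=sig, order=(0, 0, 0, 1))
    mag = np.hypot(gx, gy)
    fy = np.gradient(mag, axis=2)
    fx = np.gradient(mag, axis=3)
    field4 = np.stack([fx, fy], axis=-1)
    peak = np.max(np.abs(field4), axis=(2, 3, 4), keepdims=True)
    return field4 / np.maximum(peak, 1e-12)


def curvature_force(nodes: np.ndarray) -> np.ndarray:
    """Discrete second difference along the closed chain, (..., N, 2).

    Zero on straight segments; points inward on convex arcs with magnitude
    proportional to curvature times the squared node spacing.
    """
    return np.roll(nodes, -1, axis=-2) + np.roll(nodes, 1, axis=-2) - 2 * nodes


def coupling_forces(
    pos: np.ndarray, present: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Inter-slice and temporal coupling forces for an (S, F, N, 2) state.

    Inter-slice: pull toward the mean of corresponding nodes in the
    adjacent slices of the same frame. Edge slices (one neighbour) get
    zero force — pulling the apical slice toward its much larger
    neighbour would inflate it systematically; a single-slice stack gets
    zero force everywhere. Temporal: discrete
    second difference across frames with cyclic wrap — retrospectively
    gated cine covers exactly one cardiac cycle, so frame N-1 neighbours
    frame 0.
    """
    s = pos.shape[0]
    pres = present[..., None, None]
    inter = np.zeros_like(pos)
    if s > 1:
        nb_sum = np.zeros_like(pos)
        nb_cnt = np.zeros(pos.shape[:2] + (1, 1))
        up = np.roll(pos, 1, axis=0)
        up_ok = np.roll(present, 1, axis=0)[..., None, None].astype(float)
        up_ok[0] = 0.0
        dn = np.roll(pos, -1, axis=0)
        dn_ok = np.roll(present, -1, axis=0)[..., None, None].astype(float)
        dn_ok[-1] = 0.0
        nb_sum = up * up_ok + dn * dn_ok
        nb_cnt = up_ok + dn_ok
        mean_nb = np.where(nb_cnt >= 2, nb_sum / np.maximum(nb_cnt, 1.0), pos)
        inter = (mean_nb - pos) * pres
    nxt = np.roll(pos, -1, axis=1)
    prv = np.roll(pos, 1, axis=1)
    temporal = (nxt + prv - 2 * pos) * pres
    return inter, temporal


def reparameterize_equidistant(nodes: np.ndarray) -> np.ndarray:
    """Resample closed chains to equal arc-length node spacing.

    Idempotent up to floating point on already-equidistant chains;
    preserves the polygonal curve and the node count.
    """
    return resample_closed(nodes)


def _bilinear(field: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Sample a (S, F, R, C[, k]) field at (S, F, N, 2) positions."""
    s, f = pos.shape[:2]
    rows, cols = field.shape[2], field.shape[3]
    x = np.clip(pos[..., 0], 0.0, cols - 1.0)
    y = np.clip(pos[..., 1], 0.0, rows - 1.0)
    x0 = np.floor(x).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    x1 = np.minimum(x0 + 1, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    fx = (x - x0)[..., None] if field.ndim == 5 else (x - x0)
    fy = (y - y0)[..., None] if field.ndim == 5 else (y - y0)
    si = np.arange(s)[:, None, None]
    fi = np.arange(f)[None, :, None]
    v00 = field[si, fi, y0, x0]
    v01 = field[si, fi, y0, x1]
    v10 = field[si, fi, y1, x0]
    v11 = field[si, fi, y1, x1]
    return (
        v00 * (1 - fx) * (1 - fy)
        + v01 * fx * (1 - fy)
        + v10 * (1 - fx) * fy
        + v11 * fx * fy
    )


def deform(
    init_contours: np.ndarray,
    present: np.ndarray,
    balloon: BalloonImage | np.ndarray,
    edge_field: np.ndarray | None,
    weights: ForceWeights,
    config: DeformConfig | None = None,
) -> tuple[np.ndarray, DeformReport]:
    """Evolve all contours of one border to convergence.

    Parameters
    ----------
    init_contours
        (S, F, N, 2) initial node positions.
    present
        (S, F) bool; absent slice/frames are left untouched.
    balloon
        Balloon image (S, F, R, C) driving inflation/deflation.
    edge_field
        Optional (S, F, R, C, 2) edge force field.
    weights, config
        Force weighting and solver numerics.

    Returns the final (S, F, N, 2) positions and a report with iteration
    counts, convergence state, and per-slice/frame collapse flags
    (contours whose area fell below the collapse threshold are frozen).
    """
    config = config or DeformConfig()
    bal = balloon.values if isinstance(balloon, BalloonImage) else np.asarray(balloon)
    rows, cols = bal.shape[2], bal.shape[3]
    if config.smooth_sigma_px > 0:
        bal = ndimage.gaussian_filter(
            bal, sigma=(0, 0, config.smooth_sigma_px, config.smooth_sigma_px)
        )
        if edge_field is not None:
            edge_field = ndimage.gaussian_filter(
                edge_field,
                sigma=(0, 0, config.smooth_sigma_px, config.smooth_sigma_px, 0),
            )
    pos = np.array(init_contours, dtype=np.float64, copy=True)
    vel = np.zeros(pos.shape[:3])
    active = np.array(present, dtype=bool, copy=True)
    collapsed = np.zeros_like(active)
    report = DeformReport(collapsed=collapsed)
    damp_keep = 1.0 / (1.0 + weights.w_damping)
    best_disp = np.inf
    best_iter = 0
    for it in range(config.max_iter):
        normals = outward_normals(pos)
        f_total = np.zeros(pos.shape[:3])
        if weights.w_balloon > 0:
            f_total += weights.w_balloon * _bilinear(bal, pos)
        if weights.w_edge > 0 and edge_field is not None:
            f_vec = _bilinear(edge_field, pos)
            f_total += weights.w_edge * np.sum(f_vec * normals, axis=-1)
        if weights.w_curv_inplane > 0:
            f_total += weights.w_curv_inplane * np.sum(
                curvature_force(pos) * normals, axis=-1
            )
        if weights.w_curv_interslice > 0 or weights.w_temporal > 0:
            inter, temporal = coupling_forces(pos, active)
            if weights.w_curv_interslice > 0:
                f_total += weights.w_curv_interslice * np.sum(
                    inter * normals, axis=-1
                )
            if weights.w_temporal > 0:
                f_total += weights.w_temporal * np.sum(temporal * normals, axis=-1)
        # normalize: scale each contour's force pattern down to unit peak
        peak = np.max(np.abs(f_total), axis=-1, keepdims=True)
        f_total = f_total / np.maximum(peak, 1.0)
        vel = damp_keep * vel + f_total
        disp = config.step_px * np.clip(vel, -1.0, 1.0)
        disp = disp * active[..., None]
        pos = pos + disp[..., None] * normals
        pos[..., 0] = np.clip(pos[..., 0], 0.0, cols - 1.0)
        pos[..., 1] = np.clip(pos[..., 1], 0.0, rows - 1.0)
        pos = anchor_start(reparameterize_equidistant(pos))
        # collapse guard (every iteration: a contour can shrink through
        # zero area quickly under a uniformly negative balloon)
        areas = np.abs(signed_areas(pos))
        newly = active & (areas < config.min_area_px)
        if newly.any():
            collapsed |= newly
            active &= ~newly
        max_disp = float(np.max(np.abs(disp))) if active.any() else 0.0
        report.max_disp_history.append(max_disp)
        report.iterations = it + 1
        if max_disp < config.tol_px:
            report.converged = True
            break
        if max_disp < best_disp - 1e-9:
            best_disp = max_disp
            best_iter = it
        elif it - best_iter >= config.stall_window:
            report.stalled = True
            break
    report.collapsed = collapsed
    return pos, report
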