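"""Intensity modelling: LV localisation, EM mixture fit, balloon images.

The balloon force is the main driving force of the deformable model. It is
derived from a Gaussian mixture over the pooled image intensities with one
component per tissue class (blood, myocardium, and — for the epicardial
force — surrounding tissue). The per-pixel posterior ratio is mapped to
[-1, 1]: positive where the contour should expand to include the pixel,
negative where it should contract to exclude it, zero where the classes are
equally probable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import CineStack
from .errors import LVNotFoundError, StageError

BLOOD = "blood"
MYOCARDIUM = "myocardium"
SURROUND = "surround"


@dataclass
class GaussianComponent:
    label: str
    mean: float
    sd: float
    weight: float


@dataclass
class MixtureModel:
    """Gaussian intensity mixture with named tissue components.

    Invariant for bright-blood cine imaging: the blood mean exceeds the
    myocardium mean. ``degenerate`` is set when EM collapsed components onto
    each other or emptied a weight; ``converged`` reflects the EM stop
    criterion.
    """

    components: list[GaussianComponent]
    log_likelihood: list[float] = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self):
        w = sum(c.weight for c in self.components)
        if not np.isclose(w, 1.0, atol=1e-6):
            raise ValueError(f"component weights must sum to 1; got {w}")
        for c in self.components:
            if c.sd <= 0:
                raise ValueError(f"component {c.label} has non-positive sd")

    def component(self, label: str) -> GaussianComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)

    def log_densities(self, values: np.ndarray, weighted: bool = False) -> np.ndarray:
        """Log densities, shape (n_components,) + values.shape.

        The balloon images use the plain (unweighted) class densities, so a
        pixel where the blood and myocardium densities are equal gets force
        exactly zero regardless of the class proportions in the image.
        """
        values = np.asarray(values, dtype=np.float64)
        out = np.empty((len(self.components),) + values.shape)
        for i, c in enumerate(self.components):
            out[i] = (
                -0.5 * np.log(2 * np.pi * c.sd**2)
                - 0.5 * ((values - c.mean) / c.sd) ** 2
            )
            if weighted:
                out[i] += np.log(max(c.weight, 1e-300))
        return out


@dataclass
class BalloonImage:
    """Per-pixel inflation force in [-1, 1], per (slice, frame, row, col)."""

    values: np.ndarray
    border: str  # "endo" | "epi"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("balloon values must lie in [-1, 1]")
        self.values = np.clip(v, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Step 1: LV center point
# ---------------------------------------------------------------------------

def locate_lv_center(
    stack: CineStack,
    smooth_sigma_mm: float = 5.0,
    min_area_mm2: float = 100.0,
) -> tuple[float, float]:
    """Locate the LV blood-pool center on the time-averaged mid-stack slice.

    The whole-heart center is first taken as the intensity-weighted centroid
    of all bright pixels after heavy smoothing and Otsu thresholding. The LV
    is then the large bright connected region whose centroid lies closest to
    the right of that point (on a supine short-axis view the LV sits to the
    image right of the RV).

    Returns ``(x, y)`` in pixel coordinates. Raises :class:`LVNotFoundError`
    when no bright region survives thresholding (e.g. a constant image).
    """
    b, a = stack.analyzed_slice_range
    mid = (b + a) // 2
    img = stack.intensities[mid].mean(axis=0)  # time-averaged
    if img.max() - img.min() <= 1e-12:
        raise LVNotFoundError("image has no dynamic range; no bright region found")
    sr, sc = stack.pixel_spacing_mm
    sigma_px = (smooth_sigma_mm / sr, smooth_sigma_mm / sc)
    smoothed = ndimage.gaussian_filter(img, sigma=sigma_px)
    thr = threshold_otsu(smoothed)
    bright = smoothed > thr
    if not bright.any():
        raise LVNotFoundError("no pixels above threshold")
    # whole-heart center: intensity-weighted centroid of the bright mass
    ys, xs = np.nonzero(bright)
    w = smoothed[ys, xs]
    heart_x = float(np.sum(xs * w) / np.sum(w))
    heart_y = float(np.sum(ys * w) / np.sum(w))
    # split merged pools: require the raw time-average to be bright as well
    refined = bright & (img > thr)
    if not refined.any():
        refined = bright
    labels, n = ndimage.label(refined)
    if n == 0:
        raise LVNotFoundError("no connected bright region")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    min_area_px = min_area_mm2 / stack.pixel_area_mm2
    keep = [
        i + 1
        for i, area in enumerate(areas)
        if area >= max(min_area_px, 0.2 * areas.max())
    ]
    if not keep:
        raise LVNotFoundError("no sufficiently large bright region")
    centroids = ndimage.center_of_mass(img, labels, index=keep)  # (row, col)
    # candidates to the right of the heart center; nearest one wins
    best = None
    for lab, (cy, cx) in zip(keep, centroids):
        if cx >= heart_x - 2.0:
            d = np.hypot(cx - heart_x, cy - heart_y)
            if best is None or d < best[0]:
                best = (d, cx, cy)
    if best is None:
        # nothing to the right: fall back to the largest region
        lab = keep[int(np.argmax([areas[k - 1] for k in keep]))]
        cy, cx = ndimage.center_of_mass(img, labels, index=lab)
        return float(cx), float(cy)
    return float(best[1]), float(best[2])


# ---------------------------------------------------------------------------
# Step 2: EM mixture and balloon images
# ---------------------------------------------------------------------------

def init_blood_stats(
    stack: CineStack,
    lv_center: tuple[float, float],
    radius_mm: float = 10.0,
    min_pixels: int = 30,
) -> tuple[float, float]:
    """Mean/SD of intensity in a cylinder of given in-plane radius at the LV
    center, spanning the analyzed slices and all frames.

    The cylinder is clipped (with a flag-free warning path) where it exits
    the image; fewer than ``min_pixels`` samples is an error.
    """
    x0, y0 = lv_center
    sr, sc = stack.pixel_spacing_mm
    rows, cols = stack.grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    in_cyl = ((xx - x0) * sc) ** 2 + ((yy - y0) * sr) ** 2 <= radius_mm**2
    b, a = stack.analyzed_slice_range
    samples = stack.intensities[b : a + 1, :, in_cyl]
    if samples.size < min_pixels:
        raise StageError(
            "init_blood_stats",
            f"blood cylinder holds {samples.size} pixels (< {min_pixels})",
        )
    return float(samples.mean()), float(samples.std())


def _histogram(stack: CineStack, n_bins: int = 512,
               lv_center: tuple[float, float] | None = None,
               roi_radius_mm: float | None = None):
    b, a = stack.analyzed_slice_range
    if lv_center is not None and roi_radius_mm is not None:
        x0, y0 = lv_center
        sr, sc = stack.pixel_spacing_mm
        rows, cols = stack.grid_shape
        yy, xx = np.mgrid[0:rows, 0:cols]
        roi = ((xx - x0) * sc) ** 2 + ((yy - y0) * sr) ** 2 <= roi_radius_mm**2
        data = stack.intensities[b : a + 1, :, roi].ravel()
    else:
        data = stack.intensities[b : a + 1].ravel()
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:
        hi = lo + 1.0
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(np.float64), lo, hi


def fit_mixture(
    stack: CineStack,
    blood_init: tuple[float, float],
    n_components: int = 3,
    tol: float = 1e-6,
    max_iter: int = 200,
    sd_floor_frac: float = 0.01,
    n_bins: int = 512,
    lv_center: tuple[float, float] | None = None,
    roi_radius_mm: float | None = 55.0,
) -> MixtureModel:
    """Fit a 2- or 3-component Gaussian mixture to the pooled intensity
    histogram of the analyzed slices and frames via EM.

    When ``lv_center`` is given, pooling is restricted to a heart-sized
    disk (default 55 mm radius) around it: the balloon forces only matter
    near the heart, and whole-image pooling lets distant background mass
    drag the myocardium component toward the background mode. The blood
    component is seeded from the blood-cylinder statistics; the myocardium
    component at half the blood mean with the blood SD; the surround
    component (3-component fit only) at the 25th intensity percentile with
    the pooled SD. A floor of 1% of the intensity range keeps components
    from collapsing; collapse triggers a re-spread and the ``degenerate``
    flag. The per-sample average log-likelihood is recorded each iteration
    and is non-decreasing up to the floor interventions.
    """
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    centers, counts, lo, hi = _histogram(stack, n_bins, lv_center, roi_radius_mm)
    n_total = counts.sum()
    sd_floor = max(sd_floor_frac * (hi - lo), 1e-6)

    mu_b, sd_b = blood_init
    sd_b = max(sd_b, sd_floor)
    # pooled statistics from the (possibly ROI-restricted) histogram
    pool_mean = float(np.sum(centers * counts) / max(n_total, 1.0))
    pool_sd = max(
        float(np.sqrt(np.sum(counts * (centers - pool_mean) ** 2)
                      / max(n_total, 1.0))),
        sd_floor,
    )
    cdf = np.cumsum(counts) / max(n_total, 1.0)
    q25 = float(centers[int(np.searchsorted(cdf, 0.25))])
    means = [mu_b, mu_b / 2.0]
    sds = [sd_b, sd_b]
    labels = [BLOOD, MYOCARDIUM]
    if n_components == 3:
        means.append(q25)
        sds.append(pool_sd)
        labels.append(SURROUND)
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    weights = np.full(n_components, 1.0 / n_components)

    ll_hist: list[float] = []
    degenerate = False
    converged = False
    for _ in range(max_iter):
        # E-step on the histogram (log-space for numerical safety)
        logp = (
            np.log(np.maximum(weights[:, None], 1e-300))
            - 0.5 * np.log(2 * np.pi * sds[:, None] ** 2)
            - 0.5 * ((centers[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.sum(np.exp(logp - m), axis=0))
        resp = np.exp(logp - lse)  # (K, bins)
        ll = float(np.sum(counts * lse) / n_total)
        ll_hist.append(ll)
        # M-step with bin counts as weights
        nk = resp @ counts
        empty = nk < 1e-8 * n_total
        nk = np.maximum(nk, 1e-12)
        new_means = (resp * centers[None, :]) @ counts / nk
        var = (resp * (centers[None, :] - new_means[:, None]) ** 2) @ counts / nk
        new_sds = np.sqrt(np.maximum(var, 0.0))
        collapsed = new_sds < sd_floor
        if collapsed.any() or empty.any():
            degenerate = True
            new_sds = np.maximum(new_sds, sd_floor)
            # re-spread any collapsed/empty component across the range
            for k in np.nonzero(collapsed | empty)[0]:
                new_sds[k] = max(new_sds[k], 0.05 * (hi - lo))
        means, sds = new_means, new_sds
        weights = nk / nk.sum()
        if len(ll_hist) >= 2 and abs(ll_hist[-1] - ll_hist[-2]) < tol * max(
            abs(ll_hist[-2]), 1e-12
        ):
            converged = True
            break

    # unresolved adjacent component pairs in the final fit flag degeneracy
    # (e.g. two components requested for single-class data): Ashman's
    # D < 2 means the pair is effectively unimodal
    order = np.argsort(means)
    mu_o, sd_o = means[order], sds[order]
    ashman = np.abs(np.diff(mu_o)) / np.sqrt(0.5 * (sd_o[:-1] ** 2 + sd_o[1:] ** 2))
    if np.any(ashman < 2.0):
        degenerate = True

    # keep the semantic ordering: blood is the brightest of blood/myocardium
    idx = {lab: i for i, lab in enumerate(labels)}
    if means[idx[BLOOD]] < means[idx[MYOCARDIUM]]:
        i, j = idx[BLOOD], idx[MYOCARDIUM]
        means[[i, j]] = means[[j, i]]
        sds[[i, j]] = sds[[j, i]]
        weights[[i, j]] = weights[[j, i]]
    comps = [
        GaussianComponent(lab, float(means[idx[lab]]), float(sds[idx[lab]]),
                          float(weights[idx[lab]]))
        for lab in labels
    ]
    return MixtureModel(
        components=comps,
        log_likelihood=ll_hist,
        converged=converged,
        degenerate=degenerate,
    )


def _posterior_pair(values: np.ndarray, mixture: MixtureModel, num: list[str],
                    den: list[str]) -> np.ndarray:
    """p = sum(num densities) / sum(den densities), computed in log space.

    Where every density underflows, the pixel is assigned by nearest mean
    (probability 0 or 1).
    """
    logs = {c.label: None for c in mixture.components}
    values = np.asarray(values, dtype=np.float64)
    all_logs = mixture.log_densities(values)
    for i, c in enumerate(mixture.components):
        logs[c.label] = all_logs[i]
    num_logs = np.stack([logs[l] for l in num])
    den_logs = np.stack([logs[l] for l in den])
    m = den_logs.max(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.exp(num_logs - m[None]).sum(axis=0) / np.exp(
            den_logs - m[None]
        ).sum(axis=0)
    # underflow guard: assign by nearest mean among the denominator classes
    bad = ~np.isfinite(p) | (m < -700)
    if bad.any():
        den_means = np.asarray([mixture.component(l).mean for l in den])
        nearest = np.argmin(
            np.abs(values[..., None] - den_means), axis=-1
        )
        in_num = np.isin(np.asarray(den)[nearest], num)
        p = np.where(bad, in_num.astype(np.float64), p)
    return np.clip(p, 0.0, 1.0)


def endo_balloon(stack: CineStack, mixture: MixtureModel) -> BalloonImage:
    """Endocardial balloon: p = G_blood / (G_blood + G_myo), mapped 2p - 1.

    Zero where blood and myocardium are equally probable; +1 deep in blood,
    -1 deep in myocardium.
    """
    p = _posterior_pair(stack.intensities, mixture, [BLOOD], [BLOOD, MYOCARDIUM])
    return BalloonImage(values=2.0 * p - 1.0, border="endo")


def epi_balloon(
    stack: CineStack, mixture: MixtureModel, endo_masks: np.ndarray | None = None
) -> BalloonImage:
    """Epicardial balloon: p = G_myo / (G_blood + G_myo + G_surround),
    mapped 2p - 1 and forced to zero inside the endocardial masks.

    Negative for blood and for tissue surrounding the myocardium, so the
    epicardial contour contracts onto the outer wall from either side.
    """
    labels = [c.label for c in mixture.components]
    if SURROUND not in labels:
        raise ValueError("epicardial balloon needs a 3-component mixture")
    p = _posterior_pair(
        stack.intensities, mixture, [MYOCARDIUM], [BLOOD, MYOCARDIUM, SURROUND]
    )
    values = 2.0 * p - 1.0
    if endo_masks is not None:
        values = np.where(np.asarray(endo_masks, dtype=bool), 0.0, values)
    return BalloonImage(values=values, border="epi")
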