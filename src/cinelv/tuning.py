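"""Force-weight optimization against reference contours.

The deformable-model weights are tuned by steepest descent on a factorial
design: each round evaluates the cost at all 2^k corner perturbations of
the k active weights (multiplicative, in log space, which keeps weights
positive), estimates the descent direction from the factorial main
effects, and steps; rounds without improvement shrink the perturbation
factor. The endocardial cost is the relative end-diastolic volume error
plus the relative count of falsely segmented end-diastolic pixels; the
epicardial cost adds the relative left-ventricular-mass error (computed
against the *reference* endocardium so endocardial errors do not leak in)
and the false-pixel fraction, in both end-diastole and end-systole.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CineStack, SegmentationResult
from .deformable import ForceWeights
from .evaluation import MYOCARDIAL_DENSITY_G_PER_ML, cavity_volume_curve, result_masks


@dataclass
class TuningCase:
    """One training image with its reference segmentation."""

    stack: CineStack
    reference: SegmentationResult


@dataclass
class TuningConfig:
    active: tuple[str, ...] = ("w_balloon", "w_curv_inplane")
    perturb_factor: float = 2.0
    shrink: float = 0.5
    tol_factor: float = 1.05
    max_rounds: int = 20


@dataclass
class TuningTrace:
    """Per-round record of the factorial search."""

    costs: list[float] = field(default_factory=list)       # accepted costs
    evaluations_per_round: list[int] = field(default_factory=list)
    factors: list[float] = field(default_factory=list)
    weights: list[dict] = field(default_factory=list)


def _phase_frames(reference: SegmentationResult, stack: CineStack) -> tuple[int, int]:
    vol = cavity_volume_curve(reference, stack, "endo")
    return int(np.argmax(vol)), int(np.argmin(vol))


def endo_cost(
    auto: SegmentationResult, reference: SegmentationResult, stack: CineStack
) -> float:
    """Relative EDV error + relative false-pixel count, end-diastole only.

    End-systolic errors are dominated by papillary handling, which the
    deformable model itself does not address, so only end-diastole enters
    the endocardial cost.
    """
    ed, _ = _phase_frames(reference, stack)
    ref_vol = cavity_volume_curve(reference, stack, "endo")[ed]
    if ref_vol <= 0:
        raise ValueError("reference end-diastolic volume is zero")
    auto_vol = cavity_volume_curve(auto, stack, "endo")[ed]
    vol_term = abs(auto_vol - ref_vol) / ref_vol
    ref_mask = result_masks(reference, stack, ed, "endo")
    auto_mask = result_masks(auto, stack, ed, "endo")
    n_ref = int(ref_mask.sum())
    false_px = int((auto_mask & ~ref_mask).sum() + (ref_mask & ~auto_mask).sum())
    return vol_term + false_px / n_ref


def epi_cost(
    auto: SegmentationResult, reference: SegmentationResult, stack: CineStack
) -> float:
    """Relative LVM error + relative false pixels, in both ED and ES.

    The mass pairs the automatic epicardium with the *reference*
    endocardium, so the epicardial weights are not punished (or rewarded)
    for endocardial volume errors.
    """
    ed, es = _phase_frames(reference, stack)
    endo_vol = cavity_volume_curve(reference, stack, "endo")
    ref_epi_vol = cavity_volume_curve(reference, stack, "epi")
    auto_epi_vol = cavity_volume_curve(auto, stack, "epi")
    cost = 0.0
    for frame in (ed, es):
        ref_mass = MYOCARDIAL_DENSITY_G_PER_ML * (ref_epi_vol[frame] - endo_vol[frame])
        if ref_mass <= 0:
            raise ValueError("reference myocardial mass is zero")
        auto_mass = MYOCARDIAL_DENSITY_G_PER_ML * (
            auto_epi_vol[frame] - endo_vol[frame]
        )
        cost += abs(auto_mass - ref_mass) / ref_mass
        ref_mask = result_masks(reference, stack, frame, "epi")
        auto_mask = result_masks(auto, stack, frame, "epi")
        false_px = int(
            (auto_mask & ~ref_mask).sum() + (ref_mask & ~auto_mask).sum()
        )
        cost += false_px / int(ref_mask.sum())
    return cost


def tune_weights(
    cases_or_cost,
    init: ForceWeights,
    config: TuningConfig | None = None,
    border: str = "endo",
) -> tuple[ForceWeights, TuningTrace]:
    """Steepest-descent tuning of the active force weights.

    ``cases_or_cost`` is either a list of :class:`TuningCase` (the cost is
    then the summed segmentation cost over the cases, endocardial or
    epicardial per ``border``) or a callable ``cost(ForceWeights) ->
    float`` for direct use on synthetic cost surfaces. The accepted-cost
    trace is non-increasing by construction; each round spends exactly
    2^k evaluations on the factorial corners.
    """
    config = config or TuningConfig()
    if callable(cases_or_cost):
        cost_fn = cases_or_cost
    else:
        cases = list(cases_or_cost)
        if not cases:
            raise ValueError("no tuning cases given")
        cost_fn = _make_case_cost(cases, border)

    active = list(config.active)
    k = len(active)
    current = replace(init)
    current_cost = float(cost_fn(current))
    trace = TuningTrace()
    trace.costs.append(current_cost)
    trace.weights.append(current.asdict())
    factor = config.perturb_factor
    for _ in range(config.max_rounds):
        if factor <= config.tol_factor:
            break
        corners = []
        corner_costs = []
        n_fail = 0
        for signs in itertools.product((-1.0, 1.0), repeat=k):
            w = replace(current, **{
                name: getattr(current, name) * factor**sign
                for name, sign in zip(active, signs)
            })
            try:
                c = cost_fn(w)
            except Exception:
                n_fail += 1
                c = math.inf
            corners.append((signs, w))
            corner_costs.append(c)
        trace.evaluations_per_round.append(2**k)
        trace.factors.append(factor)
        if n_fail == 2**k:
            raise RuntimeError("cost evaluation failed at every corner")
        corner_costs = np.asarray(corner_costs)
        signs_arr = np.asarray([s for s, _ in corners])
        finite = np.isfinite(corner_costs)
        # factorial main effects -> descent direction in log space
        effects = np.array([
            corner_costs[finite & (signs_arr[:, j] > 0)].mean()
            - corner_costs[finite & (signs_arr[:, j] < 0)].mean()
            if (finite & (signs_arr[:, j] > 0)).any()
            and (finite & (signs_arr[:, j] < 0)).any()
            else 0.0
            for j in range(k)
        ])
        candidates = []
        if np.any(effects != 0.0):
            step_w = replace(current, **{
                name: getattr(current, name) * factor ** (-np.sign(e))
                for name, e in zip(active, effects)
            })
            try:
                candidates.append((float(cost_fn(step_w)), step_w))
            except Exception:
                pass
        best_corner = int(np.argmin(corner_costs))
        candidates.append((float(corner_costs[best_corner]),
                           corners[best_corner][1]))
        cand_cost, cand_w = min(candidates, key=lambda t: t[0])
        if cand_cost < current_cost - 1e-12:
            current, current_cost = cand_w, cand_cost
            trace.costs.append(current_cost)
            trace.weights.append(current.asdict())
        else:
            factor = 1.0 + (factor - 1.0) * config.shrink
    return current, trace


def _make_case_cost(cases, border):
    from .pipeline import RunConfig, run_segment

    def cost(weights: ForceWeights) -> float:
        total = 0.0
        n_ok = 0
        for case in cases:
            cfg = RunConfig()
            if border == "endo":
                cfg.deform.endo_weights = weights
            else:
                cfg.deform.epi_weights = weights
            try:
                result, _ = run_segment(case.stack, cfg)
                fn = endo_cost if border == "endo" else epi_cost
                total += fn(result, case.reference, case.stack)
                n_ok += 1
            except Exception:
                continue
        if n_ok == 0:
            raise RuntimeError("all tuning cases failed to segment")
        return total

    return cost
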