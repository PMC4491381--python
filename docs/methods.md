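# Methods

This note documents the model, the numerical choices, and the synthetic
data behind cinelv, at the level a maintainer needs to modify either.

## Intensity model

Pixel intensities near the heart are modelled as a mixture of Gaussian
classes — blood, myocardium, and (for the epicardial force) surrounding
tissue — fitted by EM on a single pooled histogram (512 bins) over all
analyzed slices and frames. Pooling is restricted to a heart-sized disk
(default radius 55 mm) around the detected LV centre: the balloon forces
are only consumed near the heart, and whole-image pooling lets distant
background mass pull the myocardium component toward the background mode
(on synthetic data this shifted the myocardium mean from ≈150 to ≈125 and
corrupted the epicardial force in background regions). The EM is seeded
from measured data: the blood component from the mean/SD inside a 10 mm
cylinder at the LV centre, the myocardium component at half the blood
mean with the blood SD, the surround component at the 25th pooled
percentile with the pooled SD.

Safeguards: an SD floor of 1% of the intensity range, with re-spread of
collapsed or emptied components (flagged `degenerate`); convergence at
relative log-likelihood change < 1e-6, cap 200 iterations; a final
bimodality check (Ashman's D < 2 between adjacent components) flags fits
where two components model one mode, which happens when fewer classes are
present than requested. The flag is informational — the pipeline
continues — but it is a useful SNR indicator (the low-SNR phantom trips
it; the clean conditions do not).

The balloon images use the *unweighted* class densities, so zero force
falls exactly where two class densities are equal, independent of class
prevalence. Both balloons are mapped by `2p − 1` into [−1, 1]; where all
densities underflow, the pixel is assigned ±1 by nearest class mean.

## Deformable model

All contours of one border — every analyzed slice, every frame — evolve
as one state (S, F, 80, 2), which makes the coupling terms act on the
current neighbours rather than a frozen snapshot. Per iteration the
scalar force along the outward normal is the weighted sum of:

- balloon value sampled bilinearly at the node,
- edge force: the gradient (central differences) of the
  gradient-of-Gaussian edge magnitude (σ = 1.5 px), normalized to unit
  peak per slice/frame, dotted with the normal,
- in-slice curvature: the discrete second difference along the chain,
- inter-slice coupling: pull toward the mean of corresponding nodes in
  the two adjacent slices. Edge slices (one neighbour) get **zero**
  inter-slice force: a pull toward the single neighbour is systematically
  outward at the apex, where the neighbour is always larger, and inflated
  the apical contour by >2 mm in testing,
- temporal acceleration: the cyclic second difference across frames
  (retrospectively gated cine covers exactly one cycle, so the last frame
  neighbours the first).

The total force per contour is normalized by `max(1, peak)` — scaled
down, never up. Scaling up to unit peak (the other reading of
"normalized") amplifies the residual forces near equilibrium and turns
convergence into a permanent limit cycle; scale-down-only preserves the
spatial force pattern while letting the displacement genuinely decay.
Integration is damped explicit Euler: velocity `v ← v/(1 + w_damping) +
force`, displacement capped at 0.5 px per iteration, positions clamped to
the image, nodes re-spaced to equal arc length (and re-anchored at the +x
direction from the centroid, which keeps node correspondence across
slices and frames for the coupling terms). Stopping: max displacement
< 0.05 px, or no new displacement minimum for 50 iterations (oscillation
guard), or 500 iterations. Contours whose area falls below 4 px² are
frozen and flagged collapsed. Inside the solver both force fields are
pre-smoothed with σ = 1 px so the near-boundary force decays smoothly and
the displacement criterion is meaningful; the balloon's zero level is
preserved up to the asymmetry of the transition.

Default weights (balloon 1.0, edge 0.3, in-plane curvature 0.5,
inter-slice 0.2, temporal 0.1, damping 1.0, both borders) were chosen by
the package's own tuning procedure on synthetic training stacks. The
temporal weight is deliberately the smallest: across a presence
transition (a basal slice whose wall leaves the plane between frames) the
temporal term drags the epicardium toward its wall-bearing neighbour
frames and can hold a ~2 mm pseudo-wall of background open, masking the
through-plane motion from the detector. Weights are image-type-specific
by design; the `tuning` module exists to re-fit them.

## Sector analysis, outflow, papillaries

The wall between the contours is divided into 24 circumferential sectors
around the endocardial centroid, with sector 0 at the septal reference
direction (LV centre → RV pool centroid; image-left if no RV is found).
Wall thickness per sector is the mean radial gap sampled on 10 rays per
sector; wall intensity is the mean over wall pixels binned by angle. All
sector geometry runs in millimetres so anisotropic pixels are handled.

Outflow detection pools the per-sector wall intensities over *all*
analyzed slices and frames for the reference statistics, flags basal
sectors (most basal 40% of the slice count at end-diastole) brighter than
mean + 2 SD or thinner than 2 mm, requires support in the adjacent more
basal slice (the most basal slice is exempt), smooths with 3-tap circular
majority filters over sectors and frames, opens with a 2-sector element,
and keeps the single largest circular run, capped at 180°. The flagged
arc is replaced on both contours by the chord between its endpoint radii.
A fully flagged slice/frame is removed; removed-slice counts per frame,
relative to end-diastole, are the long-axis displacement.

Papillary volume per sector is the volume of negative-balloon pixels
inside the endocardium, measured against the *original* endocardial
balloon (Step 6 zeroes papillary pixels in its working copy, which would
otherwise erase the signal Step 8 needs). Sectors below the basal band
whose volume falls >10% short of the end-diastolic reference (mapped
through the long-axis displacement: ED slice = s − displacement) are
expanded radially in 0.25 mm steps, at most 3 mm, clamped half a pixel
inside the epicardium. Expansion never shrinks a contour and never moves
nodes of non-deficit sectors.

## Evaluation conventions

Volumes are summation of disks: polygon area × slice spacing (thickness +
gap), no inter-slice interpolation. ED/ES are the frames of maximal and
minimal cavity volume. LVM = (epi − endo volume) × 1.05 g/mL averaged
over ED and ES. Dice is computed volumetrically per phase (all analyzed
slices pooled) and the "overall" figure averages ED and ES. Point-to-
curve resamples each border to 80 points at 4.5° on rays from its own
centroid and symmetrizes the mean point-to-polygon distance; non-star-
shaped contours fall back to nearest-node sampling, flagged. Regional
splits are contiguous thirds (remainders basal first, then mid),
recomputed per phase because the end-systolic stack can be shorter.

## Synthetic phantom

The phantom renders a truncated half-ellipsoid cavity of length L =
n_slices × slice spacing, with the apex closing exactly at the far edge
of the most apical analyzed slice — so the configured EDV equals the
analytic truth over the analyzed extent. The per-frame cavity volume
follows a piecewise-cosine curve from EDV to ESV (end-systole at 40% of
the cycle) and back; the in-plane radius scale is solved per frame from
the target volume and the current AV-plane cut. Wall thickness
interpolates between its ED and ES values on the same phase curve. The
AV plane translates apically by up to the configured displacement; a
slice whose centre lies above it is rendered as a blood pool without wall
(no through-plane partial volume — transitions are binary per frame,
which makes the truth displacement exact). The outflow tract is an
angular arc of wall replaced by blood in the basal slices; papillaries
are fixed-radius spheres (volume constant by construction), detached ones
riding at half the endocardial radius, attached ones fixed in space at
the end-diastolic border so systolic wall thickening absorbs them; an RV
blood crescent hugs the epicardium over a 120° septal arc.

Intensities: blood 300 ± 20, myocardium 150 ± 15, surround 80 ± 30
(arbitrary units, bright-blood ordering), per-class Gaussian noise.
Surround heterogeneity is half smooth field (σ = 20 mm), half iid, so the
marginal surround SD matches the configured value; `noise_sd` adds a
separate global term (30 in the low-SNR condition). With all SDs zero the
rendered stack contains exactly the class means plus antialiasing ramps.
Defaults mirror the targeted acquisition: 1.4 × 1.4 mm pixels, 8 mm
slices, 30 frames, 112² grid, 8 slices, EDV 150 mL, EF 60%, wall
10→14 mm.

What passing on the phantom does **not** show: robustness to MR physics
(banding, coil shading, fold-in artifacts), trabeculation, real papillary
shapes, breath-hold slice misregistration, or arrhythmic gating — the
phantom's classes are cleanly Gaussian and its geometry is star-shaped by
construction. Clinical accuracy claims require real delineated data.

## Tuning

Weights are tuned in log space (multiplicative perturbation factor 2,
shrink 0.5 toward 1, stop below 1.05 or after 20 rounds): per round, the
cost is evaluated at all 2^k corners of the active-weight factorial, the
descent direction is the sign pattern of the factorial main effects, and
the better of the effect step and the best corner is accepted only if it
improves — so the accepted-cost trace is non-increasing by construction.
The endocardial cost is the relative EDV error plus the relative
false-pixel count at end-diastole only; the epicardial cost adds relative
LVM error (against the reference endocardium) and false pixels in both
phases. Endo and epi weight sets are tuned in separate passes.

## Problem sizes

The shipped test and acceptance runs use the full-resolution suite
phantoms (112² × 8 slices × 30 frames) for end-to-end checks and a
reduced phantom (72² × 4 slices × 8 frames, 2 mm pixels, 60 mL EDV) where
many pipeline executions are needed (tuning, determinism); the reduced
size was chosen as the smallest geometry on which every pipeline stage is
still exercised, including a non-trivial ES.

## Known limitations

- The epicardial boundary between myocardium and low-contrast surround is
  the least constrained part of the model; LVM carries the largest
  relative error of the clinical parameters.
- Outflow-arc edges blur by one to two sectors (the endocardial bulge
  through the missing wall spreads under curvature smoothing before
  detection), so flagged arcs are slightly wider than the true arc.
- Step 8 recovers papillary *volume*, not papillary shape; the expansion
  is radial per sector.
- Detection of the long-axis displacement assumes the removal is
  contiguous from the base, which holds anatomically but is not enforced
  against pathological inputs.
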