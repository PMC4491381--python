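"""Fit the intensity mixture and inspect the balloon-force images.

The endocardial balloon is positive in blood (expand to include) and
negative in myocardium (contract to exclude); zero marks the equal-
probability boundary the contour settles on.
"""

import numpy as np

from cinelv import (
    PhantomSpec,
    endo_balloon,
    epi_balloon,
    fit_mixture,
    generate,
    init_blood_stats,
    locate_lv_center,
)

stack, truth = generate(PhantomSpec(name="baseline", seed=11))
center = locate_lv_center(stack)
print(f"LV center estimate (x, y) px: ({center[0]:.1f}, {center[1]:.1f})"
      f"   truth: {truth.lv_center_px}")

blood_mean, blood_sd = init_blood_stats(stack, center)
print(f"blood cylinder: mean {blood_mean:.1f}, sd {blood_sd:.1f}")

mix = fit_mixture(stack, (blood_mean, blood_sd), lv_center=center)
for c in mix.components:
    print(f"  {c.label:11s} mean {c.mean:6.1f}  sd {c.sd:5.1f}  w {c.weight:.2f}")

endo = endo_balloon(stack, mix)
epi = epi_balloon(stack, mix)
print(f"endo balloon range [{endo.values.min():+.2f}, {endo.values.max():+.2f}]")
print(f"epi  balloon range [{epi.values.min():+.2f}, {epi.values.max():+.2f}]")
mid = stack.n_slices // 2
inside = truth.cavity_masks[mid, 0]
print(f"mean endo balloon inside the true cavity: "
      f"{endo.values[mid, 0][inside].mean():+.2f} (should be near +1)")
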