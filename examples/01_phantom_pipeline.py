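"""Generate a noise-free neck phantom and run the full quantification
pipeline on it with the rule-based reference segmenter.

The pipeline order is: segmentation -> largest almost-connected component
-> SUV leakage removal -> VOI statistics.
"""

from dataclasses import replace

import numpy as np

from carotiq import PhantomSpec, dice, generate_phantom, run_case

spec = replace(PhantomSpec(), noise_sd_suv=0.0, ct_noise_sd_hu=0.0)
case = generate_phantom(spec)
result = run_case(case.ct, case.pet, "reference")

length = spec.grid.shape[0] * spec.grid.spacing_mm[0]
analytic_ml = np.pi * spec.carotid_radius_mm ** 2 * length / 1000
print(f"analytic tube volume: {analytic_ml:.2f} ml")
truth = {"carotid_left": case.truth_left, "carotid_right": case.truth_right}
for side, stats in result.stats.items():
    d = dice(result.masks[side], truth[side]).value
    print(f"{side}: Vol {stats.vol_ml:.2f} ml, SUVmean {stats.suv_mean:.3f}, "
          f"SUVmax {stats.suv_max:.3f}, SUVtotal {stats.suv_total:.2f}, "
          f"Dice vs truth {d:.3f}")

# Vol should sit within a few percent of the analytic cylinder volume and
# SUVmean near the phantom's carotid tissue SUV draw (around 1.0 g/ml);
# Dice close to 1 shows the segmenter recovered the ground-truth tubes.
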