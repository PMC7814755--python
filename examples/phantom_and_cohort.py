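"""Synthetic phantom and study cohort.

Builds the default four-bundle phantom (curved AP-like bundle, crossing
DP-like bundle, CS- and PN-like bundles, negative-control ROI pair),
synthesizes noisy multi-shell DWI, and draws a 100-subject cohort whose age,
sex and pain marginals match the study descriptors (age 29 +- 3.7, 64%
female, mean pain 1.63 on the 0-10 scale).
"""

import numpy as np

from paintract import build_phantom, generate_cohort, synthesize_dwi
from paintract.gradients import make_scheme
from paintract.phantom import DEFAULT_COUPLING_BETA

phantom = build_phantom()
print("bundles:", ", ".join(phantom.bundles))
print("tube voxels:", int(phantom.tube_mask.sum()),
      "| tracking-mask voxels:", int(phantom.wm_mask.sum()))

scheme = make_scheme()
dwi = synthesize_dwi(phantom, scheme, snr=50, seed=0)
print("DWI volume:", dwi.shape, "(x, y, z, diffusion volumes) at SNR 50")

coupling = {"AP": DEFAULT_COUPLING_BETA, "DP": DEFAULT_COUPLING_BETA,
            "CS": DEFAULT_COUPLING_BETA, "PN": 0.0}
cohort = generate_cohort(100, coupling=coupling, seed=0)
age = np.array([r.age for r in cohort])
pain = np.array([r.pain for r in cohort])
print(f"cohort: n=100, {sum(r.sex == 'F' for r in cohort)} F, "
      f"age {age.mean():.1f} +- {age.std():.1f}, pain {pain.mean():.2f} +- {pain.std():.2f}")
print("-> AP/DP/CS carry a pain->v_intra coupling (population Spearman ~0.3);")
print("   PN is an uncoupled control: its v_intra varies independently of pain.")
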