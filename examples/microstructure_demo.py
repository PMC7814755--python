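"""Posterior-mean estimation of compartment fractions.

Trains the polynomial posterior-mean estimator on simulated spherical-mean
signals, then recovers the intra-axonal fraction inside the phantom bundle
(truth 0.60) and the free-water fraction in the background (truth 1.0).
"""

import numpy as np

from paintract import build_phantom, estimate_map, synthesize_dwi, train_estimator
from paintract.gradients import make_scheme
from paintract.phantom import single_bundle_config

scheme = make_scheme()
estimator = train_estimator(scheme, n_samples=50_000, seed=0)
print(f"estimator trained on {estimator.n_samples} prior draws "
      f"(SNR range {estimator.snr_range})")

phantom = build_phantom(single_bundle_config())
dwi = synthesize_dwi(phantom, scheme, snr=50, seed=1)
maps = estimate_map(dwi, scheme, estimator)

tube = phantom.tube_mask
print(f"tube voxels:       v_intra = {np.nanmean(maps['v_intra'][tube]):.3f} "
      f"(ground truth 0.60)")
print(f"background voxels: v_csf   = {np.nanmean(maps['v_csf'][~tube]):.3f} "
      f"(ground truth 1.00)")
print("-> the estimator reads rotation-invariant powder averages, so it needs")
print("   no knowledge of the local fiber direction.")
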