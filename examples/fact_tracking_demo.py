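"""Deterministic FACT-style tracking on a directional tensor field.

Seeds are placed in high-density voxels (trace > 1e-1) and follow the
per-voxel principal eigenvector with a very loose stopping criterion
(trace > 1e-8). On a field whose directions are tangents of a 20 mm circle,
the tracked streamlines recover that radius.
"""

import numpy as np

from paintract import TrackingConfig, fact_track
from paintract.density import ImageGrid, TensorField

grid = ImageGrid.isotropic()
shape = grid.shape
c = (np.array(shape) - 1) * 1.5 / 2.0
idx = np.indices(shape).reshape(3, -1).T * 1.5
r = idx[:, :2] - c[:2]
rn = np.linalg.norm(r, axis=1)
tang = np.zeros((len(idx), 3))
ok = rn > 1e-9
tang[ok, 0] = -r[ok, 1] / rn[ok]
tang[ok, 1] = r[ok, 0] / rn[ok]
w = ((np.abs(rn - 20.0) <= 2.0) & (np.abs(idx[:, 2] - c[2]) <= 2.0)).astype(float)
tensors = (2.0 * w[:, None, None] * np.einsum("ni,nj->nij", tang, tang))
field = TensorField(grid=grid, tensors=tensors.reshape(shape + (3, 3)))

t = fact_track(field, TrackingConfig(n_seeds=200, max_steps=400), seed=0)
radii = []
for s in t.streamlines:
    if len(s) < 30:
        continue
    x, y = s[:, 0], s[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    sol, *_ = np.linalg.lstsq(A, x**2 + y**2, rcond=None)
    radii.append(np.sqrt(sol[2] + sol[0]**2 + sol[1]**2))

print(f"{len(t)} streamlines tracked; {len(radii)} long enough for a circle fit")
print(f"median fitted radius: {np.median(radii):.1f} mm (field built at 20 mm)")
print("-> FACT follows the local principal direction; curvature of the field")
print("   is reproduced by the tracked polylines.")
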