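"""Fiber-density mapping: scalar and rank-1 directional maps, indicator
thresholds, group probability aggregation, tensor-aware warping, tract masks
and the tract retention rule.

Densities are streamline length per voxel (mm): every streamline is discretized
at sub-voxel arc-length steps and each step deposits its exact length via
trilinear weights, so the total deposited mass equals the total streamline
length. The directional map deposits the rank-1 outer product of the unit
tangent instead, which makes its trace identical to the scalar density.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bundles import Tractogram

#: fraction of the voxel size used as the arc-length discretization step
STEP_FRACTION = 0.25
#: density cut-off (mm of streamline per voxel) for the indicator images
DENSITY_CUTOFF_MM = 1.0
#: minimal group occurrence probability for a tract to be retained
RETENTION_THRESHOLD = 0.40


@dataclass(frozen=True)
class ImageGrid:
    """Voxel grid: dims + voxel-to-world affine (axis-aligned, mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @classmethod
    def isotropic(cls, shape=(40, 40, 40), voxel_size: float = 1.5, origin=(0.0, 0.0, 0.0)):
        aff = np.diag([voxel_size] * 3 + [1.0])
        aff[:3, 3] = origin
        return cls(shape=shape, affine=aff)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        pts = np.atleast_2d(points)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, vox: np.ndarray) -> np.ndarray:
        vox = np.atleast_2d(vox)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def __eq__(self, other):
        return (isinstance(other, ImageGrid) and self.shape == other.shape
                and np.allclose(self.affine, other.affine))


@dataclass
class DensityMap:
    grid: ImageGrid
    values: np.ndarray  # mm of streamline per voxel, >= 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("densities must be finite and non-negative")
        self.values = v


@dataclass
class TensorField:
    grid: ImageGrid
    tensors: np.ndarray  # (nx, ny, nz, 3, 3) symmetric PSD

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=float)
        if t.shape != self.grid.shape + (3, 3):
            raise ValueError("tensor array shape does not match grid")
        self.tensors = t

    def trace(self) -> np.ndarray:
        return np.trace(self.tensors, axis1=-2, axis2=-1)


@dataclass
class ProbabilityMap:
    grid: ImageGrid
    values: np.ndarray  # fraction of subjects with occurrence, in [0, 1]
    n_subjects: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.values = v


@dataclass
class TractMask:
    grid: ImageGrid
    values: np.ndarray  # binary
    lower_limit: float
    upper_limit: float


@dataclass
class Warp:
    """Dense template-to-subject displacement (mm) on the template grid."""

    grid: ImageGrid
    displacement: np.ndarray  # (nx, ny, nz, 3) mm

    @classmethod
    def identity(cls, grid: ImageGrid) -> "Warp":
        return cls(grid=grid, displacement=np.zeros(grid.shape + (3,)))

    @classmethod
    def from_linear(cls, grid: ImageGrid, matrix: np.ndarray, offset=(0.0, 0.0, 0.0)) -> "Warp":
        """Displacement field of the affine map x -> M x + offset."""
        idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
        x = grid.voxel_to_world(idx)
        disp = (x @ np.asarray(matrix, dtype=float).T + np.asarray(offset, dtype=float)) - x
        return cls(grid=grid, displacement=disp.reshape(grid.shape + (3,)))

    def jacobian(self) -> np.ndarray:
        """Per-voxel Jacobian of x + disp(x), central differences, (..., 3, 3)."""
        vs = self.grid.voxel_sizes
        J = np.zeros(self.grid.shape + (3, 3))
        for c in range(3):
            grads = np.gradient(self.displacement[..., c], *vs)
            for a in range(3):
                J[..., c, a] = grads[a]
        J += np.eye(3)
        return J


def _deposit_steps(t: Tractogram, grid: ImageGrid):
    """Discretize all streamlines into (midpoints, lengths, tangents) arrays."""
    step = STEP_FRACTION * float(grid.voxel_sizes.min())
    mids, lens, tangs = [], [], []
    for s in t.streamlines:
        seg = np.diff(s, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        for p0, d, L in zip(s[:-1], seg, seg_len):
            if L <= 0:
                continue
            n = max(int(np.ceil(L / step)), 1)
            frac = (np.arange(n) + 0.5) / n
            mids.append(p0 + frac[:, None] * d)
            lens.append(np.full(n, L / n))
            tangs.append(np.tile(d / L, (n, 1)))
    if not mids:
        z = np.zeros((0, 3))
        return z, np.zeros(0), z
    return np.vstack(mids), np.concatenate(lens), np.vstack(tangs)


def _trilinear_scatter(grid: ImageGrid, points: np.ndarray, weights: np.ndarray,
                       out: np.ndarray):
    """Scatter-add weights (scalar or per-point vectors) with trilinear kernels.

    ``out`` has shape grid.shape (+ trailing weight dims). Contributions whose
    corner falls outside the grid are dropped with a warning.
    """
    vox = grid.world_to_voxel(points)
    base = np.floor(vox).astype(int)
    frac = vox - base
    dropped = 0
    shape = np.array(grid.shape)
    for corner in itertools.product((0, 1), repeat=3):
        c = np.array(corner)
        idx = base + c
        w = np.prod(np.where(c == 1, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        dropped += int(np.sum(~ok & (w > 0)))
        if not np.any(ok):
            continue
        if weights.ndim == 1:
            contrib = w[ok] * weights[ok]
        else:
            contrib = w[ok][:, None] * weights[ok]
        np.add.at(out, tuple(idx[ok].T), contrib)
    if dropped:
        warnings.warn(f"clipped {dropped} trilinear contributions outside the grid")


def density_map(t: Tractogram, grid: ImageGrid | None = None) -> DensityMap:
    """Scalar fiber-density map: streamline length (mm) per voxel.

    Default grid is 1.5 mm isotropic. Mass is conserved: the sum over voxels
    equals the total streamline arc length (up to clipped out-of-grid parts).
    """
    grid = grid or ImageGrid.isotropic()
    mids, lens, _ = _deposit_steps(t, grid)
    out = np.zeros(grid.shape)
    if len(mids):
        _trilinear_scatter(grid, mids, lens, out)
    return DensityMap(grid=grid, values=out)


def directional_density(t: Tractogram, grid: ImageGrid | None = None) -> TensorField:
    """Rank-1 directional density: per-voxel sum of length-weighted tangent
    outer products. trace(result) equals the scalar density map."""
    grid = grid or ImageGrid.isotropic()
    mids, lens, tangs = _deposit_steps(t, grid)
    out = np.zeros(grid.shape + (9,))
    if len(mids):
        outer = (tangs[:, :, None] * tangs[:, None, :]).reshape(-1, 9)
        _trilinear_scatter(grid, mids, lens[:, None] * outer, out)
    return TensorField(grid=grid, tensors=out.reshape(grid.shape + (3, 3)))


def indicator(d: DensityMap, cutoff: float = DENSITY_CUTOFF_MM) -> np.ndarray:
    """Binary streamline-indicator image: density >= cutoff (closed threshold)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if cutoff == 0:
        return (d.values > 0).astype(np.uint8)
    return (d.values >= cutoff).astype(np.uint8)


def group_probability(indicators: list[np.ndarray],
                      grid: ImageGrid | None = None) -> ProbabilityMap:
    """Voxel-wise fraction of subjects whose indicator image is set."""
    if not indicators:
        raise ValueError("need at least one indicator image")
    shape = indicators[0].shape
    if any(i.shape != shape for i in indicators):
        raise ValueError("indicator grids differ")
    grid = grid or ImageGrid.isotropic(shape=shape)
    if grid.shape != shape:
        raise ValueError("indicator shape does not match grid")
    stack = np.stack([np.asarray(i, dtype=float) for i in indicators])
    return ProbabilityMap(grid=grid, values=stack.mean(axis=0), n_subjects=len(indicators))


def warp_tensor_field(f: TensorField, w: Warp, mode: str = "rotation") -> TensorField:
    """Map a tensor field through a spatial normalization warp.

    For each template voxel, the field is resampled (trilinearly per component)
    at the warped subject coordinate, and the tensor is reoriented with the
    local Jacobian of the warp: R T R^T with R the rotation factor of the
    Jacobian's polar decomposition (``mode="rotation"``, preserves eigenvalue
    ratios) or J T J^T (``mode="full"``). An all-zero displacement returns the
    field unchanged bit-exactly. Voxels with a singular Jacobian are zeroed
    with a warning.
    """
    if mode not in ("rotation", "full"):
        raise ValueError("mode must be 'rotation' or 'full'")
    if not np.any(w.displacement):
        return TensorField(grid=f.grid, tensors=f.tensors.copy())

    grid = w.grid
    idx = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    x = grid.voxel_to_world(idx)
    y = x + w.displacement.reshape(-1, 3)

    sampled = _trilinear_gather_tensors(f, y).reshape(grid.shape + (3, 3))

    J = w.jacobian()
    detJ = np.linalg.det(J)
    singular = np.abs(detJ) < 1e-12
    if np.any(singular):
        warnings.warn(f"{int(singular.sum())} voxels with singular Jacobian skipped")
        J = np.where(singular[..., None, None], np.eye(3), J)

    if mode == "rotation":
        U, _, Vt = np.linalg.svd(J)
        R = U @ Vt
        # keep proper rotations (polar factor of an orientation-preserving map)
        neg = np.linalg.det(R) < 0
        if np.any(neg):
            U = U.copy()
            U[neg, ..., -1] *= -1
            R = U @ Vt
        A = R
    else:
        A = J
    out = A @ sampled @ np.swapaxes(A, -1, -2)
    out[singular] = 0.0
    return TensorField(grid=grid, tensors=out)


def _trilinear_gather_tensors(f: TensorField, points: np.ndarray) -> np.ndarray:
    """Sample the tensor field (per component) at world-mm points; zero outside."""
    vox = f.grid.world_to_voxel(points)
    base = np.floor(vox).astype(int)
    frac = vox - base
    shape = np.array(f.grid.shape)
    flat = f.tensors.reshape(-1, 9)
    out = np.zeros((len(points), 9))
    for corner in itertools.product((0, 1), repeat=3):
        c = np.array(corner)
        idx = base + c
        wgt = np.prod(np.where(c == 1, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        if not np.any(ok):
            continue
        lin = np.ravel_multi_index(tuple(idx[ok].T), f.grid.shape)
        out[ok] += wgt[ok, None] * flat[lin]
    return out.reshape(len(points), 3, 3)


def tract_mask(p: ProbabilityMap, lower_limit: float) -> TractMask:
    """Binary tract-core mask: occurrence probability >= lower_limit.

    The recorded upper limit is the maximal observed occurrence probability.
    """
    if not (0.0 <= lower_limit <= 1.0):
        raise ValueError("lower_limit must lie in [0, 1]")
    mask = (p.values >= lower_limit).astype(np.uint8)
    if not mask.any():
        warnings.warn("empty tract mask at this lower limit")
    return TractMask(grid=p.grid, values=mask, lower_limit=lower_limit,
                     upper_limit=float(p.values.max()))


def retention_filter(p: ProbabilityMap, threshold: float = RETENTION_THRESHOLD) -> bool:
    """Keep a tract only if some voxel reaches the occurrence threshold.

    Weak or highly variable tracts never accumulate a high group occurrence
    probability anywhere; they are dropped when max(p) < threshold.
    """
    return bool(p.values.max() >= threshold)
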