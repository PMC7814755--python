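"""Deterministic FACT-style bundle-specific tractography on a tensor field.

Seeds are placed uniformly at random inside voxels whose density trace exceeds
a seeding threshold; streamlines then follow the per-voxel principal
eigenvector bidirectionally (sign-aligned with the previous step, directions
being sign-free) until the trace drops below a very loose stopping threshold,
the turning angle exceeds the limit, or the path leaves the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bundles import Tractogram
from .density import TensorField


@dataclass(frozen=True)
class TrackingConfig:
    seed_threshold: float = 1e-1   # trace above which voxels may seed
    stop_threshold: float = 1e-8   # trace below which tracking stops
    step_mm: float = 0.75
    max_angle_deg: float = 60.0
    n_seeds: int = 2000
    max_steps: int = 1000
    interp: str = "nearest"  # nearest (FACT) | trilinear direction lookup

    def __post_init__(self):
        if self.stop_threshold >= self.seed_threshold:
            raise ValueError("stop_threshold must be below seed_threshold")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")


def _principal_dirs(f: TensorField, stop_threshold: float):
    tr = f.trace()
    valid = tr > stop_threshold
    dirs = np.zeros(f.grid.shape + (3,))
    if np.any(valid):
        w, v = np.linalg.eigh(f.tensors[valid])
        dirs[valid] = v[..., -1]  # eigenvector of the largest eigenvalue
    return tr, valid, dirs


def fact_track(f: TensorField, cfg: TrackingConfig | None = None,
               seed: int = 0) -> Tractogram:
    """Track streamlines through the directional density field.

    Returns world-mm polylines; paths shorter than 3 points are discarded.
    Deterministic given (field, config, seed).
    """
    cfg = cfg or TrackingConfig()
    grid = f.grid
    tr, valid, dirs = _principal_dirs(f, cfg.stop_threshold)

    seed_vox = np.argwhere(tr > cfg.seed_threshold)
    if len(seed_vox) == 0:
        warnings.warn("no voxel above the seeding threshold; empty tractogram")
        return Tractogram([], affine=grid.affine)

    rng = np.random.default_rng(seed)
    picks = seed_vox[rng.integers(0, len(seed_vox), size=cfg.n_seeds)]
    offsets = rng.uniform(-0.5, 0.5, size=(cfg.n_seeds, 3))
    seeds_world = grid.voxel_to_world(picks + offsets)

    cos_limit = np.cos(np.deg2rad(cfg.max_angle_deg))
    inv = np.linalg.inv(grid.affine)
    shape = np.array(grid.shape)

    def local_dir(p):
        """Direction at world point p, or None outside / below stop threshold."""
        v = p @ inv[:3, :3].T + inv[:3, 3]
        if cfg.interp == "nearest":
            ijk = np.rint(v).astype(int)
            if np.any(ijk < 0) or np.any(ijk >= shape):
                return None
            i, j, k = ijk
            if not valid[i, j, k]:
                return None
            return dirs[i, j, k]
        base = np.floor(v).astype(int)
        if np.any(base < 0) or np.any(base + 1 >= shape):
            return None
        frac = v - base
        acc = np.zeros(3)
        tot = 0.0
        ref = None
        for cx in (0, 1):
            for cy in (0, 1):
                for cz in (0, 1):
                    w = ((frac[0] if cx else 1 - frac[0])
                         * (frac[1] if cy else 1 - frac[1])
                         * (frac[2] if cz else 1 - frac[2]))
                    d = dirs[base[0] + cx, base[1] + cy, base[2] + cz]
                    if not np.any(d):
                        continue
                    if ref is None:
                        ref = d
                    if np.dot(d, ref) < 0:
                        d = -d
                    acc += w * d
                    tot += w
        if tot <= 0:
            return None
        n = np.linalg.norm(acc)
        return acc / n if n > 0 else None

    def march(p0, d0):
        pts = []
        p, d = p0.copy(), d0.copy()
        for _ in range(cfg.max_steps):
            p = p + cfg.step_mm * d
            nd = local_dir(p)
            if nd is None:
                break
            if np.dot(nd, d) < 0:
                nd = -nd
            if np.dot(nd, d) < cos_limit:
                break
            pts.append(p.copy())
            d = nd
        return pts

    streamlines = []
    for p0 in seeds_world:
        d0 = local_dir(p0)
        if d0 is None:
            continue
        fwd = march(p0, d0)
        bwd = march(p0, -d0)
        line = bwd[::-1] + [p0] + fwd
        if len(line) >= 3:
            streamlines.append(np.array(line))
    return Tractogram(streamlines, affine=grid.affine)
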