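"""Multi-shell acquisition schemes and the stick-zeppelin-ball forward model.

b-values are stored internally in ms/um^2 (so diffusivities are um^2/ms and
b*d is dimensionless); text I/O accepts the conventional s/mm^2 and converts
(1000 s/mm^2 == 1.0 ms/um^2).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

#: b-values at or below this (s/mm^2) count as unweighted volumes.
B0_THRESHOLD_S_MM2 = 50.0
#: b-values within this distance (s/mm^2) belong to the same shell.
SHELL_TOLERANCE_S_MM2 = 50.0
#: Free-water diffusivity convention, um^2/ms.
D_CSF_DEFAULT = 3.0


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion acquisition geometry: per-volume b-value, direction, shell.

    Attributes
    ----------
    bvalues : (n,) float array, ms/um^2
    directions : (n, 3) float array, unit vectors (zero vector allowed on b0)
    shell_ids : (n,) int array; shell 0 is the b0 shell
    """

    bvalues: np.ndarray
    directions: np.ndarray
    shell_ids: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bvalues, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        s = np.asarray(self.shell_ids, dtype=int)
        if b.ndim != 1 or g.shape != (b.size, 3) or s.shape != b.shape:
            raise ValueError("inconsistent scheme array shapes")
        if np.any(b < 0):
            raise ValueError("negative b-value")
        nonb0 = s != 0
        norms = np.linalg.norm(g[nonb0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-unit gradient direction on a weighted volume")
        if not np.any(~nonb0):
            raise ValueError("scheme must contain at least one b0 volume")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)
        object.__setattr__(self, "shell_ids", s)

    @property
    def n_volumes(self) -> int:
        return self.bvalues.size

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.shell_ids == 0))

    @property
    def shells(self) -> np.ndarray:
        """Sorted unique shell ids (0 first if present)."""
        return np.unique(self.shell_ids)

    @property
    def shell_bvalues(self) -> np.ndarray:
        """Mean b-value per shell, ordered as ``shells``."""
        return np.array([self.bvalues[self.shell_ids == s].mean() for s in self.shells])

    def volumes_in_shell(self, shell_id: int) -> np.ndarray:
        return np.flatnonzero(self.shell_ids == shell_id)

    def to_tsv(self) -> str:
        lines = ["volume\tb\tgx\tgy\tgz\tshell"]
        for i in range(self.n_volumes):
            gx, gy, gz = self.directions[i]
            lines.append(f"{i}\t{self.bvalues[i]:.6g}\t{gx:.8f}\t{gy:.8f}\t{gz:.8f}\t{self.shell_ids[i]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class CompartmentParams:
    """Three-compartment voxel parameters (stick + zeppelin + ball).

    Fractions are signal fractions on the simplex; diffusivities in um^2/ms.
    """

    v_intra: float
    v_extra: float
    v_csf: float
    d_a: float = 2.0
    d_e_par: float = 2.0
    d_e_perp: float = 0.7
    d_csf: float = D_CSF_DEFAULT
    s0: float = 1.0

    def __post_init__(self):
        if abs(self.v_intra + self.v_extra + self.v_csf - 1.0) > 1e-9:
            raise ValueError("compartment fractions must sum to 1")
        for v in (self.v_intra, self.v_extra, self.v_csf):
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError("fraction outside [0, 1]")
        if self.d_e_perp > self.d_e_par + 1e-12:
            raise ValueError("d_e_perp must not exceed d_e_par")
        for d in (self.d_a, self.d_e_par, self.d_e_perp, self.d_csf):
            if not (0 < d <= 4.0):
                raise ValueError("diffusivity outside (0, 4] um^2/ms")


def _cluster_shells(b_s_mm2: np.ndarray) -> np.ndarray:
    """Greedy 1-D clustering of b-values into shells (tolerance +-50 s/mm^2).

    Returns integer shell ids; shell 0 collects b <= 50 s/mm^2.
    """
    shell_ids = np.zeros(b_s_mm2.size, dtype=int)
    weighted = b_s_mm2 > B0_THRESHOLD_S_MM2
    if not np.any(weighted):
        return shell_ids
    order = np.argsort(b_s_mm2[weighted])
    vals = b_s_mm2[weighted][order]
    labels = np.zeros(vals.size, dtype=int)
    current = 1
    labels[0] = current
    for i in range(1, vals.size):
        if vals[i] - vals[i - 1] > SHELL_TOLERANCE_S_MM2:
            current += 1
        labels[i] = current
    out = np.zeros(vals.size, dtype=int)
    out[order] = labels
    shell_ids[weighted] = out
    return shell_ids


def load_scheme(bval_text: str, bvec_text: str) -> GradientScheme:
    """Parse FSL-dialect bval/bvec text into a :class:`GradientScheme`.

    ``bval_text`` is one row of whitespace-separated b-values in s/mm^2;
    ``bvec_text`` is three rows of direction components. Non-unit weighted
    directions are normalized with a warning.
    """
    try:
        bvals = np.loadtxt(io.StringIO(bval_text), ndmin=1, dtype=float)
        bvecs = np.loadtxt(io.StringIO(bvec_text), ndmin=2, dtype=float)
    except ValueError as e:
        raise ValueError(f"unparseable bval/bvec text: {e}") from e
    if bvals.ndim != 1:
        bvals = bvals.ravel()
    if bvecs.shape[0] != 3:
        raise ValueError(f"bvec text must have 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise ValueError(f"bval count {bvals.size} != bvec count {bvecs.shape[1]}")
    g = bvecs.T.copy()
    shell_ids = _cluster_shells(bvals)
    norms = np.linalg.norm(g, axis=1)
    weighted = shell_ids != 0
    bad = weighted & (np.abs(norms - 1.0) > 1e-6)
    if np.any(bad):
        warnings.warn(f"normalizing {int(bad.sum())} non-unit gradient direction(s)")
        g[bad] /= norms[bad, None]
    return GradientScheme(bvalues=bvals / 1000.0, directions=g, shell_ids=shell_ids)


def repulsion_directions(n: int, seed: int = 0, n_iter: int = 2000) -> np.ndarray:
    """Antipodally-symmetric electrostatic-repulsion direction set on the sphere.

    Minimizes the Coulomb energy of n point pairs {x, -x} by projected gradient
    descent from a seeded random start; deterministic given (n, seed).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    for it in range(n_iter):
        step = 0.05 * (1.0 - 0.9 * it / n_iter)
        d_same = x[:, None, :] - x[None, :, :]
        d_anti = x[:, None, :] + x[None, :, :]
        r_same = np.linalg.norm(d_same, axis=-1)
        r_anti = np.linalg.norm(d_anti, axis=-1)
        np.fill_diagonal(r_same, np.inf)
        np.fill_diagonal(r_anti, np.inf)
        force = (d_same / r_same[..., None] ** 3).sum(axis=1) + (d_anti / r_anti[..., None] ** 3).sum(axis=1)
        # project tangentially and take a normalized step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        fmax = np.linalg.norm(force, axis=1).max()
        if fmax > 0:
            x = x + step * force / fmax
            x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def make_scheme(shell_bvalues=(1.0, 2.0, 3.0), n_dirs: int = 30, n_b0: int = 1,
                seed: int = 0) -> GradientScheme:
    """Build a synthetic multi-shell scheme with repulsion-optimized directions.

    ``shell_bvalues`` are in ms/um^2 (default matches a b = 1000/2000/3000
    s/mm^2 three-shell acquisition).
    """
    bvals = [0.0] * n_b0
    dirs = [np.zeros(3)] * n_b0
    shells = [0] * n_b0
    for k, b in enumerate(shell_bvalues, start=1):
        g = repulsion_directions(n_dirs, seed=seed + k)
        bvals.extend([float(b)] * n_dirs)
        dirs.extend(list(g))
        shells.extend([k] * n_dirs)
    return GradientScheme(bvalues=np.array(bvals), directions=np.array(dirs),
                          shell_ids=np.array(shells))


def model_signal(p: CompartmentParams, scheme: GradientScheme, fiber_dir: np.ndarray) -> np.ndarray:
    """Per-volume signal attenuation A(b, g) of the three-compartment model.

    A = v_intra exp(-b d_a (g.n)^2)
      + v_extra exp(-b (d_e_perp + (d_e_par - d_e_perp)(g.n)^2))
      + v_csf   exp(-b d_csf)

    The stick has zero radial diffusivity; the ball is isotropic. Returns
    attenuation (signal / s0), exactly 1 at b = 0.
    """
    n = np.asarray(fiber_dir, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("fiber_dir must be a unit vector")
    b = scheme.bvalues
    c2 = (scheme.directions @ n) ** 2
    a_stick = np.exp(-b * p.d_a * c2)
    a_zep = np.exp(-b * (p.d_e_perp + (p.d_e_par - p.d_e_perp) * c2))
    a_ball = np.exp(-b * p.d_csf)
    return p.v_intra * a_stick + p.v_extra * a_zep + p.v_csf * a_ball


def stick_spherical_mean(b: float, d_a: float) -> float:
    """Closed-form powder average of the stick kernel: sqrt(pi/(4 b d)) erf(sqrt(b d))."""
    from scipy.special import erf
    bd = b * d_a
    if bd <= 0:
        return 1.0
    return float(np.sqrt(np.pi / (4.0 * bd)) * erf(np.sqrt(bd)))


def zeppelin_spherical_mean(b: float, d_par: float, d_perp: float) -> float:
    """Closed-form powder average of an axially symmetric tensor kernel."""
    return float(np.exp(-b * d_perp) * stick_spherical_mean(b, d_par - d_perp))


def spherical_mean(signal: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """Per-shell mean of the signal over directions (powder average).

    Returns one value per shell, ordered as ``scheme.shells``. The powder
    average of any fiber-orientation-dependent signal is rotation invariant up
    to direction-sampling error. Works on a trailing volume axis, so stacked
    voxel signals of shape (..., n_volumes) average to (..., n_shells).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] != scheme.n_volumes:
        raise ValueError("signal length does not match scheme volume count")
    out = []
    for s in scheme.shells:
        idx = scheme.volumes_in_shell(int(s))
        if idx.size == 0:
            raise ValueError(f"empty shell {s}")
        if s != 0 and idx.size < 6:
            warnings.warn(f"shell {s} has only {idx.size} directions; powder average is unreliable")
        out.append(signal[..., idx].mean(axis=-1))
    return np.stack(out, axis=-1)
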