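"""Supervised posterior-mean estimation of three-compartment fractions.

Training simulates signals from the stick-zeppelin-ball forward model under a
broad parameter prior, reduces them to rotation-invariant per-shell spherical
means (powder averages), and fits a polynomial regression from features to
parameters. Least-squares regression onto a sampled prior approximates the
Bayesian posterior mean under squared loss, which keeps the unconstrained
compartment model while the regression absorbs the noise model; prediction is
a closed-form polynomial evaluation, so whole-volume maps take seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gradients import CompartmentParams, GradientScheme, D_CSF_DEFAULT

FRACTION_NAMES = ("v_intra", "v_extra", "v_csf")


@dataclass(frozen=True)
class Prior:
    """Sampling prior for training: uniform simplex fractions, uniform diffusivities.

    Diffusivities in um^2/ms; ``d_e_perp`` is constrained below ``d_e_par``.
    ``snr_range`` is the b0 signal-to-noise interval for training noise.
    """

    d_a_range: tuple[float, float] = (1.5, 2.5)
    d_e_par_range: tuple[float, float] = (1.0, 2.5)
    d_e_perp_range: tuple[float, float] = (0.3, 1.5)
    d_csf: float = D_CSF_DEFAULT
    snr_range: tuple[float, float] = (20.0, 200.0)

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        fr = rng.dirichlet(np.ones(3), size=n)
        d_a = rng.uniform(*self.d_a_range, size=n)
        d_e_par = rng.uniform(*self.d_e_par_range, size=n)
        hi = np.minimum(self.d_e_perp_range[1], d_e_par)
        d_e_perp = rng.uniform(self.d_e_perp_range[0], hi)
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        snr = rng.uniform(*self.snr_range, size=n)
        return {"v_intra": fr[:, 0], "v_extra": fr[:, 1], "v_csf": fr[:, 2],
                "d_a": d_a, "d_e_par": d_e_par, "d_e_perp": d_e_perp,
                "dirs": dirs, "snr": snr}


def batch_signal(params: dict[str, np.ndarray], scheme: GradientScheme) -> np.ndarray:
    """Noise-free attenuation for a batch of parameter draws, shape (n, n_volumes)."""
    b = scheme.bvalues
    g = scheme.directions
    c2 = (params["dirs"] @ g.T) ** 2
    d_csf = params.get("d_csf", np.full(len(c2), D_CSF_DEFAULT))
    if np.isscalar(d_csf) or np.ndim(d_csf) == 0:
        d_csf = np.full(len(c2), float(d_csf))
    a_stick = np.exp(-b * params["d_a"][:, None] * c2)
    a_zep = np.exp(-b * (params["d_e_perp"][:, None]
                         + (params["d_e_par"] - params["d_e_perp"])[:, None] * c2))
    a_ball = np.exp(-np.outer(d_csf, b))
    return (params["v_intra"][:, None] * a_stick
            + params["v_extra"][:, None] * a_zep
            + params["v_csf"][:, None] * a_ball)


def _shell_features(signal: np.ndarray, scheme: GradientScheme) -> np.ndarray:
    """b0-normalized spherical means on the weighted shells, shape (n, n_shells-1)."""
    b0_idx = scheme.volumes_in_shell(0)
    b0 = signal[..., b0_idx].mean(axis=-1)
    feats = []
    for s in scheme.shells:
        if s == 0:
            continue
        idx = scheme.volumes_in_shell(int(s))
        feats.append(signal[..., idx].mean(axis=-1) / b0)
    return np.stack(feats, axis=-1)


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    from sklearn.preprocessing import PolynomialFeatures

    return PolynomialFeatures(degree=degree, include_bias=True).fit_transform(x)


@dataclass
class Estimator:
    """Polynomial posterior-mean regressor from spherical-mean features.

    Predicted fractions are clipped to [0, 1] and renormalized to the simplex.
    """

    coef: np.ndarray          # (n_poly_terms, n_targets)
    degree: int
    target_names: tuple[str, ...]
    shell_bvalues: np.ndarray
    n_samples: int
    snr_range: tuple[float, float]
    seed: int

    def predict(self, features: np.ndarray) -> dict[str, np.ndarray]:
        X = _poly_design(np.atleast_2d(features), self.degree)
        raw = X @ self.coef
        out = {n: raw[:, i] for i, n in enumerate(self.target_names)}
        fr = np.stack([np.clip(out[n], 0.0, 1.0) for n in FRACTION_NAMES], axis=-1)
        tot = fr.sum(axis=-1)
        bad = tot <= 1e-12
        fr[bad] = 1.0 / 3.0
        fr /= np.maximum(fr.sum(axis=-1, keepdims=True), 1e-12)
        for i, n in enumerate(FRACTION_NAMES):
            out[n] = fr[:, i]
        return out


def train_estimator(scheme: GradientScheme, prior: Prior | None = None,
                    n_samples: int = 50_000, seed: int = 0,
                    degree: int = 3) -> Estimator:
    """Fit the posterior-mean polynomial on simulated noisy spherical means.

    Rician noise at a b0 SNR drawn from the prior is applied per volume before
    the powder average, so the regression learns the noise floor (including
    the Rician bias on high-b shells). Deterministic given the seed.
    """
    prior = prior or Prior()
    if len(scheme.shells) < 3:
        warnings.warn("single-shell scheme: compartment fractions are poorly determined")
    if n_samples < 10_000:
        warnings.warn("fewer than 10^4 training samples; posterior-mean fit may be rough")
    rng = np.random.default_rng(seed)
    params = prior.sample(n_samples, rng)
    sig = batch_signal(params, scheme)
    sigma = 1.0 / params["snr"][:, None]
    e1 = rng.normal(0.0, 1.0, sig.shape) * sigma
    e2 = rng.normal(0.0, 1.0, sig.shape) * sigma
    noisy = np.sqrt((sig + e1) ** 2 + e2**2)
    feats = _shell_features(noisy, scheme)

    targets = ("v_intra", "v_extra", "v_csf", "d_a")
    Y = np.stack([params[t] for t in targets], axis=-1)
    X = _poly_design(feats, degree)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Estimator(coef=coef, degree=degree, target_names=targets,
                     shell_bvalues=scheme.shell_bvalues, n_samples=n_samples,
                     snr_range=prior.snr_range, seed=seed)


def estimate_map(dwi: np.ndarray, scheme: GradientScheme, est: Estimator,
                 mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Voxel-wise compartment parameter maps from a 4-D DWI volume.

    Returns v_intra / v_extra / v_csf / d_a volumes plus a ``valid`` mask;
    voxels with non-positive b0 are flagged invalid (NaN outputs). ``mask``
    restricts computation to a subset of voxels.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("DWI volume count does not match the scheme")
    shape = dwi.shape[:-1]
    vox = dwi.reshape(-1, scheme.n_volumes)
    sel = np.ones(vox.shape[0], dtype=bool) if mask is None else np.asarray(mask, dtype=bool).ravel()

    b0 = vox[:, scheme.volumes_in_shell(0)].mean(axis=-1)
    valid = sel & (b0 > 0) & np.all(np.isfinite(vox), axis=-1)

    out = {n: np.full(vox.shape[0], np.nan) for n in (*FRACTION_NAMES, "d_a")}
    if np.any(valid):
        feats = _shell_features(vox[valid], scheme)
        pred = est.predict(feats)
        for n in out:
            out[n][valid] = pred[n]
    result = {n: v.reshape(shape) for n, v in out.items()}
    result["valid"] = valid.reshape(shape)
    return result


def mask_mean(param_volume: np.ndarray, mask) -> tuple[float, int]:
    """Mean parameter over valid (finite) mask voxels; returns (mean, n_voxels).

    Returns (nan, 0) when the mask is empty or all voxels are invalid.
    """
    m = np.asarray(getattr(mask, "values", mask)).astype(bool)
    vals = np.asarray(param_volume)[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)
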