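"""End-to-end pipeline: phantom -> DWI -> global tractography -> bundle
selection -> density / probability / masks -> FACT visualization tract ->
per-subject v_intra -> pain statistics.

The synthetic cohort shares one anatomy (registration is out of scope); each
subject carries their own tract microstructure, so the per-subject stages are
DWI synthesis at the tract-mask voxels, posterior-mean estimation, and mask
averaging. Inter-subject tract variability in the density maps is emulated by
a seeded bootstrap of each tract's streamlines per subject. A single master
seed fans out to per-stage seeds by fixed offsets; re-running the same
configuration reproduces every artifact.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as ptio
from .bundles import Tractogram, select_combinations
from .density import (ImageGrid, Warp, density_map, directional_density,
                      group_probability, indicator, retention_filter,
                      tract_mask, warp_tensor_field)
from .global_tracking import AnnealSchedule, EnergyModel, accumulate
from .gradients import CompartmentParams, make_scheme, model_signal
from .microstructure import Estimator, Prior, train_estimator, mask_mean
from .phantom import (PhantomConfig, build_phantom, generate_cohort,
                      synthesize_dwi, CohortCalibration, TUBE_V_CSF,
                      DEFAULT_COUPLING_BETA)
from .stats import StatsConfig, adjust, rank_regression, results_frame
from .tracking import TrackingConfig, fact_track

# per-stage seed offsets from the master seed
SEED_TRACKING = 1
SEED_COHORT = 2
SEED_ESTIMATOR = 3
SEED_SUBJECT_DWI = 4
SEED_BOOTSTRAP = 5
SEED_FACT = 6
SEED_PERM = 7


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults give the standard demo study."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    shell_bvalues: tuple = (1.0, 2.0, 3.0)
    n_dirs_per_shell: int = 30
    n_b0: int = 1
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    tracts: dict = field(default_factory=lambda: {
        "AP": ("A1", "A2", "A3"), "DP": ("D1", "D2"),
        "CS": ("C1", "C2"), "PN": ("P1", "P2"), "NC": ("N1", "N2"),
    })
    coupling: dict = field(default_factory=lambda: {
        "AP": DEFAULT_COUPLING_BETA, "DP": DEFAULT_COUPLING_BETA,
        "CS": DEFAULT_COUPLING_BETA, "PN": 0.0,
    })
    n_subjects: int = 100
    calibration: CohortCalibration = field(default_factory=CohortCalibration)
    subject_snr: float = 50.0
    density_cutoff_mm: float = 1.0
    bootstrap_fraction: float = 0.7
    mask_lower_limit: float | dict = 0.8  # scalar, or per-tract dict (TSV loadable)
    retention_threshold: float = 0.40
    tracking: TrackingConfig = field(default_factory=lambda: TrackingConfig(n_seeds=500))
    prior: Prior = field(default_factory=Prior)
    n_train: int = 50_000
    stats: StatsConfig = field(default_factory=lambda: StatsConfig(n_permutations=999))
    master_seed: int = 0
    out_dir: str | None = None
    write_artifacts: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a run configuration from a key=value text file.

        Recognized keys (one per line, '#' comments): master_seed, out_dir,
        n_subjects, subject_snr, n_train, density_cutoff_mm,
        bootstrap_fraction, mask_lower_limit, retention_threshold,
        n_permutations, anneal_n_iter, anneal_reheat_iter, anneal_rounds,
        tract_limits_tsv (path to a tract/lower_limit TSV). Unknown keys are
        rejected."""
        from pathlib import Path as _Path

        kv = {}
        for line in _Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        cfg = cls()
        sched = dict(n_iter=cfg.schedule.n_iter, reheat_iter=cfg.schedule.reheat_iter,
                     rounds=cfg.schedule.rounds)
        stats_kw = dict(n_permutations=cfg.stats.n_permutations)
        for key, val in kv.items():
            if key == "master_seed":
                cfg.master_seed = int(val)
            elif key == "out_dir":
                cfg.out_dir = val
            elif key == "n_subjects":
                cfg.n_subjects = int(val)
            elif key == "subject_snr":
                cfg.subject_snr = float(val)
            elif key == "n_train":
                cfg.n_train = int(val)
            elif key == "density_cutoff_mm":
                cfg.density_cutoff_mm = float(val)
            elif key == "bootstrap_fraction":
                cfg.bootstrap_fraction = float(val)
            elif key == "mask_lower_limit":
                cfg.mask_lower_limit = float(val)
            elif key == "retention_threshold":
                cfg.retention_threshold = float(val)
            elif key == "n_permutations":
                stats_kw["n_permutations"] = int(val)
            elif key == "anneal_n_iter":
                sched["n_iter"] = int(val)
            elif key == "anneal_reheat_iter":
                sched["reheat_iter"] = int(val)
            elif key == "anneal_rounds":
                sched["rounds"] = int(val)
            elif key == "tract_limits_tsv":
                from . import io as _io
                cfg.mask_lower_limit = _io.load_tract_limits(val)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        cfg.schedule = AnnealSchedule(**sched)
        cfg.stats = StatsConfig(**stats_kw)
        return cfg


def _subject_signal_at(phantom, scheme, vox_idx, bundle_vintra, snr, rng):
    """Forward signal at a voxel subset with per-bundle subject v_intra."""
    n = len(vox_idx)
    sig = np.zeros((n, scheme.n_volumes))
    csf = model_signal(CompartmentParams(0.0, 0.0, 1.0), scheme, np.array([0.0, 0.0, 1.0]))
    total_w = np.zeros(n)
    b = scheme.bvalues
    g = scheme.directions
    for name, wvol in phantom.bundle_weight.items():
        w = wvol[tuple(vox_idx.T)]
        m = w > 0
        if not m.any():
            continue
        vi = float(bundle_vintra.get(name, 0.60))
        ve = 1.0 - vi - TUBE_V_CSF
        p = CompartmentParams(vi, ve, TUBE_V_CSF)
        dirs = phantom.bundle_dirs[name][tuple(vox_idx[m].T)]
        c2 = (dirs @ g.T) ** 2
        a = (p.v_intra * np.exp(-b * p.d_a * c2)
             + p.v_extra * np.exp(-b * (p.d_e_perp + (p.d_e_par - p.d_e_perp) * c2))
             + p.v_csf * np.exp(-b * p.d_csf))
        sig[m] += phantom.s0 * w[m][:, None] * a
        total_w[m] += w[m]
    sig[total_w == 0] = phantom.s0 * csf
    if snr is not None and np.isfinite(snr):
        s = phantom.s0 / snr
        sig = np.sqrt((sig + rng.normal(0, s, sig.shape)) ** 2
                      + rng.normal(0, s, sig.shape) ** 2)
    return sig


def run_pipeline(cfg: PipelineConfig | None = None,
                 estimator: Estimator | None = None) -> dict:
    """Execute the full study on synthetic data; returns the run report.

    The report carries per-stage counts, the per-tract regression results
    (also as a DataFrame under ``results``), and the manifest of written
    artifacts. A pre-trained ``estimator`` may be supplied to reuse training
    across runs; by default one is trained from the config's prior and seed.
    """
    cfg = cfg or PipelineConfig()
    t_start = time.time()
    report = {"config_seed": cfg.master_seed, "stages": {}, "artifacts": []}
    out = Path(cfg.out_dir) if (cfg.out_dir and cfg.write_artifacts) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name, writer):
        if out:
            writer(out / name)
            report["artifacts"].append(name)

    # 1 - anatomy and acquisition
    phantom = build_phantom(cfg.phantom)
    scheme = make_scheme(cfg.shell_bvalues, cfg.n_dirs_per_shell, cfg.n_b0)
    grid = ImageGrid(shape=phantom.shape, affine=phantom.affine)
    dwi_ref = synthesize_dwi(phantom, scheme)  # noise-free reference for tracking
    report["stages"]["phantom"] = {"tube_voxels": int(phantom.tube_mask.sum()),
                                   "mask_voxels": int(phantom.wm_mask.sum())}
    emit("dwi_reference.nii.gz", lambda p: ptio.save_nifti(dwi_ref, phantom.affine, p))
    emit("wm_mask.nii.gz", lambda p: ptio.save_nifti(phantom.wm_mask.astype(np.uint8),
                                                     phantom.affine, p, dtype=np.uint8))
    if out:
        ptio.save_scheme_fsl(scheme, out / "dwi.bval", out / "dwi.bvec")
        report["artifacts"] += ["dwi.bval", "dwi.bvec"]

    # 2 - global tractography with accumulation
    tractogram = accumulate(dwi_ref, scheme, phantom.wm_mask, cfg.schedule,
                            seed=cfg.master_seed + SEED_TRACKING,
                            model=cfg.energy_model, affine=phantom.affine)
    report["stages"]["tracking"] = {"n_streamlines": len(tractogram)}
    emit("tractogram.tck", lambda p: ptio.save_tractogram(tractogram, p))

    # 3 - exhaustive ROI-combination selection
    rois = phantom.rois
    combos = select_combinations(tractogram, rois, min_size=2, max_size=4)
    report["stages"]["selection"] = {
        "n_connected_combinations": len(combos),
        "combinations": {"+".join(k): len(v) for k, v in combos.items()},
    }

    # 4 - per-tract density, group probability, retention, masks
    rng_boot = np.random.default_rng(cfg.master_seed + SEED_BOOTSTRAP)
    masks = {}
    prob_maps = {}
    dropped = []
    tract_streams = {}
    for tract, roi_names in cfg.tracts.items():
        key = tuple(n for n in [r.name for r in rois] if n in roi_names)
        idx = combos.get(key, set())
        sub = tractogram.subset(sorted(idx))
        tract_streams[tract] = sub
        if len(sub) == 0:
            dropped.append(tract)
            continue
        inds = []
        for _ in range(cfg.n_subjects):
            take = rng_boot.random(len(sub)) < cfg.bootstrap_fraction
            boot = sub.subset(np.flatnonzero(take)) if take.any() else sub.subset([0])
            inds.append(indicator(density_map(boot, grid), cfg.density_cutoff_mm))
        prob = group_probability(inds, grid)
        prob_maps[tract] = prob
        if not retention_filter(prob, cfg.retention_threshold):
            dropped.append(tract)
            continue
        lower = (cfg.mask_lower_limit.get(tract, 0.8)
                 if isinstance(cfg.mask_lower_limit, dict) else cfg.mask_lower_limit)
        masks[tract] = tract_mask(prob, lower)
        emit(f"prob_{tract}.nii.gz",
             lambda p, pr=prob: ptio.save_nifti(pr.values, phantom.affine, p))
        emit(f"mask_{tract}.nii.gz",
             lambda p, mk=masks[tract]: ptio.save_nifti(mk.values, phantom.affine, p,
                                                        dtype=np.uint8))
    report["stages"]["density"] = {
        "kept_tracts": sorted(masks), "dropped_tracts": sorted(dropped),
        "mask_voxels": {t: int(m.values.sum()) for t, m in masks.items()},
    }
    if not masks:
        raise RuntimeError("density stage: no tract survived retention/masking")

    # 5 - group directional field (identity normalization warp) + FACT tract
    pooled = Tractogram([s for t in masks for s in tract_streams[t].streamlines],
                        affine=phantom.affine)
    field_t = directional_density(pooled, grid)
    field_t = warp_tensor_field(field_t, Warp.identity(grid))  # template warp slot
    fact = fact_track(field_t, cfg.tracking, seed=cfg.master_seed + SEED_FACT)
    report["stages"]["fact"] = {"n_streamlines": len(fact)}
    emit("fact_tract.tck", lambda p: ptio.save_tractogram(fact, p))

    # 6 - cohort + estimator + per-subject v_intra in tract masks
    cohort = generate_cohort(cfg.n_subjects, cfg.calibration, cfg.coupling,
                             seed=cfg.master_seed + SEED_COHORT)
    est = estimator or train_estimator(scheme, cfg.prior, cfg.n_train,
                                       seed=SEED_ESTIMATOR)
    union = np.zeros(phantom.shape, dtype=bool)
    for m in masks.values():
        union |= m.values.astype(bool)
    vox_idx = np.argwhere(union)
    mask_rows = {t: m.values.astype(bool)[tuple(vox_idx.T)] for t, m in masks.items()}
    rng_subj = np.random.default_rng(cfg.master_seed + SEED_SUBJECT_DWI)
    from .microstructure import _shell_features  # feature path shared with estimate_map
    for rec in cohort:
        sig = _subject_signal_at(phantom, scheme, vox_idx,
                                 rec.tract_vintra_true, cfg.subject_snr, rng_subj)
        b0 = sig[:, scheme.volumes_in_shell(0)].mean(axis=1)
        ok = b0 > 0
        vi = np.full(len(vox_idx), np.nan)
        if ok.any():
            vi[ok] = est.predict(_shell_features(sig[ok], scheme))["v_intra"]
        for t, rows in mask_rows.items():
            vals = vi[rows]
            vals = vals[np.isfinite(vals)]
            rec.tract_vintra_est[t] = float(vals.mean()) if vals.size else float("nan")
    emit("cohort.tsv", lambda p: ptio.save_cohort_tsv(cohort, p))
    report["stages"]["microstructure"] = {
        "n_subjects": len(cohort), "estimator_n_train": est.n_samples,
        "mean_est_v_intra": {t: float(np.nanmean([r.tract_vintra_est[t] for r in cohort]))
                             for t in masks},
    }

    # 7 - rank regression + multiple-comparison control
    stats_cfg = StatsConfig(alpha=cfg.stats.alpha, fdr_q=cfg.stats.fdr_q,
                            n_permutations=cfg.stats.n_permutations,
                            perm_seed=cfg.master_seed + SEED_PERM)
    results = [rank_regression(cohort, t, stats_cfg) for t in sorted(masks)]
    bon, fdr, log10_thr = adjust(results, stats_cfg)
    frame = results_frame(results)
    emit("results.tsv", lambda p: frame.to_csv(p, sep="\t", index=False))
    report["stages"]["stats"] = {
        "fdr_log10_threshold": log10_thr,
        "sig_bonferroni": [r.tract for r in results if r.sig_bonferroni],
        "sig_fdr": [r.tract for r in results if r.sig_fdr],
    }
    report["results"] = frame
    report["elapsed_s"] = time.time() - t_start
    if out:
        manifest = {k: v for k, v in report.items() if k != "results"}
        ptio.save_json(manifest, out / "manifest.json")
    return report
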