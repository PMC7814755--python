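"""File I/O: TCK/TRK streamlines, NIfTI volumes, bval/bvec, cohort tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .bundles import Tractogram
from .gradients import GradientScheme, load_scheme
from .phantom import SubjectRecord


def save_tractogram(t: Tractogram, path) -> None:
    """Write streamlines as TCK (world mm, RAS) or TRK by extension."""
    path = Path(path)
    aff = t.affine if t.affine is not None else np.eye(4)
    tg = nib.streamlines.Tractogram(t.streamlines, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        hdr = nib.streamlines.trk.TrkFile.create_empty_header()
        hdr["voxel_to_rasmm"] = aff.astype(np.float32)
        hdr["voxel_sizes"] = np.linalg.norm(aff[:3, :3], axis=0).astype(np.float32)
        hdr["dimensions"] = np.array([64, 64, 64], dtype=np.uint16)
        nib.streamlines.save(tg, str(path), header=hdr)
    else:
        nib.streamlines.save(tg, str(path))


def load_tractogram(path) -> Tractogram:
    tf = nib.streamlines.load(str(path))
    return Tractogram([np.asarray(s, dtype=float) for s in tf.tractogram.streamlines])


def save_nifti(values: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=dtype), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_scheme_fsl(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """FSL dialect: one row of b-values (s/mm^2), three rows of components."""
    np.savetxt(bval_path, scheme.bvalues[None, :] * 1000.0, fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")


def load_scheme_fsl(bval_path, bvec_path) -> GradientScheme:
    return load_scheme(Path(bval_path).read_text(), Path(bvec_path).read_text())


def save_cohort_tsv(records: list[SubjectRecord], path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "age": r.age, "sex": r.sex, "pain": r.pain}
        for t, v in r.tract_vintra_true.items():
            row[f"true_{t}"] = v
        for t, v in r.tract_vintra_est.items():
            row[f"est_{t}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_cohort_tsv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        true = {c[5:]: float(row[c]) for c in df.columns
                if c.startswith("true_") and np.isfinite(row[c])}
        est = {c[4:]: float(row[c]) for c in df.columns
               if c.startswith("est_") and np.isfinite(row[c])}
        out.append(SubjectRecord(subject_id=str(row["subject_id"]), age=float(row["age"]),
                                 sex=str(row["sex"]), pain=float(row["pain"]),
                                 tract_vintra_true=true, tract_vintra_est=est))
    return out


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def save_rois(rois, path) -> None:
    """Sphere-ROI config dialect: one line per ROI, ``name cx cy cz radius_mm``."""
    lines = [f"{r.name} {r.center[0]:g} {r.center[1]:g} {r.center[2]:g} {r.radius:g}"
             for r in rois]
    Path(path).write_text("\n".join(lines) + "\n")


def load_rois(path):
    from .phantom import RoiSpec

    rois = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#")[0].strip()
        if not line:
            continue
        name, cx, cy, cz, rad = line.split()
        rois.append(RoiSpec(name=name, center=np.array([float(cx), float(cy), float(cz)]),
                            radius=float(rad)))
    return rois


def save_tract_limits(limits: dict, path) -> None:
    """Per-tract mask thresholds as TSV: tract, lower_limit[, upper_limit]."""
    lines = ["tract\tlower_limit\tupper_limit"]
    for tract, v in limits.items():
        lo, hi = v if isinstance(v, (tuple, list)) else (v, "")
        lines.append(f"{tract}\t{lo}\t{hi}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_tract_limits(path) -> dict:
    """Read per-tract lower probability limits from a TSV (tract, lower_limit, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "tract" not in df.columns or "lower_limit" not in df.columns:
        raise ValueError("tract-limits TSV needs 'tract' and 'lower_limit' columns")
    return {str(r["tract"]): float(r["lower_limit"]) for _, r in df.iterrows()}
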