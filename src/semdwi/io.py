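"""File formats: NIfTI-1 volumes, FSL-style .bval lines, JSON sidecars and
the pipeline's CSV tables.

A single image dialect is used throughout: NIfTI-1 with an RAS diagonal
affine built from the voxel size; world <-> voxel conversion goes through
the affine only. Parameter maps carry NaN as the missing-value marker.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .roi_extraction import BiopsyTarget, PARAMETER_NAMES
from .scheme import BValueScheme
from .sem_fit import DWIVolume, ParameterMaps

TARGET_COLUMNS = ["target_id", "patient_id", "i", "j", "k", "source_image"]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def write_dwi(dwi: DWIVolume, stem: Path | str) -> dict[str, Path]:
    """Write `<stem>.nii` (4-D), `<stem>.bval` and `<stem>.json` (NEX sidecar)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "nifti": stem.with_suffix(".nii"),
        "bval": stem.with_suffix(".bval"),
        "sidecar": stem.with_suffix(".json"),
    }
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float64), _affine(dwi.voxel_size)),
             paths["nifti"])
    paths["bval"].write_text(
        " ".join(f"{b:g}" for b in dwi.scheme.b_values) + "\n"
    )
    paths["sidecar"].write_text(json.dumps(
        {"nex": dwi.scheme.nex.tolist(), "voxel_size_mm": list(dwi.voxel_size)},
        indent=2,
    ))
    return paths


def read_dwi(stem: Path | str) -> DWIVolume:
    """Read a 4-D NIfTI + .bval (+ optional NEX sidecar) back into a volume."""
    stem = Path(stem)
    nii_path = stem.with_suffix(".nii")
    img = nib.load(nii_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{nii_path}: expected a 4-D volume, got {data.ndim}-D")
    bval_path = stem.with_suffix(".bval")
    try:
        b = np.array([float(x) for x in bval_path.read_text().split()])
    except (OSError, ValueError) as exc:
        raise FormatError(f"{bval_path}: unreadable .bval") from exc
    if b.size != data.shape[3]:
        raise FormatError(
            f"{bval_path}: {b.size} b values but volume has {data.shape[3]} frames"
        )
    nex = None
    sidecar = stem.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        nex = np.array(meta.get("nex"), dtype=int) if meta.get("nex") else None
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DWIVolume(data=data, scheme=BValueScheme(b, nex), voxel_size=voxel_size)


def write_maps(maps: ParameterMaps, out_dir: Path | str, voxel_size) -> dict[str, Path]:
    """Write the four parameter maps plus quality maps as 3-D NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {name: maps[name] for name in PARAMETER_NAMES}
    arrays.update({
        "rss1500": maps.rss1500, "rss5000": maps.rss5000,
        "fit_mask": maps.fit_mask.astype(np.uint8),
        "converged1500": maps.converged1500.astype(np.uint8),
        "converged5000": maps.converged5000.astype(np.uint8),
    })
    paths = {}
    aff = _affine(voxel_size)
    for name, arr in arrays.items():
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), p)
        paths[name] = p
    return paths


def read_maps(maps_dir: Path | str) -> dict[str, np.ndarray]:
    """Read parameter maps (`ddc1500.nii` etc.) from a directory."""
    maps_dir = Path(maps_dir)
    out = {}
    for name in PARAMETER_NAMES:
        p = maps_dir / f"{name}.nii"
        if not p.exists():
            raise FormatError(f"missing parameter map {p}")
        out[name] = np.asarray(nib.load(p).dataobj, dtype=float)
    return out


def write_truth(truth, out_dir: Path | str) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(truth.voxel_size)
    paths = {}
    for name, arr in (("true_ddc", truth.ddc_map), ("true_alpha", truth.alpha_map),
                      ("true_s0", truth.s0_map), ("labels", truth.label_map)):
        p = out_dir / f"{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), aff), p)
        paths[name] = p
    return paths


def write_targets(targets: list[BiopsyTarget], path: Path | str) -> None:
    pd.DataFrame(
        {
            "target_id": [t.target_id for t in targets],
            "patient_id": [t.patient_id for t in targets],
            "i": [t.center[0] for t in targets],
            "j": [t.center[1] for t in targets],
            "k": [t.center[2] for t in targets],
            "source_image": [t.source_image for t in targets],
        }
    ).to_csv(path, index=False)


def read_targets(path: Path | str) -> list[BiopsyTarget]:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty targets file") from exc
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no target rows")
    return [
        BiopsyTarget(str(r.target_id), str(r.patient_id),
                     (int(r.i), int(r.j), int(r.k)), str(r.source_image))
        for r in df.itertuples()
    ]
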