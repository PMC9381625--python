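"""NIfTI, manifest and configuration I/O.

Voxel indices are 0-based (i, j, k) with k the axial slice; spacing comes
from the NIfTI header zooms and is written back as a diagonal affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .voi import ImageVolume, VOIMask

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "write_voi", "read_manifest", "write_manifest", "write_cohort"]


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI volume; spacing taken from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(values=np.asarray(data, dtype=np.float64), spacing=spacing)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.values, affine), str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return read_volume(path).values > 0.5


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    write_volume(ImageVolume(values=mask.astype(np.float64), spacing=spacing), path)


def write_voi(voi: VOIMask, path: str | Path) -> None:
    """VOI mask as NIfTI plus a JSON sidecar with seed voxel and diameter."""
    path = Path(path)
    write_mask(voi.mask, voi.spacing, path)
    sidecar = {
        "seed_voxel": list(voi.seed_voxel),
        "diameter_mm": voi.diameter_mm,
        "voxel_count": voi.voxel_count,
    }
    side = path.with_name(path.name.split(".")[0] + ".json")
    side.write_text(json.dumps(sidecar, indent=2))


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    return json.loads(path.read_text())


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def write_cohort(cases, out_dir: str | Path,
                 clicks: dict[str, tuple[int, int, int]] | None = None) -> Path:
    """Write per-case NIfTI files plus a manifest; returns the manifest path."""
    from .phantom import cohort_manifest

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cohort_manifest(cases, clicks)
    for case, rec in zip(cases, manifest["cases"]):
        cdir = out / case.case_id
        cdir.mkdir(exist_ok=True)
        paths = {}
        for seq, vol in case.volumes.items():
            p = cdir / f"{seq}.nii.gz"
            write_volume(vol, p)
            paths[seq] = str(p)
        pm = cdir / "prostate_mask.nii.gz"
        write_mask(case.prostate_mask, case.volumes["ADC"].spacing, pm)
        paths["prostate_mask"] = str(pm)
        rec["paths"] = paths
    mpath = out / "manifest.json"
    write_manifest(manifest, mpath)
    return mpath
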