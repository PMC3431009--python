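"""File formats: NIfTI scans and masks, phenotype CSV, TSV tables.

Scans are written as 4D NIfTI (RAS+, identity-scaled affine, 0-based voxel
coordinates throughout); template compartments as 3D label images; seeds
and motion parameters as plain TSV; phenotypes as CSV with ``NA`` marking
missing values.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic_data import BrainTemplate, Scan4D

__all__ = [
    "save_scan",
    "load_scan",
    "save_template",
    "load_template",
    "save_phenotypes",
    "load_phenotypes",
    "save_motion_params",
    "load_motion_params",
    "save_seeds",
    "load_seeds",
]

_AFFINE = np.eye(4)


def save_scan(scan: Scan4D, path, motion_path=None) -> None:
    img = nib.Nifti1Image(scan.data.astype(np.float32), _AFFINE)
    img.header.set_zooms((1.0, 1.0, 1.0, scan.tr))
    img.to_filename(str(path))
    if motion_path is not None:
        save_motion_params(scan.motion_params, motion_path)


def load_scan(path, mask: np.ndarray, motion_path=None, tr: float | None = None) -> Scan4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    motion = load_motion_params(motion_path) if motion_path is not None else np.zeros((data.shape[-1], 0))
    return Scan4D(data=data, tr=tr, mask=np.asarray(mask, dtype=bool), motion_params=motion)


def _save_label(volume: np.ndarray, path) -> None:
    nib.Nifti1Image(np.asarray(volume, dtype=np.int16), _AFFINE).to_filename(str(path))


def save_template(template: BrainTemplate, outdir) -> dict[str, Path]:
    """Write mask/parcels/CSF/periphery NIfTIs and a seeds TSV into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mask": outdir / "brain_mask.nii.gz",
        "parcels": outdir / "parcel_labels.nii.gz",
        "csf": outdir / "csf_region.nii.gz",
        "periphery": outdir / "periphery.nii.gz",
        "seeds": outdir / "seeds.tsv",
    }
    _save_label(template.brain_mask, paths["mask"])
    _save_label(template.parcel_labels, paths["parcels"])
    _save_label(template.csf_region, paths["csf"])
    _save_label(template.periphery, paths["periphery"])
    save_seeds(template.seed_coords, paths["seeds"])
    return paths


def load_template(outdir) -> BrainTemplate:
    outdir = Path(outdir)

    def _load(name):
        return np.asarray(nib.load(str(outdir / name)).dataobj)

    mask = _load("brain_mask.nii.gz").astype(bool)
    template = BrainTemplate(
        grid_dims=mask.shape,
        brain_mask=mask,
        parcel_labels=_load("parcel_labels.nii.gz").astype(np.int16),
        seed_coords=load_seeds(outdir / "seeds.tsv"),
        csf_region=_load("csf_region.nii.gz").astype(bool),
        periphery=_load("periphery.nii.gz").astype(bool),
    )
    template.validate()
    return template


def save_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def load_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA", ""])


def save_motion_params(motion: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(motion)).to_csv(path, sep="\t", index=False, header=False)


def load_motion_params(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def save_seeds(coords: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(coords, dtype=int), columns=["x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


def load_seeds(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=int)
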