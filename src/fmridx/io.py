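"""Disk formats: NIfTI-1 scans, CSV phenotypes, feature/model containers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import Scan4D
from .reduction import FeatureBlock


def load_scan(path, tr: Optional[float] = None) -> Scan4D:
    """Read a 4-D NIfTI-1 scan (.nii / .nii.gz).

    The sampling period is taken from the header time step unless ``tr``
    overrides it; a missing/zero header TR without an override is an error.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    if tr is None:
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if not tr > 0:
            raise ValidationError(
                f"{path}: header carries no usable TR; pass tr= explicitly"
            )
    voxel = tuple(float(z) for z in zooms[:3])
    return Scan4D(values=data, voxel_size=voxel, sampling_period=float(tr))


def save_scan(scan: Scan4D, path) -> Path:
    """Write a scan as NIfTI-1 with TR in the header time step."""
    affine = np.diag(list(scan.voxel_size) + [1.0])
    img = nib.Nifti1Image(scan.values.astype(np.float32), affine)
    img.header.set_zooms(tuple(scan.voxel_size) + (scan.sampling_period,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return Path(path)


def load_phenotypes(path) -> pd.DataFrame:
    """Read a phenotypic CSV; empty IQ fields become NaN."""
    df = pd.read_csv(path)
    missing = {"subject_id", "site", "dx"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: phenotypic table lacks columns {sorted(missing)}")
    return df


def save_features(block: FeatureBlock, path) -> tuple[Path, Path]:
    """Persist a feature block as ``.npz`` with a JSON provenance sidecar."""
    path = Path(path)
    np.savez_compressed(path, features=block.features)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = npz.with_suffix(".json")
    sidecar.write_text(json.dumps(block.provenance, indent=2, default=str) + "\n")
    return npz, sidecar


def load_features(path) -> FeatureBlock:
    npz = Path(path)
    with np.load(npz) as data:
        features = data["features"]
    sidecar = npz.with_suffix(".json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FeatureBlock(features=features, provenance=provenance)
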