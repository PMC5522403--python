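"""Voxel-data readers and writers (NIfTI, NPZ, CSV)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_nifti_timeseries",
    "read_voxels_npz",
    "write_voxels_npz",
    "read_voxels_csv",
    "write_fits_csv",
]


def read_nifti_timeseries(path: str, mask_path: str | None = None) -> np.ndarray:
    """Load a 4-D NIfTI as a (voxels, TRs) array, optionally masked.

    The mask is a 3-D NIfTI; nonzero voxels are kept, in C order.
    """
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    flat = data.reshape(-1, data.shape[-1])
    if mask_path is not None:
        mask = np.asanyarray(nib.load(mask_path).dataobj)
        if mask.shape != data.shape[:3]:
            raise ValueError("mask shape does not match volume")
        flat = flat[mask.reshape(-1) != 0]
    return flat.astype(float)


def write_voxels_npz(path: str, Y: np.ndarray, tr_s: float) -> None:
    np.savez_compressed(path, Y=np.asarray(Y, float), tr_s=tr_s)


def read_voxels_npz(path: str) -> tuple[np.ndarray, float]:
    with np.load(path) as npz:
        return npz["Y"].astype(float), float(npz["tr_s"])


def read_voxels_csv(path: str) -> np.ndarray:
    """CSV with one row per voxel, one column per TR."""
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def write_fits_csv(fits, path: str) -> None:
    from .prf import fits_to_frame

    fits_to_frame(fits).to_csv(path, index=False)
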