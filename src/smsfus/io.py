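"""Standard-format I/O: NIfTI volumes, HDF5 IQ/channel data, CSV, JSON sidecars.

Volumetric data travel as NIfTI with an affine carrying the Bregma-relative
millimetre frame (x lateral, y dorsoventral, z anteroposterior); every
written volume gets a JSON sidecar echoing TR, per-slice onsets and the
generating/filtering parameters so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .clutter import IQBlock
from .volume import PDVolume

__all__ = [
    "save_pd_nifti",
    "load_pd_nifti",
    "save_labels_nifti",
    "load_labels_nifti",
    "save_iq_h5",
    "load_iq_h5",
    "write_sidecar",
    "read_sidecar",
]


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def write_sidecar(path, meta: dict) -> Path:
    sp = _sidecar_path(path)
    with open(sp, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return sp


def read_sidecar(path) -> dict:
    with open(_sidecar_path(path)) as fh:
        return json.load(fh)


def save_pd_nifti(vol: PDVolume, path, extra_meta: dict | None = None) -> None:
    """Write a 4D Power Doppler series as NIfTI + JSON sidecar."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms((*np.abs(np.diag(vol.affine)[:3]), vol.tr_s))
    nib.save(img, str(path))
    meta = {"tr_s": vol.tr_s, "slice_onsets_s": list(map(float, vol.slice_onsets_s))}
    meta.update(getattr(vol, "provenance", {}) or {})
    meta.update(extra_meta or {})
    write_sidecar(path, meta)


def load_pd_nifti(path) -> PDVolume:
    img = nib.load(str(path))
    meta = read_sidecar(path)
    return PDVolume(
        np.asarray(img.dataobj, dtype=float),
        tr_s=float(meta["tr_s"]),
        slice_onsets_s=np.asarray(meta["slice_onsets_s"], dtype=float),
        affine=np.asarray(img.affine),
    )


def save_labels_nifti(labels: np.ndarray, path, table: pd.DataFrame | None = None, affine=None) -> None:
    """Write an integer label volume (+ optional region table CSV)."""
    aff = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), aff), str(path))
    if table is not None:
        table.to_csv(str(Path(path).with_suffix("").with_suffix("")) + "_regions.csv", index=False)


def load_labels_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(int)


def save_iq_h5(block: IQBlock, path, attrs: dict | None = None) -> None:
    """Write an IQ block to HDF5 (dataset /frames, complex)."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("frames", data=block.data)
        ds.attrs["frame_rate_hz"] = block.frame_rate_hz
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def load_iq_h5(path) -> IQBlock:
    with h5py.File(path, "r") as fh:
        ds = fh["frames"]
        return IQBlock(ds[()], frame_rate_hz=float(ds.attrs["frame_rate_hz"]))
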