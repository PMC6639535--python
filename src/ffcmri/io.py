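"""Serialisation: HDF5 raw data, NIfTI maps, CSV profiles, JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .quantify import NMRDProfile
from .scanner import KSpaceSeries

__all__ = [
    "save_kspace_h5",
    "load_kspace_h5",
    "save_nifti_map",
    "load_nifti_map",
    "profile_to_csv",
    "profile_from_csv",
    "write_manifest",
]

PROFILE_COLUMNS = ["field_T", "frequency_Hz", "R1_s-1", "R1_err_s-1"]


def save_kspace_h5(path, kspace: KSpaceSeries, metadata: Optional[dict] = None) -> None:
    """Write a KSpaceSeries (data, navigators, timing) to HDF5 + JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=kspace.data)
        if kspace.navigators is not None:
            h5.create_dataset("navigators", data=kspace.navigators)
        if kspace.line_times is not None:
            h5.create_dataset("line_times", data=kspace.line_times)
        h5.attrs["evolution_fields"] = np.asarray(kspace.evolution_fields)
        h5.attrs["navigator_dwell"] = kspace.navigator_dwell
        h5.attrs["detection_field"] = kspace.detection_field
        flat_times = json.dumps([list(ts) for ts in kspace.evolution_times])
        h5.attrs["evolution_times_json"] = flat_times
    sidecar = {
        "evolution_fields_T": list(kspace.evolution_fields),
        "evolution_times_s": [list(ts) for ts in kspace.evolution_times],
        "detection_field_T": kspace.detection_field,
        "shape": list(kspace.data.shape),
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_kspace_h5(path) -> KSpaceSeries:
    with h5py.File(path, "r") as h5:
        data = h5["kspace"][...]
        navs = h5["navigators"][...] if "navigators" in h5 else None
        line_times = h5["line_times"][...] if "line_times" in h5 else None
        fields = tuple(float(b) for b in h5.attrs["evolution_fields"])
        times = tuple(tuple(ts) for ts in json.loads(h5.attrs["evolution_times_json"]))
        return KSpaceSeries(
            data=data,
            evolution_fields=fields,
            evolution_times=times,
            navigators=navs,
            navigator_dwell=float(h5.attrs["navigator_dwell"]),
            line_times=line_times,
            detection_field=float(h5.attrs["detection_field"]),
        )


def save_nifti_map(path, array: np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a 2-D (or stacked 3-D) map as NIfTI with isotropic voxels."""
    arr = np.asarray(array, dtype=np.float64)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_nifti_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def profile_to_csv(path, profile: NMRDProfile) -> None:
    """Write an NMRD profile with the standard header columns."""
    err = profile.r1_err if profile.r1_err is not None else np.zeros_like(profile.r1)
    df = pd.DataFrame(
        {
            "field_T": profile.fields,
            "frequency_Hz": profile.frequencies,
            "R1_s-1": profile.r1,
            "R1_err_s-1": err,
        }
    )
    df.to_csv(path, index=False)


def profile_from_csv(path) -> NMRDProfile:
    df = pd.read_csv(path)
    missing = [c for c in ("field_T", "R1_s-1") if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    err = df["R1_err_s-1"].to_numpy() if "R1_err_s-1" in df.columns else None
    return NMRDProfile(fields=df["field_T"].to_numpy(), r1=df["R1_s-1"].to_numpy(), r1_err=err)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, artefacts: Dict[str, str]) -> Path:
    """JSON manifest listing every artefact with its checksum."""
    out_dir = Path(out_dir)
    entries = []
    for kind, rel in artefacts.items():
        p = out_dir / rel
        entries.append({"kind": kind, "path": rel, "sha256": _sha256(p), "bytes": p.stat().st_size})
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"artefacts": entries}, indent=2))
    return manifest_path
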