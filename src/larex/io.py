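"""Reading and writing of spectra, estimates and parameter maps.

Spectrum-mode data travel as delimited text (columns offset_ppm, Z, B1_uT,
long format, one row per sample) with an optional JSON sidecar holding
provenance; map-mode stacks are NIfTI volumes with offsets and B1 levels
along the fourth dimension, described by a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .zproc import ZStack

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_estimates",
    "write_nifti_stack",
    "read_nifti_stack",
    "write_map",
]


def write_spectra(path, stack: ZStack, sidecar: dict | None = None) -> None:
    """Write a sample-mode stack as delimited text (+ JSON sidecar)."""
    if stack.voxel_shape != ():
        raise ValueError("text serialization is for sample-mode stacks")
    rows = []
    for b, b1 in enumerate(stack.B1_uT):
        for o, off in enumerate(stack.offsets_ppm):
            rows.append((off, stack.Z[b, o], b1))
    df = pd.DataFrame(rows, columns=["offset_ppm", "Z", "B1_uT"])
    df.to_csv(path, sep="\t", index=False)
    meta = {"normalized": bool(stack.normalized)}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_spectra(path) -> ZStack:
    """Read a delimited-text stack written by :func:`write_spectra`."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"offset_ppm", "Z", "B1_uT"}
    if not required.issubset(df.columns):
        raise ValueError(f"spectrum table needs columns {sorted(required)}")
    b1s = np.sort(df["B1_uT"].unique())
    offs = np.sort(df["offset_ppm"].unique())
    Z = np.full((b1s.size, offs.size), np.nan)
    bi = {v: i for i, v in enumerate(b1s)}
    oi = {v: i for i, v in enumerate(offs)}
    for _, r in df.iterrows():
        Z[bi[r["B1_uT"]], oi[r["offset_ppm"]]] = r["Z"]
    normalized = True
    side = Path(str(path) + ".json")
    if side.exists():
        normalized = bool(json.loads(side.read_text()).get("normalized", True))
    return ZStack(Z, offs, b1s, normalized=normalized)


def write_estimates(path, estimates: list[dict]) -> None:
    """Write omega-plot results as a delimited table."""
    cols = ["id", "method", "f_b_permil", "k_ba_Hz", "intercept", "slope",
            "r_squared", "admissible", "flags"]
    df = pd.DataFrame(estimates)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df[cols].to_csv(path, sep="\t", index=False)


def write_nifti_stack(prefix, stack: ZStack) -> None:
    """Write a map-mode stack as NIfTI (4th dim = B1-major frames) + sidecar."""
    if len(stack.voxel_shape) != 2:
        raise ValueError("map-mode stacks carry two voxel dimensions")
    ny, nx = stack.voxel_shape
    data = stack.Z.reshape(ny, nx, 1, -1)
    nib.save(nib.Nifti1Image(data.astype(np.float32), np.eye(4)),
             f"{prefix}.nii")
    meta = {
        "offsets_ppm": list(map(float, stack.offsets_ppm)),
        "B1_uT": list(map(float, stack.B1_uT)),
        "normalized": bool(stack.normalized),
        "frame_order": "B1-major",
    }
    Path(f"{prefix}.json").write_text(json.dumps(meta, indent=2))


def read_nifti_stack(prefix) -> ZStack:
    img = nib.load(f"{prefix}.nii")
    meta = json.loads(Path(f"{prefix}.json").read_text())
    offs = np.array(meta["offsets_ppm"])
    b1s = np.array(meta["B1_uT"])
    data = np.asarray(img.dataobj)
    ny, nx = data.shape[:2]
    Z = data.reshape(ny, nx, b1s.size, offs.size)
    return ZStack(Z, offs, b1s, normalized=meta.get("normalized", False))


def write_map(path, array: np.ndarray) -> None:
    """Write a 2D parameter map (f_b, k_ba, T1 ...) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(array, np.float32)[..., None], np.eye(4)),
             str(path))
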