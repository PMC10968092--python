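"""Volume and table I/O: NIfTI, raw+JSON sidecar, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import LabeledVolume
from .tissues import TISSUE_NAMES


def save_nifti(vol: LabeledVolume, path) -> None:
    """Write labels as an unsigned-integer NIfTI; spacing/origin go in the affine."""
    affine = np.diag([*vol.spacing, 1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))


def load_nifti(path) -> LabeledVolume:
    img = nib.load(str(path))
    affine = img.affine
    return LabeledVolume(
        labels=np.asarray(img.dataobj).astype(np.uint8),
        spacing=np.abs(np.diag(affine)[:3]),
        origin=affine[:3, 3].copy(),
    )


def save_raw(vol: LabeledVolume, stem) -> tuple[Path, Path]:
    """Write labels as flat uint8 binary plus a JSON sidecar with grid metadata."""
    stem = Path(stem)
    raw_path = stem.with_suffix(".raw")
    json_path = stem.with_suffix(".json")
    vol.labels.astype(np.uint8).tofile(raw_path)
    sidecar = {
        "dims": list(vol.shape),
        "spacing_mm": vol.spacing.tolist(),
        "origin_mm": vol.origin.tolist(),
        "dtype": "uint8",
        "order": "C",
        "label_map": {str(k): v for k, v in TISSUE_NAMES.items()},
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return raw_path, json_path


def load_raw(stem) -> LabeledVolume:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".json").read_text())
    labels = np.fromfile(stem.with_suffix(".raw"), dtype=np.uint8).reshape(sidecar["dims"])
    return LabeledVolume(
        labels=labels,
        spacing=np.array(sidecar["spacing_mm"]),
        origin=np.array(sidecar["origin_mm"]),
    )


def load_volume(path) -> LabeledVolume:
    """Dispatch on extension: .nii/.nii.gz -> NIfTI, .raw/.json -> raw+sidecar."""
    p = Path(path)
    if p.name.endswith((".nii", ".nii.gz")):
        return load_nifti(p)
    if p.suffix in (".raw", ".json", ""):
        return load_raw(p.with_suffix(""))
    raise ValueError(f"unrecognized volume format: {p}")


def save_path_spec_csv(segments: dict[str, np.ndarray], path) -> None:
    """Conduction-path control points: columns segment,x_mm,y_mm,z_mm (ordered)."""
    rows = []
    for seg, pts in segments.items():
        for x, y, z in np.atleast_2d(pts):
            rows.append({"segment": seg, "x_mm": x, "y_mm": y, "z_mm": z})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_path_spec_csv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    out: dict[str, np.ndarray] = {}
    for seg in df["segment"].unique():
        sub = df[df["segment"] == seg]
        out[str(seg)] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    return out
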